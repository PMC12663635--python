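# SYNTHETIC stand-in gene list bundled for demonstrations and tests.
# Replace with a real curated list (one gene symbol per line) to analyse
# actual data; '#' lines are ignored by the reader.
prey0003
prey0007
prey0009
prey0010
prey0015
prey0016
prey0023
prey0024
prey0036
prey0040
prey0047
prey0048
prey0061
prey0077
prey0101
prey0114
prey0115
prey0118
prey0119
prey0121
prey0130
prey0131
prey0135
prey0137
prey0143
prey0150
prey0152
prey0153
prey0157
prey0159
prey0161
prey0162
prey0166
prey0167
prey0177
prey0188
prey0192
prey0193
prey0196
prey0199
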