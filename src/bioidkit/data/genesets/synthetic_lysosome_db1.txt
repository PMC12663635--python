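# SYNTHETIC stand-in gene list bundled for demonstrations and tests.
# Replace with a real curated list (one gene symbol per line) to analyse
# actual data; '#' lines are ignored by the reader.
prey0001
prey0007
prey0017
prey0021
prey0027
prey0050
prey0058
prey0059
prey0065
prey0071
prey0073
prey0075
prey0080
prey0083
prey0102
prey0104
prey0112
prey0117
prey0127
prey0131
prey0132
prey0141
prey0144
prey0151
prey0163
prey0167
prey0169
prey0172
prey0181
prey0188
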