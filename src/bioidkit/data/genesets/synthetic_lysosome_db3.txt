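# SYNTHETIC stand-in gene list bundled for demonstrations and tests.
# Replace with a real curated list (one gene symbol per line) to analyse
# actual data; '#' lines are ignored by the reader.
prey0000
prey0002
prey0005
prey0015
prey0029
prey0033
prey0045
prey0047
prey0048
prey0053
prey0054
prey0069
prey0077
prey0098
prey0100
prey0101
prey0107
prey0114
prey0119
prey0124
prey0130
prey0143
prey0151
prey0154
prey0164
prey0174
prey0185
prey0186
prey0187
prey0192
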