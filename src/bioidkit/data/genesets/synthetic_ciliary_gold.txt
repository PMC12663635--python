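# SYNTHETIC stand-in gene list bundled for demonstrations and tests.
# Replace with a real curated list (one gene symbol per line) to analyse
# actual data; '#' lines are ignored by the reader.
prey0002
prey0003
prey0010
prey0018
prey0019
prey0023
prey0025
prey0037
prey0053
prey0054
prey0062
prey0066
prey0075
prey0084
prey0094
prey0095
prey0098
prey0113
prey0116
prey0147
prey0149
prey0153
prey0156
prey0159
prey0162
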