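# SYNTHETIC stand-in gene list bundled for demonstrations and tests.
# Replace with a real curated list (one gene symbol per line) to analyse
# actual data; '#' lines are ignored by the reader.
prey0000
prey0003
prey0004
prey0013
prey0017
prey0018
prey0022
prey0025
prey0030
prey0034
prey0050
prey0053
prey0054
prey0063
prey0069
prey0074
prey0079
prey0085
prey0086
prey0096
prey0098
prey0101
prey0104
prey0107
prey0120
prey0144
prey0161
prey0172
prey0175
prey0181
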