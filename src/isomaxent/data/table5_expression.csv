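cell_line,treatment,I,II,III,IV
A549,normal,0.264,0.268,0.462,0.006
A549,colchicine,0.316,0.267,0.414,0.002
A549,D20,0.188,0.36,0.429,0.024
HeLa,normal,0.452,0.139,0.352,0.057
HeLa,colchicine,0.436,0.138,0.37,0.055
HeLa,D20,0.395,0.227,0.258,0.119
MCF-7,normal,0.112,0.596,0.291,0
MCF-7,colchicine,0.168,0.499,0.333,0
MCF-7,D20,0.162,0.309,0.509,0.02
CEM,normal,0.279,0.16,0.56,0
CEM,colchicine,0.852,0,0,0.148
CEM,D20,0.328,0.181,0.481,0.009
M010B,normal,0.393,0.24,0.329,0.038
M010B,colchicine,0.446,0.19,0.259,0.106
M010B,D20,0.466,0.189,0.243,0.101
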