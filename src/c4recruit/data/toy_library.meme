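MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF GBOX_toy
letter-probability matrix: alphabet= ACGT w= 6 nsites= 20 E= 0
0.060000 0.820000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.060000 0.820000 0.060000 0.060000
0.060000 0.060000 0.820000 0.060000
0.060000 0.060000 0.060000 0.820000
0.060000 0.060000 0.820000 0.060000

MOTIF TATA_toy
letter-probability matrix: alphabet= ACGT w= 6 nsites= 20 E= 0
0.060000 0.060000 0.060000 0.820000
0.820000 0.060000 0.060000 0.060000
0.060000 0.060000 0.060000 0.820000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000

MOTIF DOF_toy
letter-probability matrix: alphabet= ACGT w= 6 nsites= 20 E= 0
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.060000 0.060000 0.820000 0.060000
0.060000 0.060000 0.820000 0.060000

MOTIF IBOX_toy
letter-probability matrix: alphabet= ACGT w= 6 nsites= 20 E= 0
0.060000 0.060000 0.820000 0.060000
0.820000 0.060000 0.060000 0.060000
0.060000 0.060000 0.060000 0.820000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.060000 0.060000 0.820000 0.060000

MOTIF GT1_toy
letter-probability matrix: alphabet= ACGT w= 6 nsites= 20 E= 0
0.060000 0.060000 0.820000 0.060000
0.060000 0.060000 0.820000 0.060000
0.060000 0.060000 0.060000 0.820000
0.060000 0.060000 0.060000 0.820000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000

MOTIF TELO_toy
letter-probability matrix: alphabet= ACGT w= 8 nsites= 20 E= 0
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.820000 0.060000 0.060000 0.060000
0.060000 0.820000 0.060000 0.060000
0.060000 0.820000 0.060000 0.060000
0.060000 0.820000 0.060000 0.060000
0.060000 0.060000 0.060000 0.820000
0.820000 0.060000 0.060000 0.060000

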