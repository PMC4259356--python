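MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF SYN_MAZ
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000

MOTIF SYN_MEIS1
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.850000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.850000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000

MOTIF SYN_FOXO4
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.850000 0.050000 0.050000

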