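# Toy RNA-binding-protein motif set (counts; synthetic stand-ins for a
# curated motif database). Consensus sequences follow the literature motifs
# of the named splicing factors loosely; weights are illustrative.
>M001 SRSF5
A  2 16  2  1 16  2  2
C  1  1 16  1  1 16  2
G 16  1  1 16  1  1  2
T  1  2  1  2  2  1 14
>M002 SRSF9
A 16  1  1 16  2  16
C  1  1  2  1 16  2
G  1 16 16  1  1  1
T  2  2  1  2  1  1
>M003 RBFOX1
A  1  1  2 16  1  2
C  1  1 16  1  1  1
G  1 16  1  1  1 16
T 17  2  1  2 17  1
>M004 PTBP1
A  1  1  1  1  1  1
C  2 16  2 16  2 16
G  1  1  1  1  1  1
T 16  2 16  2 16  2
>M005 NOVA1
A  2  1 16  2  1 16
C  1 16  1  1 16  1
G  1  1  2  1  1  2
T 16  2  1 16  2  1
>M006 HNRNPA1
A  1 16  1  1  1  2
C  1  1  1  1  1  1
G  2  2 16 16 16  1
T 16  1  2  2  2 16
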