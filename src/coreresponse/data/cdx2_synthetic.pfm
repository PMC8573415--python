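>PH0013.1-like Cdx2_synthetic
A  [  5 85  5 85 85 85  5 ]
C  [ 30  5  5  5  5  5  5 ]
G  [  5  5  5  5  5  5 35 ]
T  [ 60  5 85  5  5  5 55 ]
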