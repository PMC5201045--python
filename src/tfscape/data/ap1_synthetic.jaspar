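>AP1 AP1
A  [ 5  5  85  5  5  5  85 ]
C  [ 5  5  5  85  5  85  5 ]
G  [ 5  85  5  5  5  5  5 ]
T  [ 85  5  5  5  85  5  5 ]
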