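group,stem,mode,weight
F00,F00,prefix,7.1
G81,G81,prefix,4.4
G30,G30,prefix,4.0
I69,I69,prefix,3.7
R29,R29,prefix,3.6
N39,N39,prefix,3.2
F05,F05,prefix,3.2
W19,W19,prefix,3.2
S00,S00,prefix,3.2
R31,R31,prefix,3.0
B96,B96,prefix,2.9
R41,R41,prefix,2.7
R26,R26,prefix,2.6
I67,I67,prefix,2.3
R56,R56,prefix,2.2
R33,R33,prefix,2.1
G20,G20,prefix,2.0
R54,R54,prefix,1.9
F03,F03,prefix,1.8
W18,W18,prefix,1.8
E86,E86,prefix,1.7
Z75,Z75,prefix,1.6
M25,M25,prefix,1.5
E87,E87,prefix,1.5
W06,W06,prefix,1.4
S06,S06,prefix,1.4
Z50,Z50,prefix,1.3
F01,F01,prefix,1.3
R40,R40,prefix,1.2
Z74,Z74,prefix,1.1
S72,S72,prefix,1.0
L03,L03,prefix,1.0
K59,K59,prefix,0.9
N17,N17,prefix,0.9
L89,L89,prefix,0.9
Z87,Z87,prefix,0.8
R02,R02,prefix,0.8
J96,J96,prefix,0.7
R55,R55,prefix,0.7
X59,X59,prefix,0.6
I95,I95,prefix,0.6
M19,M19,prefix,0.5
G40,G40,prefix,0.5
A41,A41,prefix,0.4
J18,J18,prefix,0.4
I48,I48,prefix,0.3
N18,N18,prefix,0.3
R11,R11,prefix,0.2
E53,E53,prefix,0.2
D64,D64,prefix,0.1
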