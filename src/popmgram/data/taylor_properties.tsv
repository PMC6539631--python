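# taylor-overlapping-v1
Polar	N,Q,S,D,E,C,T,K,R,H,Y,W
Positive	K,H,R
Negative	D,E
Charged	K,H,R,D,E
Hydrophobic	A,G,C,T,I,V,L,K,H,F,Y,W,M
Aliphatic	I,V,L
Aromatic	F,Y,W,H
Small	P,N,D,T,C,A,G,S,V
Tiny	A,S,G,C
Proline	P
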