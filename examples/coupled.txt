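# two-species network X1 <-> 2 X2; conserves 2 c1 + c2
species: X1 X2
X1 <-> 2 X2 ; kf=1 kb=1
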