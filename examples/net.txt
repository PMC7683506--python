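# scalar two-reaction-pair network with detailed balance (c* = 1)
species: X
0 <-> X ; kf=4 kb=4
0 <-> 2 X ; kf=1 kb=1
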