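# linear birth-death network 0 <-> X with unit rates
species: X
0 <-> X ; kf=1 kb=1
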