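# 3-site chain, footprint 2, unit rates, 1% drop-off, no interaction forces
n: 3
ell: 2
lambda: [1, 1, 1, 1]
alpha: [0.01, 0.01, 0.01]
q: 1
r: 1
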