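# Misclassified surrogate (sens 0.90, spec 0.95); treatment more likely
# when the confounder is absent (p0 > p1) -> negative bias.
name: scenario1
sens: 0.90
spec: 0.95
pL: 0.50
p0: 0.90
p1: 0.45
beta: 1.0
lam: 2.0
beta0: 0.0
sigma: 1.0
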