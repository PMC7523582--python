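# High-prevalence confounder, moderate confounder-treatment link.
name: scenario3
sens: 0.90
spec: 0.95
pL: 0.80
p0: 0.50
p1: 0.75
beta: 1.0
lam: 2.0
beta0: 0.0
sigma: 1.0
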