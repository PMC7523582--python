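# No classification error; confounder prevalence 0.50, treatment 0.50/0.75.
name: scenario0
sens: 1.0
spec: 1.0
pL: 0.50
p0: 0.50
p1: 0.75
beta: 1.0
lam: 2.0
beta0: 0.0
sigma: 1.0
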