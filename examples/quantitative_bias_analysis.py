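"""Probabilistic quantitative bias analysis on one observed dataset.

We only get to see (A, L*, Y). Assuming the surrogate's sensitivity and
specificity each lie in [0.90, 0.98], we propagate that uncertainty
through the closed-form bias expressions: each prior draw re-estimates the
nuisance parameters (matrix-corrected for the assumed misclassification)
and yields one plausible bias, giving a whole bias distribution and
bias-adjusted effect estimates.
"""

from confbias import (
    MisclassSpec,
    ScenarioParams,
    SensSpecPrior,
    SimulationDesign,
    generate_dataset,
    run_qba,
)

# one synthetic "study" of 5,000 subjects with a misclassified confounder
design = SimulationDesign(
    params=ScenarioParams(pL=0.50, p0=0.90, p1=0.45, beta=1.0, lam=2.0),
    mis=MisclassSpec(sens=0.94, spec=0.94),
    n_obs=5000, n_reps=2, seed=11,
)
data = generate_dataset(design, 0)

for kind in ("uniform", "trapezoidal", "triangular"):
    prior = SensSpecPrior(kind, 0.90, 0.98)
    result = run_qba(data, prior, n_draws=5000, seed=7, correction="matrix")
    s = result.summary()["msm_ipw"]
    print(f"{kind:12s} mean bias {s['mean']:+.3f}  median {s['median']:+.3f}"
          f"  IQR ({s['iqr'][0]:+.3f}, {s['iqr'][1]:+.3f})")

print()
print(f"fitted MSM-IPW estimate: {result.fitted_msm:+.3f} (true ATE is 1)")
print("The three priors agree on the center of the bias distribution; the")
print("peaked priors (trapezoidal, triangular) just spread it less. Subtracting")
print("a bias draw from the fitted estimate gives an adjusted estimate.")
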