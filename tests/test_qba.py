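"""Priors over (sens, spec), nuisance-parameter correction, QBA propagation."""

import numpy as np
import pytest
from scipy import stats

from confbias import (
    IdentifiabilityError,
    MisclassSpec,
    ScenarioParams,
    SensSpecPrior,
    SimulationDesign,
    bias_conditional,
    bias_msm,
    estimate_bias_parameters,
    generate_dataset,
    run_qba,
    sample_prior,
)
from confbias.qba import PriorError

TRUE_PARAMS = ScenarioParams(pL=0.5, p0=0.9, p1=0.45, beta=1.0, lam=2.0)
TRUE_MIS = MisclassSpec(sens=0.90, spec=0.95)


def make_data(n=100_000, seed=31):
    design = SimulationDesign(params=TRUE_PARAMS, mis=TRUE_MIS, n_obs=n,
                              n_reps=2, seed=seed)
    return generate_dataset(design, 0)


class TestPriors:
    @pytest.mark.parametrize("kind", ["uniform", "trapezoidal", "triangular"])
    def test_support_and_symmetry(self, kind):
        prior = SensSpecPrior(kind, 0.90, 0.98)
        draws = sample_prior(prior, 20_000, seed=1)
        assert draws.shape == (20_000, 2)
        assert draws.min() >= 0.90 and draws.max() <= 0.98
        assert draws.mean() == pytest.approx(0.94, abs=0.001)

    def test_trapezoid_lower_mode_is_first_quartile(self):
        """Mass below the lower mode (one third in) is exactly 1/4."""
        prior = SensSpecPrior("trapezoidal", 0.90, 0.98)
        mode_lo = 0.90 + (0.98 - 0.90) / 3
        assert prior.distribution().cdf(mode_lo) == pytest.approx(0.25, abs=1e-12)
        draws = sample_prior(prior, 40_000, seed=2)
        assert (draws <= mode_lo).mean() == pytest.approx(0.25, abs=0.01)

    def test_spread_ordering_on_same_support(self):
        n = 50_000
        sds = {k: sample_prior(SensSpecPrior(k, 0.90, 0.98), n, seed=3).std()
               for k in ("uniform", "trapezoidal", "triangular")}
        assert sds["triangular"] < sds["trapezoidal"] < sds["uniform"]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(PriorError):
            SensSpecPrior("uniform", 0.9, 0.8)
        with pytest.raises(PriorError):
            SensSpecPrior("gaussian", 0.8, 0.9)

    def test_point_mass_prior(self):
        draws = sample_prior(SensSpecPrior("uniform", 1.0, 1.0), 10, seed=4)
        assert np.all(draws == 1.0)


class TestEstimateBiasParameters:
    def test_matrix_equals_naive_at_perfect_classification(self):
        data = make_data(n=20_000)
        naive, _ = estimate_bias_parameters(data, 1.0, 1.0, "naive")
        matrix, _ = estimate_bias_parameters(data, 1.0, 1.0, "matrix")
        for field in ("pL", "p0", "p1", "lam", "beta", "beta0"):
            assert getattr(matrix, field) == pytest.approx(
                getattr(naive, field), abs=1e-8)

    def test_prevalence_back_calculation(self):
        """pL = (P(L*=1) - (1-spec)) / (sens + spec - 1), e.g. 0.475 -> 0.50."""
        data = make_data(n=400_000, seed=13)
        p_star = (data.Lobs == 1).mean()
        params, _ = estimate_bias_parameters(data, 0.90, 0.95, "matrix")
        assert params.pL == pytest.approx((p_star - 0.05) / 0.85, abs=1e-12)
        assert params.pL == pytest.approx(0.50, abs=0.01)

    def test_matrix_recovers_generating_parameters(self):
        data = make_data(n=400_000, seed=19)
        params, _ = estimate_bias_parameters(data, 0.90, 0.95, "matrix")
        # ~3 SE at n = 400k: binomial SE ~ 0.001 on probabilities
        assert params.pL == pytest.approx(0.50, abs=0.005)
        assert params.p0 == pytest.approx(0.90, abs=0.01)
        assert params.p1 == pytest.approx(0.45, abs=0.01)
        assert params.lam == pytest.approx(2.0, abs=0.05)

    def test_chance_level_classification_not_identifiable(self):
        data = make_data(n=1000)
        with pytest.raises(IdentifiabilityError, match="chance"):
            estimate_bias_parameters(data, 0.5, 0.5, "matrix")

    def test_inconsistent_draw_names_parameter(self):
        # near-chance accuracy makes the corrected prevalence blow up
        data = make_data(n=1000)
        with pytest.raises(IdentifiabilityError, match="pL"):
            estimate_bias_parameters(data, 0.52, 0.50, "matrix")


class TestRunQba:
    def test_degenerate_prior_gives_zero_bias(self):
        data = make_data(n=5000)
        result = run_qba(data, SensSpecPrior("uniform", 1.0, 1.0),
                         n_draws=50, seed=7, correction="matrix")
        assert np.allclose(result.bias_draws_msm, 0.0, atol=1e-12)
        assert np.allclose(result.adjusted_msm, result.fitted_msm)

    def test_point_prior_at_truth_recovers_formula_bias(self):
        """With the prior degenerate at the true accuracy, the matrix
        correction concentrates the bias draws on the closed-form bias."""
        params = ScenarioParams(pL=0.5, p0=0.9, p1=0.45, beta=1.0, lam=2.0)
        mis = MisclassSpec(sens=0.92, spec=0.92)
        design = SimulationDesign(params=params, mis=mis, n_obs=400_000,
                                  n_reps=2, seed=23)
        data = generate_dataset(design, 0)
        result = run_qba(data, SensSpecPrior("uniform", 0.92, 0.92),
                         n_draws=20, seed=8, correction="matrix")
        truth_msm = bias_msm(params, mis)
        truth_cm = bias_conditional(params, mis)
        # n = 400k: nuisance-estimate noise on the bias is well below 0.02
        assert np.median(result.bias_draws_msm) == pytest.approx(
            truth_msm, abs=0.02)
        assert np.median(result.bias_draws_conditional) == pytest.approx(
            truth_cm, abs=0.02)

    def test_summary_ordering(self):
        data = make_data(n=5000)
        result = run_qba(data, SensSpecPrior("uniform", 0.85, 0.99),
                         n_draws=200, seed=9)
        for method, s in result.summary().items():
            assert s["iqr"][0] <= s["median"] <= s["iqr"][1]

    def test_narrow_priors_give_narrower_bias_distributions(self):
        data = make_data(n=20_000)
        spreads = {}
        means = {}
        for kind in ("uniform", "trapezoidal", "triangular"):
            res = run_qba(data, SensSpecPrior(kind, 0.85, 0.99),
                          n_draws=2000, seed=10)
            spreads[kind] = res.bias_draws_msm.std()
            means[kind] = res.bias_draws_msm.mean()
        assert spreads["triangular"] < spreads["uniform"]
        assert spreads["trapezoidal"] < spreads["uniform"]
        assert means["triangular"] == pytest.approx(means["uniform"], abs=0.05)

    def test_deterministic_under_fixed_seed(self):
        data = make_data(n=5000)
        a = run_qba(data, SensSpecPrior("uniform", 0.9, 0.98), 100, seed=11)
        b = run_qba(data, SensSpecPrior("uniform", 0.9, 0.98), 100, seed=11)
        assert np.array_equal(a.bias_draws_msm, b.bias_draws_msm)
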