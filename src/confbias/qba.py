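"""Probabilistic quantitative bias analysis for a misclassified confounder.

The analyst observes only (A, L*, Y) and does not know the surrogate's
sensitivity and specificity. A QBA places a prior over (sens, spec),
re-estimates the nuisance parameters of the bias expressions for each
prior draw, and propagates the draws through the closed-form biases of
both estimators, yielding a distribution of plausible biases (and,
optionally, of bias-adjusted treatment-effect estimates).

Two ways to turn data plus a (sens, spec) draw into bias-formula inputs:

* ``naive``: use the surrogate as if it were the truth — prevalence,
  treatment probabilities and the confounder-outcome coefficient are read
  straight off L*;
* ``matrix`` (default): invert the misclassification matrix. The true
  prevalence solves P(L*=1) = sens*pL + (1-spec)*(1-pL); the true joint
  treatment-confounder cells solve the analogous 2x2 system; the
  confounder-outcome coefficient comes from regressing Y on A and the
  Bayes posterior P(L=1 | A, L*) implied by the corrected parameters.
  Requires sens + spec > 1 (better-than-chance classification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bias import bias_conditional, bias_msm
from .estimators import Dataset, fit_conditional, fit_msm_ipw
from .joint import build_joint, confounder_posterior
from .params import MisclassSpec, ScenarioParams

PRIOR_KINDS = ("uniform", "trapezoidal", "triangular")


class PriorError(ValueError):
    pass


class IdentifiabilityError(ValueError):
    """A (sens, spec) draw is inconsistent with the observed data."""


@dataclass(frozen=True)
class SensSpecPrior:
    """Independent prior for sensitivity and specificity on [lower, upper].

    kind:
      * uniform — flat on the interval;
      * trapezoidal — symmetric, flat top between modes at one third and
        two thirds of the interval;
      * triangular — symmetric with mode at the midpoint.
    """

    kind: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in PRIOR_KINDS:
            raise PriorError(f"kind must be one of {PRIOR_KINDS}, got {self.kind!r}")
        if not (0.0 < self.lower <= self.upper <= 1.0):
            raise PriorError(
                f"need 0 < lower <= upper <= 1, got ({self.lower}, {self.upper})"
            )
        if self.lower == self.upper and self.kind != "uniform":
            raise PriorError("degenerate (point-mass) support requires kind='uniform'")

    def distribution(self):
        """The scipy frozen distribution of one marginal."""
        loc, scale = self.lower, self.upper - self.lower
        if self.kind == "uniform":
            return stats.uniform(loc=loc, scale=scale)
        if self.kind == "triangular":
            return stats.triang(c=0.5, loc=loc, scale=scale)
        return stats.trapezoid(c=1.0 / 3.0, d=2.0 / 3.0, loc=loc, scale=scale)


def sample_prior(prior: SensSpecPrior, n_draws: int,
                 seed: int | np.random.Generator) -> np.ndarray:
    """Draw (sens, spec) pairs; the two components are independent.

    Returns an array of shape (n_draws, 2).
    """
    if n_draws < 1:
        raise PriorError("n_draws must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if prior.lower == prior.upper:  # point mass
        return np.full((n_draws, 2), prior.lower)
    dist = prior.distribution()
    return dist.rvs(size=(n_draws, 2), random_state=rng)


def _lambda_from_posterior(data: Dataset, params_wo_lam: dict,
                           mis: MisclassSpec) -> tuple[float, float, float]:
    """Regress Y on (1, A, P(L=1|A,L*)); returns (beta0, beta, lam)."""
    probe = ScenarioParams(lam=0.0, **params_wo_lam)
    joint = build_joint(probe, mis)
    post = np.empty(data.n)
    for a in (0, 1):
        for s in (0, 1):
            mask = (data.A == a) & (data.Lobs == s)
            if mask.any():
                post[mask] = confounder_posterior(joint, a=a, s=s)
    x = np.column_stack([np.ones(data.n), data.A, post])
    coef, *_ = np.linalg.lstsq(x, data.Y, rcond=None)
    resid_sd = float(np.std(data.Y - x @ coef, ddof=3))
    return float(coef[0]), float(coef[1]), float(coef[2]), resid_sd


def estimate_bias_parameters(data: Dataset, sens: float, spec: float,
                             correction: str = "matrix"
                             ) -> tuple[ScenarioParams, MisclassSpec]:
    """Estimate the bias-formula inputs (pL, p0, p1, lam) from the data.

    See the module docstring for the two correction modes.
    """
    if correction not in ("naive", "matrix"):
        raise ValueError(f"correction must be 'naive' or 'matrix', got {correction!r}")
    mis = MisclassSpec(sens=sens, spec=spec)
    p_star = float((data.Lobs == 1).mean())

    if correction == "naive":
        p1_hat = float(data.A[data.Lobs == 1].mean())
        p0_hat = float(data.A[data.Lobs == 0].mean())
        x = np.column_stack([np.ones(data.n), data.A, data.Lobs])
        coef, *_ = np.linalg.lstsq(x, data.Y, rcond=None)
        resid = data.Y - x @ coef
        params = ScenarioParams(
            pL=_checked(p_star, "pL"), p0=_checked(p0_hat, "p0"),
            p1=_checked(p1_hat, "p1"), beta=float(coef[1]), lam=float(coef[2]),
            beta0=float(coef[0]),
            sigma=float(np.std(resid, ddof=3)),
        )
        return params, mis

    denom = sens + spec - 1.0
    if denom <= 0.0:
        raise IdentifiabilityError(
            f"sens + spec = {sens + spec:.3f} <= 1: classification is not "
            "better than chance; the matrix correction is not identifiable"
        )
    p_l = _checked((p_star - (1.0 - spec)) / denom, "pL")

    # True joint treated cells from the observed ones:
    #   P(A=1, L*=1) = sens * u1 + (1-spec) * u0
    #   P(A=1, L*=0) = (1-sens) * u1 + spec * u0
    # with u1 = p1*pL, u0 = p0*(1-pL).
    q11 = float(((data.A == 1) & (data.Lobs == 1)).mean())
    q10 = float(((data.A == 1) & (data.Lobs == 0)).mean())
    mat = np.array([[sens, 1.0 - spec], [1.0 - sens, spec]])
    u1, u0 = np.linalg.solve(mat, np.array([q11, q10]))
    p1_hat = _checked(float(u1) / p_l, "p1")
    p0_hat = _checked(float(u0) / (1.0 - p_l), "p0")

    base = {"pL": p_l, "p0": p0_hat, "p1": p1_hat}
    b0, beta_hat, lam_hat, resid_sd = _lambda_from_posterior(data, base, mis)
    params = ScenarioParams(**base, beta=beta_hat, lam=lam_hat, beta0=b0,
                            sigma=resid_sd)
    return params, mis


def _checked(value: float, name: str) -> float:
    if not 0.0 < value < 1.0:
        raise IdentifiabilityError(
            f"corrected {name} = {value:.4f} falls outside (0, 1): the "
            "(sens, spec) draw is inconsistent with the data"
        )
    return value


@dataclass(frozen=True)
class QbaResult:
    draws: np.ndarray                   # (n_ok, 2) accepted (sens, spec) pairs
    bias_draws_msm: np.ndarray
    bias_draws_conditional: np.ndarray
    fitted_msm: float
    fitted_conditional: float
    adjusted_msm: np.ndarray            # fitted - bias draw
    adjusted_conditional: np.ndarray
    n_failed_draws: int
    failed_draw_indices: tuple[int, ...]
    correction: str

    def summary(self) -> dict:
        out = {}
        for method, arr in (("msm_ipw", self.bias_draws_msm),
                            ("conditional", self.bias_draws_conditional)):
            q1, med, q3 = np.percentile(arr, [25, 50, 75])  # type-7 interpolation
            out[method] = {
                "mean": float(arr.mean()),
                "median": float(med),
                "iqr": (float(q1), float(q3)),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "correction": self.correction,
            "n_draws": int(self.bias_draws_msm.size),
            "n_failed_draws": self.n_failed_draws,
            "fitted": {"msm_ipw": self.fitted_msm,
                       "conditional": self.fitted_conditional},
            "bias_summary": self.summary(),
            "adjusted_summary": {
                "msm_ipw": _describe(self.adjusted_msm),
                "conditional": _describe(self.adjusted_conditional),
            },
        }


def _describe(arr: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"mean": float(arr.mean()), "median": float(med),
            "iqr": (float(q1), float(q3))}


def run_qba(data: Dataset, prior: SensSpecPrior, n_draws: int, seed: int,
            correction: str = "matrix",
            max_failure_frac: float = 0.05) -> QbaResult:
    """Propagate prior uncertainty in (sens, spec) to a bias distribution.

    For each prior draw, the bias-formula inputs are re-estimated from the
    data under that draw and both closed-form biases evaluated. Draws whose
    implied parameters are inconsistent with the data (matrix correction
    outside the unit interval) are recorded and skipped; the run aborts if
    more than `max_failure_frac` of draws fail.
    """
    pairs = sample_prior(prior, n_draws, seed)
    ok_pairs, b_msm, b_cm, failed = [], [], [], []
    for i, (sens, spec) in enumerate(pairs):
        try:
            params, mis = estimate_bias_parameters(data, float(sens), float(spec),
                                                   correction)
            b_msm.append(bias_msm(params, mis))
            b_cm.append(bias_conditional(params, mis))
            ok_pairs.append((float(sens), float(spec)))
        except IdentifiabilityError:
            failed.append(i)
    if len(failed) > max_failure_frac * n_draws:
        raise IdentifiabilityError(
            f"{len(failed)}/{n_draws} prior draws inconsistent with the data "
            f"(first failures at indices {failed[:5]})"
        )
    fit_m = fit_msm_ipw(data).estimate
    fit_c = fit_conditional(data).estimate
    b_msm_arr = np.array(b_msm)
    b_cm_arr = np.array(b_cm)
    return QbaResult(
        draws=np.array(ok_pairs),
        bias_draws_msm=b_msm_arr,
        bias_draws_conditional=b_cm_arr,
        fitted_msm=fit_m,
        fitted_conditional=fit_c,
        adjusted_msm=fit_m - b_msm_arr,
        adjusted_conditional=fit_c - b_cm_arr,
        n_failed_draws=len(failed),
        failed_draw_indices=tuple(failed),
        correction=correction,
    )
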