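"""Monte Carlo simulation study of the two ATE estimators.

Data are generated from the Bernoulli-confounder / linear-Gaussian-outcome
law described in `params`, under one of two assignment modes:

* ``setting2`` (default): treatment depends on the true confounder L, and
  only the misclassified surrogate L* is available at analysis time —
  adjusting for L* leaves residual confounding;
* ``setting1``: treatment depends on the surrogate L* itself, so
  conditioning on L* blocks the backdoor path and both estimators are
  unbiased despite the classification error.

Each replicate is generated from an independent RNG stream keyed by
(seed, rep_index), so results are independent of execution order and
bit-for-bit reproducible. Performance measures (bias, MSE, coverage,
empirical SE, mean model SE) follow standard simulation-study practice,
each with its Monte Carlo standard error.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bias import bias_conditional, bias_msm
from .estimators import Z95, Dataset, EmptyCellError, fit_conditional, fit_msm_ipw
from .params import MisclassSpec, ScenarioParams

SETTING_TREATMENT_ON_TRUE = "setting2"
SETTING_TREATMENT_ON_SURROGATE = "setting1"


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationDesign:
    params: ScenarioParams
    mis: MisclassSpec
    n_obs: int
    n_reps: int
    seed: int
    mode: str = SETTING_TREATMENT_ON_TRUE

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (Monte Carlo SEs undefined)")
        if self.n_obs < 4:
            raise ValueError("n_obs must be >= 4")
        if self.mode not in (SETTING_TREATMENT_ON_TRUE,
                             SETTING_TREATMENT_ON_SURROGATE):
            raise ValueError(f"unknown mode {self.mode!r}")


def generate_dataset(design: SimulationDesign, rep_index: int) -> Dataset:
    """Draw one replicate dataset from the design's data-generating law."""
    rng = np.random.default_rng([design.seed, rep_index])
    p = design.params
    m = design.mis
    n = design.n_obs

    ltrue = (rng.random(n) < p.pL).astype(np.int64)
    flip_to = np.where(ltrue == 1, m.sens, 1.0 - m.spec)  # P(L*=1 | L)
    lobs = (rng.random(n) < flip_to).astype(np.int64)
    basis = lobs if design.mode == SETTING_TREATMENT_ON_SURROGATE else ltrue
    p_treat = np.where(basis == 1, p.p1, p.p0)
    a = (rng.random(n) < p_treat).astype(np.int64)
    y = p.beta0 + p.beta * a + p.lam * ltrue + p.sigma * rng.standard_normal(n)
    return Dataset(A=a, Lobs=lobs, Y=y, Ltrue=ltrue)


@dataclass(frozen=True)
class PerformanceMeasures:
    """Performance of one estimator over the replicates, with MC standard errors."""

    bias: float
    bias_mcse: float
    mse: float
    mse_mcse: float
    coverage: float
    coverage_mcse: float
    emp_se: float
    emp_se_mcse: float
    model_se: float
    model_se_mcse: float
    n_reps: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "bias", "bias_mcse", "mse", "mse_mcse", "coverage",
            "coverage_mcse", "emp_se", "emp_se_mcse", "model_se",
            "model_se_mcse", "n_reps")}


def performance_measures(estimates: np.ndarray, ses: np.ndarray,
                         true_beta: float) -> PerformanceMeasures:
    """Aggregate replicate-level estimates/SEs into performance measures.

    Coverage counts normal-based 95% intervals (estimate +/- 1.96 se) that
    contain the true effect. MCSE formulas are the standard ones for
    simulation studies: bias -> empSE/sqrt(R); empSE -> empSE/sqrt(2(R-1));
    coverage -> sqrt(c(1-c)/R); MSE -> SD(squared errors)/sqrt(R);
    model SE -> SD(SEs)/sqrt(R).
    """
    estimates = np.asarray(estimates, dtype=np.float64)
    ses = np.asarray(ses, dtype=np.float64)
    if estimates.size != ses.size or estimates.size == 0:
        raise ValueError("estimates and ses must be non-empty, equal-length")
    r = estimates.size
    if r < 2:
        raise ValueError("need at least 2 replicates for Monte Carlo SEs")

    err = estimates - true_beta
    emp_se = float(np.std(estimates, ddof=1))
    sq_err = err ** 2
    covered = np.abs(err) <= Z95 * ses
    cov = float(covered.mean())
    return PerformanceMeasures(
        bias=float(err.mean()),
        bias_mcse=emp_se / np.sqrt(r),
        mse=float(sq_err.mean()),
        mse_mcse=float(np.std(sq_err, ddof=1)) / np.sqrt(r),
        coverage=cov,
        coverage_mcse=float(np.sqrt(cov * (1.0 - cov) / r)),
        emp_se=emp_se,
        emp_se_mcse=emp_se / np.sqrt(2.0 * (r - 1)),
        model_se=float(ses.mean()),
        model_se_mcse=float(np.std(ses, ddof=1)) / np.sqrt(r),
        n_reps=r,
    )


@dataclass(frozen=True)
class SimulationSummary:
    design: SimulationDesign
    msm_ipw: PerformanceMeasures
    conditional: PerformanceMeasures
    theoretical_bias_msm: float
    theoretical_bias_conditional: float
    n_failed_reps: int = 0
    failed_rep_indices: tuple[int, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (method, measure)."""
        rows = []
        for method, perf in (("msm_ipw", self.msm_ipw),
                             ("conditional", self.conditional)):
            d = perf.to_dict()
            for measure in ("bias", "mse", "coverage", "emp_se", "model_se"):
                rows.append({
                    "method": method,
                    "sample_size": self.design.n_obs,
                    "measure": measure,
                    "value": d[measure],
                    "mcse": d[f"{measure}_mcse"],
                })
            rows.append({
                "method": method,
                "sample_size": self.design.n_obs,
                "measure": "theoretical_bias",
                "value": (self.theoretical_bias_msm if method == "msm_ipw"
                          else self.theoretical_bias_conditional),
                "mcse": 0.0,
            })
        return pd.DataFrame(rows)


def run_simulation(design: SimulationDesign,
                   max_failure_frac: float = 0.01) -> SimulationSummary:
    """Run the full generate -> fit(conditional) -> fit(MSM-IPW) loop.

    Replicates where an estimator fails (an empty (A, L*) cell, which can
    happen at small n) are excluded and counted; the run aborts if more
    than `max_failure_frac` of replicates fail.
    """
    est_c, se_c, est_m, se_m = [], [], [], []
    failed: list[int] = []
    for rep in range(design.n_reps):
        data = generate_dataset(design, rep)
        try:
            res_m = fit_msm_ipw(data)
            res_c = fit_conditional(data)
        except EmptyCellError:
            failed.append(rep)
            continue
        est_m.append(res_m.estimate)
        se_m.append(res_m.se)
        est_c.append(res_c.estimate)
        se_c.append(res_c.se)

    if len(failed) > max_failure_frac * design.n_reps:
        raise SimulationError(
            f"{len(failed)}/{design.n_reps} replicates failed "
            f"(> {max_failure_frac:.0%}); design is too degenerate"
        )

    beta = design.params.beta
    return SimulationSummary(
        design=design,
        msm_ipw=performance_measures(np.array(est_m), np.array(se_m), beta),
        conditional=performance_measures(np.array(est_c), np.array(se_c), beta),
        theoretical_bias_msm=bias_msm(design.params, design.mis),
        theoretical_bias_conditional=bias_conditional(design.params, design.mis),
        n_failed_reps=len(failed),
        failed_rep_indices=tuple(failed),
    )


# ---------------------------------------------------------------------------
# packaged scenario files
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("scenario0", "scenario1", "scenario2", "scenario3", "scenario4")


def load_scenario(source: str | Path) -> tuple[ScenarioParams, MisclassSpec]:
    """Load a scenario from a packaged name (e.g. 'scenario1') or a YAML path.

    YAML keys mirror the parameter field names:
    pL, p0, p1, beta, lam, beta0, sigma, sens, spec.
    """
    name = str(source)
    if name in SCENARIO_NAMES:
        ref = importlib.resources.files("confbias.scenarios") / f"{name}.yaml"
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    mis = MisclassSpec(sens=float(raw.pop("sens")), spec=float(raw.pop("spec")))
    raw.pop("name", None)
    params = ScenarioParams(**{k: float(v) for k, v in raw.items()})
    return params, mis
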