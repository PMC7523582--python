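"""Finite-sample estimators of the average treatment effect.

Two estimators, both using the observed (possibly misclassified) surrogate
confounder:

* conditional regression — OLS of Y on (1, A, L*) with the classical
  model-based SE of the treatment coefficient;
* MSM-IPW — each subject weighted by the inverse of the empirical
  probability of their observed treatment within their L* stratum
  (a saturated propensity model), followed by weighted least squares of Y
  on (1, A) with an HC0 robust sandwich SE that treats the weights as
  known. Not accounting for weight estimation makes the SE conservative,
  which is the commonly used MSM-IPW procedure this package studies.

Both report normal-based 95% confidence intervals (z = 1.96). Degenerate
inputs (missing treatment arm, empty (A, L*) cell, collinear design) fail
loudly with a named error rather than silently dropping rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


class DatasetError(ValueError):
    """The dataset violates a structural invariant."""


class RankDeficientError(ValueError):
    """The regression design matrix is collinear."""


class EmptyCellError(ValueError):
    """An (A, L*) cell is empty: in-sample positivity fails."""


@dataclass(frozen=True)
class Dataset:
    """Subject-level data: treatment A, surrogate confounder Lobs, outcome Y.

    `Ltrue` (the error-free confounder) is optional and only available for
    synthetic data; the estimators never touch it.
    """

    A: np.ndarray
    Lobs: np.ndarray
    Y: np.ndarray
    Ltrue: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.Y)
        if len(self.A) != n or len(self.Lobs) != n:
            raise DatasetError("columns have unequal lengths")
        if self.Ltrue is not None and len(self.Ltrue) != n:
            raise DatasetError("columns have unequal lengths")
        if n < 4:
            raise DatasetError(f"need at least 4 rows, got {n}")
        for name, col in (("A", self.A), ("Lobs", self.Lobs)):
            vals = np.unique(col)
            if not np.isin(vals, (0, 1)).all():
                raise DatasetError(f"{name} must be coded 0/1")
        if len(np.unique(self.A)) < 2:
            raise DatasetError("both treatment arms must be present")
        if len(np.unique(self.Lobs)) < 2:
            raise DatasetError("both surrogate-confounder strata must be present")

    @property
    def n(self) -> int:
        return len(self.Y)

    # -- CSV round trip (columns A, Lstar, Y[, L]) --------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        df = pd.read_csv(path)
        missing = {"A", "Lstar", "Y"} - set(df.columns)
        if missing:
            raise DatasetError(f"CSV is missing columns: {sorted(missing)}")
        ltrue = df["L"].to_numpy(dtype=np.int64) if "L" in df.columns else None
        return cls(
            A=df["A"].to_numpy(dtype=np.int64),
            Lobs=df["Lstar"].to_numpy(dtype=np.int64),
            Y=df["Y"].to_numpy(dtype=np.float64),
            Ltrue=ltrue,
        )

    def to_csv(self, path: str | Path) -> None:
        cols = {"A": self.A, "Lstar": self.Lobs, "Y": self.Y}
        if self.Ltrue is not None:
            cols["L"] = self.Ltrue
        pd.DataFrame(cols).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        cols = {"A": self.A, "Lstar": self.Lobs, "Y": self.Y}
        if self.Ltrue is not None:
            cols["L"] = self.Ltrue
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class EstimateResult:
    """Point estimate of the ATE with its standard error and 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str               # "conditional" | "msm_ipw"
    se_kind: str              # "model_based" | "robust_sandwich"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "se_kind": self.se_kind,
        }


def _result(estimate: float, se: float, method: str, se_kind: str) -> EstimateResult:
    return EstimateResult(
        estimate=estimate, se=se,
        ci_low=estimate - Z95 * se, ci_high=estimate + Z95 * se,
        method=method, se_kind=se_kind,
    )


def fit_conditional(data: Dataset) -> EstimateResult:
    """OLS of Y on (1, A, Lobs), classical SE for the treatment coefficient."""
    n = data.n
    x = np.column_stack([np.ones(n), data.A, data.Lobs]).astype(np.float64)
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx, tol=1e-10) < 3:
        raise RankDeficientError(
            "design (1, A, Lstar) is collinear; A and Lstar coincide or a "
            "column is constant"
        )
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (x.T @ data.Y)
    resid = data.Y - x @ coef
    sigma2 = float(resid @ resid) / (n - 3)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return _result(float(coef[1]), se, "conditional", "model_based")


def ipw_weights(data: Dataset) -> np.ndarray:
    """Unstabilized inverse-probability-of-treatment weights.

    The propensity P(A=1 | Lobs=s) is the empirical treated fraction within
    each surrogate stratum (a saturated model — identical to fitting a
    logistic regression of A on Lobs). Requires every (A, Lobs) cell to be
    nonempty, which also bounds the weights.
    """
    w = np.empty(data.n, dtype=np.float64)
    for s in (0, 1):
        stratum = data.Lobs == s
        n_s = int(stratum.sum())
        n_treated = int(data.A[stratum].sum())
        if n_treated == 0 or n_treated == n_s:
            raise EmptyCellError(
                f"empty (A, Lstar) cell in stratum Lstar={s}: "
                f"{n_treated}/{n_s} treated"
            )
        p_hat = n_treated / n_s
        w[stratum] = np.where(data.A[stratum] == 1, 1.0 / p_hat,
                              1.0 / (1.0 - p_hat))
    return w


def fit_msm_ipw(data: Dataset) -> EstimateResult:
    """MSM-IPW: weighted least squares of Y on (1, A), HC0 sandwich SE.

    Weights are treated as fixed, so the SE is conservative for the ATE.
    """
    w = ipw_weights(data)
    a = data.A.astype(np.float64)
    y = data.Y

    # WLS normal equations for X = (1, A); exploit A^2 = A.
    sw = float(w.sum())
    swa = float((w * a).sum())
    swy = float((w * y).sum())
    sway = float((w * a * y).sum())
    det = sw * swa - swa * swa
    if det <= 0.0:
        raise RankDeficientError("weighted design (1, A) is degenerate")
    b0 = (swa * swy - swa * sway) / det
    b1 = (sw * sway - swa * swy) / det

    # HC0 sandwich: (X'WX)^-1 X'W diag(e^2) WX (X'WX)^-1, weights fixed.
    e2 = (y - b0 - b1 * a) ** 2
    m11 = float((w * w * e2).sum())
    m12 = float((w * w * e2 * a).sum())
    bread = np.array([[swa, -swa], [-swa, sw]]) / det  # (X'WX)^-1
    meat = np.array([[m11, m12], [m12, m12]])
    cov = bread @ meat @ bread
    se = float(np.sqrt(cov[1, 1]))
    return _result(b1, se, "msm_ipw", "robust_sandwich")
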