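"""Closed-form asymptotic bias of the ATE under confounder misclassification.

Both estimators replace the true confounder L by the surrogate L* when
treatment was in fact assigned on L. Because the outcome is linear,
Y = beta0 + beta*A + lam*L + eps, every large-sample bias is lam times a
purely distributional quantity:

* MSM-IPW (weights 1/P(A|L*)): the weighted fit standardizes over L*, so
  the probability limit of the treatment coefficient is
  sum_s P(L*=s) [E(Y|A=1,L*=s) - E(Y|A=0,L*=s)], and the bias is

      lam * sum_s P(L*=s) [P(L=1|A=1,L*=s) - P(L=1|A=0,L*=s)].

* Conditional regression of Y on (1, A, L*): the treatment coefficient
  converges to beta + lam * alpha_A, where alpha_A is the A-coefficient of
  the population least-squares projection of L onto (1, A, L*). The true
  regression E[L|A,L*] contains an A-by-L* interaction that the
  main-effects fit omits, which is where the residual bias comes from.

Each bias ships in two independently coded routes: a direct algebraic form
(this module's `bias_msm` / `bias_conditional`, using only scalar parameter
arithmetic) and a brute-force oracle assembled from the eight-cell joint
table (`bias_msm_oracle` / `bias_conditional_oracle`). Tests hold the two
routes to 1e-10 of each other across the parameter space; the oracle is the
arbiter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .joint import (
    DegenerateDistributionError,
    build_joint,
    confounder_posterior,
    propensity_observed,
)
from .params import MisclassSpec, ScenarioParams


class PositivityError(ValueError):
    """An observed-propensity stratum has probability 0 or 1."""


class CollinearDesignError(ValueError):
    """The population design matrix (1, A, L*) is rank deficient."""


# ---------------------------------------------------------------------------
# population moments, written directly in the parameters
# ---------------------------------------------------------------------------

def _moments(params: ScenarioParams, mis: MisclassSpec) -> dict[str, float]:
    """First and second moments of (A, L*, L); binary so squares collapse."""
    p, p0, p1 = params.pL, params.p0, params.p1
    s1 = mis.sens            # P(L*=1 | L=1)
    s0 = 1.0 - mis.spec      # P(L*=1 | L=0)
    return {
        "EA": p * p1 + (1 - p) * p0,
        "ES": p * s1 + (1 - p) * s0,
        "EL": p,
        "EAS": p * p1 * s1 + (1 - p) * p0 * s0,
        "EAL": p * p1,
        "ELS": p * s1,
    }


def _check_observed_positivity(params: ScenarioParams, mis: MisclassSpec) -> None:
    p, p0, p1 = params.pL, params.p0, params.p1
    s1, s0 = mis.sens, 1.0 - mis.spec
    for s, q1, q0 in ((1, s1, s0), (0, 1.0 - s1, 1.0 - s0)):
        ps = p * q1 + (1 - p) * q0        # P(L*=s)
        if ps <= 0.0:
            raise DegenerateDistributionError(
                f"P(L*={s}) = 0: surrogate distribution is degenerate"
            )
        pi = (p * p1 * q1 + (1 - p) * p0 * q0) / ps
        if pi <= 0.0 or pi >= 1.0:
            raise PositivityError(
                f"P(A=1 | L*={s}) = {pi}: inverse-probability weights diverge"
            )


# ---------------------------------------------------------------------------
# direct algebraic forms
# ---------------------------------------------------------------------------

def bias_msm(params: ScenarioParams, mis: MisclassSpec) -> float:
    """Asymptotic bias of the ATE from an MSM-IPW weighted on the surrogate.

    lam * sum_s P(L*=s) [P(L=1|A=1,L*=s) - P(L=1|A=0,L*=s)], with the
    posteriors expanded by Bayes' rule in the raw parameters.
    """
    _check_observed_positivity(params, mis)
    p, p0, p1 = params.pL, params.p0, params.p1
    s1, s0 = mis.sens, 1.0 - mis.spec

    total = 0.0
    for q1, q0 in ((s1, s0), (1.0 - s1, 1.0 - s0)):   # s = 1 then s = 0
        ps = p * q1 + (1 - p) * q0
        m1 = p * p1 * q1 / (p * p1 * q1 + (1 - p) * p0 * q0)
        m0 = (p * (1 - p1) * q1
              / (p * (1 - p1) * q1 + (1 - p) * (1 - p0) * q0))
        total += ps * (m1 - m0)
    return params.lam * total


def bias_conditional(params: ScenarioParams, mis: MisclassSpec) -> float:
    """Asymptotic bias of the A-coefficient when Y is regressed on (1, A, L*).

    lam times the A-coefficient of the population projection of L onto
    (1, A, L*), solved in closed form via Cramer's rule on the 3x3 normal
    equations.
    """
    m = _moments(params, mis)
    ea, es, el = m["EA"], m["ES"], m["EL"]
    eas, eal, els = m["EAS"], m["EAL"], m["ELS"]

    # Gram matrix of (1, A, L*); A^2 = A and L*^2 = L* for indicators.
    g11, g12, g13 = 1.0, ea, es
    g22, g23, g33 = ea, eas, es
    det = (g11 * (g22 * g33 - g23 * g23)
           - g12 * (g12 * g33 - g23 * g13)
           + g13 * (g12 * g23 - g22 * g13))
    if abs(det) < 1e-14:
        raise CollinearDesignError(
            "population design (1, A, L*) is collinear "
            f"(E[A]={ea}, E[L*]={es}, E[AL*]={eas})"
        )
    # Cramer's rule: replace the A-column of the Gram matrix with the
    # moment vector (E[L], E[AL], E[L L*]).
    det_a = (g11 * (eal * g33 - g23 * els)
             - el * (g12 * g33 - g23 * g13)
             + g13 * (g12 * els - eal * g13))
    return params.lam * det_a / det


# ---------------------------------------------------------------------------
# brute-force oracles via the joint table
# ---------------------------------------------------------------------------

def bias_msm_oracle(params: ScenarioParams, mis: MisclassSpec) -> float:
    """Standardization-over-L* bias computed from joint-table operations only."""
    joint = build_joint(params, mis)
    pi0, pi1 = propensity_observed(joint)
    for s, pi in ((0, pi0), (1, pi1)):
        if pi <= 0.0 or pi >= 1.0:
            raise PositivityError(f"P(A=1 | L*={s}) = {pi}")
    total = 0.0
    for s in (0, 1):
        ps = joint.prob(s=s)
        total += ps * (confounder_posterior(joint, a=1, s=s)
                       - confounder_posterior(joint, a=0, s=s))
    return params.lam * total


def bias_conditional_oracle(params: ScenarioParams, mis: MisclassSpec) -> float:
    """Population least-squares projection of L onto (1, A, L*), numerically.

    Second moments are accumulated by brute-force summation over the eight
    joint cells and the normal equations solved with numpy — no shared
    algebra with `bias_conditional`.
    """
    joint = build_joint(params, mis)
    ea = joint.expectation(lambda l, a, s: a)
    es = joint.expectation(lambda l, a, s: s)
    eas = joint.expectation(lambda l, a, s: a * s)
    gram = np.array([[1.0, ea, es], [ea, ea, eas], [es, eas, es]])
    rhs = np.array([
        joint.expectation(lambda l, a, s: l),
        joint.expectation(lambda l, a, s: l * a),
        joint.expectation(lambda l, a, s: l * s),
    ])
    if np.linalg.matrix_rank(gram, tol=1e-12) < 3:
        raise CollinearDesignError("singular population normal equations")
    coeffs = np.linalg.solve(gram, rhs)
    return params.lam * float(coeffs[1])


# ---------------------------------------------------------------------------
# diagnostics and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionalBiasTerms:
    """Diagnostic decomposition of the conditional-model bias.

    alpha_a, alpha_s, alpha_0 are the coefficients of the population
    projection of L onto (A, L*, 1); the conditional bias equals
    lam * alpha_a. curly_factor is the ratio of the conditional bias to the
    MSM-IPW bias — the multiplier that separates the two closed forms.
    It equals 1 exactly when the two methods are equally biased; it is NaN
    when the MSM-IPW bias is zero.
    """

    alpha_a: float
    alpha_s: float
    alpha_0: float
    curly_factor: float


def conditional_bias_terms(params: ScenarioParams,
                           mis: MisclassSpec) -> ConditionalBiasTerms:
    joint = build_joint(params, mis)
    ea = joint.expectation(lambda l, a, s: a)
    es = joint.expectation(lambda l, a, s: s)
    eas = joint.expectation(lambda l, a, s: a * s)
    gram = np.array([[1.0, ea, es], [ea, ea, eas], [es, eas, es]])
    rhs = np.array([
        joint.expectation(lambda l, a, s: l),
        joint.expectation(lambda l, a, s: l * a),
        joint.expectation(lambda l, a, s: l * s),
    ])
    a0, aa, asld = np.linalg.solve(gram, rhs)
    b_msm = bias_msm(params, mis)
    # ratio is undefined (NaN) when the MSM bias is numerically null
    curly = params.lam * aa / b_msm if abs(b_msm) >= 1e-12 else float("nan")
    return ConditionalBiasTerms(alpha_a=float(aa), alpha_s=float(asld),
                                alpha_0=float(a0), curly_factor=curly)


class BiasCategory(str, Enum):
    NULL = "null"
    EQUAL = "equal"
    MSM_SMALLER = "msm_smaller"
    CM_SMALLER = "cm_smaller"


@dataclass(frozen=True)
class BiasClassification:
    category: BiasCategory
    sign: int                 # sign shared by the two biases; 0 if both null
    bias_msm: float
    bias_conditional: float


def classify_bias(params: ScenarioParams, mis: MisclassSpec,
                  tol: float = 1e-10) -> BiasClassification:
    """Evaluate both biases and report null / equal / relative magnitude.

    `tol` is the numerical threshold for calling a bias zero or the two
    biases equal; raise it to the data's printed precision when comparing
    against rounded tables.
    """
    b_m = bias_msm(params, mis)
    b_c = bias_conditional(params, mis)
    if abs(b_m) < tol and abs(b_c) < tol:
        category = BiasCategory.NULL
        sign = 0
    elif abs(b_m - b_c) < tol:
        category = BiasCategory.EQUAL
        sign = int(np.sign(b_m))
    elif abs(b_m) < abs(b_c):
        category = BiasCategory.MSM_SMALLER
        sign = int(np.sign(b_c))
    else:
        category = BiasCategory.CM_SMALLER
        sign = int(np.sign(b_m))
    return BiasClassification(category=category, sign=sign,
                              bias_msm=b_m, bias_conditional=b_c)
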