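"""Parameter types for the confounded point-treatment model.

The data-generating law is:

    L  ~ Bernoulli(pL)                      (dichotomous confounder)
    A | L=l ~ Bernoulli(p_l)                (treatment, l in {0, 1})
    Y = beta0 + beta * A + lam * L + sigma * eps,  eps ~ N(0, 1)

and the surrogate confounder L* is a nondifferentially misclassified copy
of L with sensitivity P(L*=1 | L=1) and specificity P(L*=0 | L=0); the
classification error does not depend on A or Y given L.
"""

from __future__ import annotations

from dataclasses import dataclass


class ParameterError(ValueError):
    """A parameter violates its admissible range."""


def _check_prob_open(value: float, name: str) -> None:
    if not 0.0 < value < 1.0:
        raise ParameterError(f"{name} must lie strictly in (0, 1), got {value!r}")


def _check_prob_closed(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ScenarioParams:
    """True data-generating parameters.

    Parameters
    ----------
    pL : float
        Prevalence of the confounder, P(L=1). Must be strictly inside
        (0, 1): populations where the confounder is present or absent in
        everyone are excluded.
    p0, p1 : float
        Treatment probabilities P(A=1 | L=0) and P(A=1 | L=1); strictly
        inside (0, 1) (positivity).
    beta : float
        Average treatment effect on the outcome scale (the estimand).
    lam : float
        Confounder-outcome coefficient (the strength of confounding on the
        outcome side).
    beta0 : float
        Outcome intercept. Default 0.
    sigma : float
        Residual standard deviation of the outcome. Default 1.
    """

    pL: float
    p0: float
    p1: float
    beta: float = 1.0
    lam: float = 2.0
    beta0: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        _check_prob_open(self.pL, "pL")
        _check_prob_open(self.p0, "p0")
        _check_prob_open(self.p1, "p1")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be nonnegative, got {self.sigma!r}")

    def treatment_prob(self, l: int) -> float:
        """P(A=1 | L=l)."""
        return self.p1 if l == 1 else self.p0


@dataclass(frozen=True)
class MisclassSpec:
    """Classification accuracy of the surrogate confounder L*.

    sens = P(L*=1 | L=1), spec = P(L*=0 | L=0). Misclassification is
    nondifferential by construction: neither depends on treatment or
    outcome.
    """

    sens: float
    spec: float

    def __post_init__(self) -> None:
        _check_prob_closed(self.sens, "sens")
        _check_prob_closed(self.spec, "spec")

    @property
    def is_perfect(self) -> bool:
        return self.sens == 1.0 and self.spec == 1.0

    def surrogate_prob(self, l: int, s: int) -> float:
        """P(L*=s | L=l)."""
        if l == 1:
            return self.sens if s == 1 else 1.0 - self.sens
        return 1.0 - self.spec if s == 1 else self.spec


PERFECT_CLASSIFICATION = MisclassSpec(sens=1.0, spec=1.0)
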