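"""Exact discrete joint distribution of (L, A, L*).

The eight-cell table P(L=l, A=a, L*=s) = P(L=l) P(A=a|L=l) P(L*=s|L=l)
encodes the point-treatment factorization in which treatment is initiated
on the true confounder L and the surrogate L* is conditionally independent
of (A, Y) given L. It is the backbone for every closed-form identity in
the package: marginals, observed propensities and Bayes posteriors are all
finite sums over these cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .params import MisclassSpec, ScenarioParams

Cell = tuple[int, int, int]  # (l, a, s)


class DegenerateDistributionError(ValueError):
    """A required conditioning event has zero probability."""


@dataclass(frozen=True)
class JointTable:
    """Joint probability table of (true confounder L, treatment A, surrogate L*)."""

    cells: dict[Cell, float] = field(repr=False)

    def __post_init__(self) -> None:
        total = sum(self.cells.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cells must sum to 1, got {total!r}")
        for key, value in self.cells.items():
            if value < 0:
                raise ValueError(f"negative probability {value!r} at cell {key}")

    def prob(self, l: int | None = None, a: int | None = None,
             s: int | None = None) -> float:
        """Marginal/joint probability with unspecified coordinates summed out."""
        return sum(
            p for (cl, ca, cs), p in self.cells.items()
            if (l is None or cl == l)
            and (a is None or ca == a)
            and (s is None or cs == s)
        )

    def expectation(self, f) -> float:
        """E[f(L, A, L*)] by direct summation over the eight cells."""
        return sum(p * f(l, a, s) for (l, a, s), p in self.cells.items())


def build_joint(params: ScenarioParams, mis: MisclassSpec) -> JointTable:
    """Construct the joint law of (L, A, L*) under treatment-on-L assignment.

    cell(l, a, s) = pL^l (1-pL)^(1-l) * p_l^a (1-p_l)^(1-a)
                    * P(L*=s | L=l)
    """
    cells: dict[Cell, float] = {}
    for l, a, s in itertools.product((0, 1), repeat=3):
        pl = params.pL if l == 1 else 1.0 - params.pL
        pa = params.treatment_prob(l)
        cells[(l, a, s)] = pl * (pa if a == 1 else 1.0 - pa) * mis.surrogate_prob(l, s)
    return JointTable(cells=cells)


def propensity_observed(joint: JointTable) -> tuple[float, float]:
    """Observed-data propensities (P(A=1|L*=0), P(A=1|L*=1)).

    These are the weights' denominators in the misclassified MSM-IPW fit.
    """
    out = []
    for s in (0, 1):
        ps = joint.prob(s=s)
        if ps <= 0.0:
            raise DegenerateDistributionError(
                f"P(L*={s}) = 0: surrogate distribution is degenerate"
            )
        out.append(joint.prob(a=1, s=s) / ps)
    return out[0], out[1]


def confounder_posterior(joint: JointTable, a: int, s: int) -> float:
    """Bayes posterior P(L=1 | A=a, L*=s)."""
    denom = joint.prob(a=a, s=s)
    if denom <= 0.0:
        raise DegenerateDistributionError(
            f"P(A={a}, L*={s}) = 0: cannot condition on an empty cell"
        )
    return joint.prob(l=1, a=a, s=s) / denom
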