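"""Deterministic bias grids: how the two biases move with one parameter.

Evaluates the closed-form biases along a grid over the treatment
probability in the confounded group (p1), the confounder prevalence (pL),
or a two-dimensional (sens, spec) grid, holding everything else fixed.
The output is a tidy table; rendering is left to the caller (or the thin
`plot_surface` helper, which needs matplotlib).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bias import PositivityError, bias_conditional, bias_msm
from .joint import DegenerateDistributionError
from .params import MisclassSpec, ScenarioParams

VARY_CHOICES = ("p1", "pL", "sens_spec_grid")


def default_grid(n: int = 101) -> np.ndarray:
    """Evenly spaced probability grid clipped to [0.01, 0.99]."""
    return np.linspace(0.01, 0.99, n)


@dataclass(frozen=True)
class SurfaceSpec:
    vary: str
    params: ScenarioParams
    mis: MisclassSpec
    grid: Sequence = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.vary not in VARY_CHOICES:
            raise ValueError(f"vary must be one of {VARY_CHOICES}")
        pts = np.asarray(self.grid, dtype=float)
        if self.vary == "sens_spec_grid":
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError("sens_spec_grid expects (n, 2) points")
        else:
            if pts.ndim != 1:
                raise ValueError("one-dimensional grid expected")
            if not np.all(np.diff(pts) > 0):
                raise ValueError("grid must be strictly increasing")
            if np.any(pts <= 0) or np.any(pts >= 1):
                raise ValueError("probability grid must lie in (0, 1)")


def compute_surface(spec: SurfaceSpec) -> pd.DataFrame:
    """Evaluate both biases at every grid point.

    Returns a DataFrame with the grid coordinate(s), bias_msm, bias_cm and
    an `error` column; points where positivity fails are marked rather than
    aborting the whole surface.
    """
    rows = []
    for point in np.asarray(spec.grid, dtype=float):
        if spec.vary == "p1":
            params = replace(spec.params, p1=float(point))
            mis = spec.mis
            coords = {"p1": float(point)}
        elif spec.vary == "pL":
            params = replace(spec.params, pL=float(point))
            mis = spec.mis
            coords = {"pL": float(point)}
        else:
            sens, specificity = float(point[0]), float(point[1])
            params = spec.params
            mis = MisclassSpec(sens=sens, spec=specificity)
            coords = {"sens": sens, "spec": specificity}
        try:
            row = {**coords,
                   "bias_msm": bias_msm(params, mis),
                   "bias_cm": bias_conditional(params, mis),
                   "error": None}
        except (PositivityError, DegenerateDistributionError) as exc:
            row = {**coords, "bias_msm": np.nan, "bias_cm": np.nan,
                   "error": str(exc)}
        rows.append(row)
    return pd.DataFrame(rows)


def sens_spec_grid(sens_values: Sequence[float],
                   spec_values: Sequence[float]) -> np.ndarray:
    """Cartesian product of sensitivity and specificity values, (n, 2)."""
    ss, pp = np.meshgrid(np.asarray(sens_values), np.asarray(spec_values),
                         indexing="ij")
    return np.column_stack([ss.ravel(), pp.ravel()])


def plot_surface(table: pd.DataFrame, path: str) -> None:
    """Line plot of a one-dimensional bias surface (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axis = next(c for c in ("p1", "pL", "sens") if c in table.columns)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table[axis], table["bias_msm"], label="MSM-IPW")
    ax.plot(table[axis], table["bias_cm"], label="conditional", linestyle="--")
    ax.axhline(0.0, color="grey", linewidth=0.5)
    ax.set_xlabel(axis)
    ax.set_ylabel("bias in the ATE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
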