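"""Fitness aggregation across temporally varying pollinator climates.

When the pollinator climate varies among years (or within a season), each
epoch has its own adaptive landscape, and long-run selection favours the
phenotype with the highest *geometric* mean fitness across epochs — a
multiplicative average that is highly sensitive to near-zero years.  A
highly effective but unreliable visitor (absent half the time) therefore
contributes far less to the long-run optimum than its good-year landscape
suggests, while a modest but constant visitor anchors it.  The arithmetic
mean is provided as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import FitnessCurve, make_tabulated_curve
from .landscape import PhenotypeGrid

__all__ = ["TemporalSeries", "geometric_mean_landscape", "arithmetic_mean_landscape"]


@dataclass(frozen=True)
class TemporalSeries:
    """Weighted epochs of per-epoch adaptive landscapes on a common grid.

    Weights (e.g. relative epoch lengths or frequencies) are normalised to
    sum to 1 on construction.
    """

    epochs: tuple[tuple[float, FitnessCurve], ...]
    grid: PhenotypeGrid

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ValueError("at least one epoch is required")
        w = np.asarray([wt for wt, _ in self.epochs], dtype=float)
        if np.any(w < 0):
            raise ValueError("epoch weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("epoch weights must not all be zero")
        norm = tuple(
            (float(wt / total), curve) for (wt, curve) in self.epochs
        )
        object.__setattr__(self, "epochs", norm)

    def _values(self) -> tuple[np.ndarray, np.ndarray]:
        z = self.grid.points
        w = np.asarray([wt for wt, _ in self.epochs])
        vals = np.stack([np.asarray(c(z), dtype=float) for _, c in self.epochs])
        if np.any(vals < 0):
            raise ValueError("epoch fitness values must be nonnegative")
        return w, vals


def geometric_mean_landscape(series: TemporalSeries, label: str = "geometric mean") -> FitnessCurve:
    """Weighted geometric mean of the epoch landscapes, tabulated on the grid.

    ``value(z) = exp(sum_i w_i * ln(f_i(z)))`` with weights summing to 1.
    Wherever any positively weighted epoch is exactly 0, the result is 0
    (the limit convention), so one disastrous year zeroes long-run fitness
    at that phenotype no matter how good the other years are.
    """
    w, vals = series._values()
    active = w > 0
    zero_mask = np.any(vals[active] == 0.0, axis=0)
    safe = np.where(vals <= 0.0, 1.0, vals)
    logmean = np.einsum("i,ij->j", w, np.log(safe))
    out = np.where(zero_mask, 0.0, np.exp(logmean))
    return make_tabulated_curve(series.grid.points, out, label=label)


def arithmetic_mean_landscape(series: TemporalSeries, label: str = "arithmetic mean") -> FitnessCurve:
    """Weighted pointwise arithmetic mean of the epoch landscapes."""
    w, vals = series._values()
    out = np.einsum("i,ij->j", w, vals)
    return make_tabulated_curve(series.grid.points, out, label=label)
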