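"""Diagnostics of adaptive landscapes on a phenotype grid.

Given a (combined) fitness curve evaluated on an even grid, these routines
locate adaptive peaks and valleys, classify the landscape as flat, unimodal
or multimodal, measure its steepness, and identify which visitor's own
optimum lies closest to the combined optimum (the "nearest contributor" —
e.g. whether the overall optimal tube length broadly matches the optimum
predicted by hawkmoths alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import FitnessCurve

__all__ = [
    "PhenotypeGrid",
    "LandscapeSummary",
    "NoOptimumError",
    "summarize_landscape",
    "nearest_contributor",
]

#: Relative tolerance below which a landscape counts as flat.
FLAT_RTOL = 1e-12


class NoOptimumError(ValueError):
    """No visitor in the guild has a defined phenotypic optimum."""


@dataclass(frozen=True)
class PhenotypeGrid:
    """Evenly spaced phenotype grid on ``[lo, hi]``, endpoints included."""

    lo: float
    hi: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("grid requires lo < hi")
        if self.n_points < 3:
            raise ValueError("grid requires at least 3 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / (self.n_points - 1)


@dataclass(frozen=True)
class LandscapeSummary:
    """Peaks, valleys and slope diagnostics of a landscape on a grid.

    Attributes
    ----------
    global_optimum, global_max : float
        Location and height of the highest point (ties resolved toward the
        lowest phenotype).
    local_optima : tuple of (phenotype, value)
        Local maxima; a plateau of equal values is reported once, at its
        lowest phenotype.  Grid endpoints strictly above their single
        neighbour count as local optima, so the global optimum is always a
        member unless the landscape is flat.
    modality : {"unimodal", "multimodal", "flat"}
    valley_depth : float
        ``global_max`` minus the highest minimum separating two local
        optima; 0 unless multimodal.
    steepness : float
        Maximum |Δvalue/Δphenotype| over adjacent grid points.
    """

    global_optimum: float
    global_max: float
    local_optima: tuple[tuple[float, float], ...]
    modality: str
    valley_depth: float
    steepness: float


def _plateau_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exactly equal consecutive values, as (start, stop)."""
    runs = []
    start = 0
    for i in range(1, len(values)):
        if values[i] != values[start]:
            runs.append((start, i))
            start = i
    runs.append((start, len(values)))
    return runs


def summarize_landscape(curve: FitnessCurve, grid: PhenotypeGrid) -> LandscapeSummary:
    """Evaluate ``curve`` on ``grid`` and summarise its peaks and valleys."""
    z = grid.points
    v = np.asarray(curve(z), dtype=float)

    vmax = float(v.max())
    scale = max(abs(vmax), float(np.abs(v).max()), 1e-300)
    if float(v.max() - v.min()) <= FLAT_RTOL * scale:
        return LandscapeSummary(
            global_optimum=float(z[0]),
            global_max=vmax,
            local_optima=(),
            modality="flat",
            valley_depth=0.0,
            steepness=0.0,
        )

    runs = _plateau_runs(v)
    optima: list[tuple[float, float]] = []  # (phenotype of run start, value)
    opt_runs: list[int] = []
    for r, (a, b) in enumerate(runs):
        val = v[a]
        left_ok = r == 0 or v[runs[r - 1][0]] < val
        right_ok = r == len(runs) - 1 or v[runs[r + 1][0]] < val
        if left_ok and right_ok:
            optima.append((float(z[a]), float(val)))
            opt_runs.append(r)

    modality = "unimodal" if len(optima) == 1 else "multimodal"

    valley_depth = 0.0
    if modality == "multimodal":
        # Highest of the minima separating consecutive local optima.
        sep_minima = []
        for r0, r1 in zip(opt_runs[:-1], opt_runs[1:]):
            i0 = runs[r0][1]  # first index after the left optimum's plateau
            i1 = runs[r1][0]  # first index of the right optimum's plateau
            sep_minima.append(float(v[i0:i1].min()))
        valley_depth = vmax - max(sep_minima)

    i_global = int(np.argmax(v))  # first occurrence → lowest phenotype on ties
    steepness = float(np.max(np.abs(np.diff(v)) / grid.step))
    return LandscapeSummary(
        global_optimum=float(z[i_global]),
        global_max=vmax,
        local_optima=tuple(optima),
        modality=modality,
        valley_depth=valley_depth,
        steepness=steepness,
    )


def nearest_contributor(
    combined: LandscapeSummary,
    visitors: list[tuple[str, FitnessCurve]],
) -> tuple[str, float]:
    """Which visitor's own optimum is closest to the combined optimum?

    Returns the visitor label and the absolute phenotype distance.  Ties are
    broken toward the visitor listed first.  Flat visitor curves have no
    optimum; they are excluded with a warning, and a guild with no non-flat
    curve raises :class:`NoOptimumError`.
    """
    if not visitors:
        raise ValueError("visitors must be nonempty")
    best: tuple[str, float] | None = None
    for lab, curve in visitors:
        if curve.form == "flat" or curve.optimum is None:
            warnings.warn(
                f"visitor {lab!r} has a flat curve with no optimum; excluded "
                "from nearest-contributor search",
                stacklevel=2,
            )
            continue
        d = abs(curve.optimum - combined.global_optimum)
        if best is None or d < best[1]:
            best = (lab, d)
    if best is None:
        raise NoOptimumError("no visitor in the guild has a defined optimum")
    return best
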