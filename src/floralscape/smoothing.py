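"""Binned and smoothed per-phenotype summaries of simulation output.

Per-flower means are grouped into equal-width phenotype bins and the binned
means are passed through a local-mean (boxcar) smoother whose window is a
fraction of the phenotype axis — the per-phenotype curves one would plot for
visitation, removal and export landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import AdditiveBaseline, FlowerPopulation, SimulationResult

__all__ = ["SmoothedLandscape", "bin_and_smooth", "bin_and_smooth_values", "summarize_optima"]

DEFAULT_BINS = 20
DEFAULT_BANDWIDTH = 0.15


@dataclass(frozen=True)
class SmoothedLandscape:
    """Binned then smoothed per-phenotype values of one metric.

    ``binned`` holds per-bin means of per-flower values (NaN for empty
    bins); ``smoothed`` the local-mean smoothed series (NaN propagates only
    for bins that were themselves empty).  ``counts`` is the bin occupancy.
    """

    metric: str
    bin_centres: np.ndarray
    binned: np.ndarray
    smoothed: np.ndarray
    counts: np.ndarray
    n_bins: int
    bandwidth: float


def bin_and_smooth_values(
    phenotypes: np.ndarray,
    values: np.ndarray,
    metric: str = "",
    n_bins: int = DEFAULT_BINS,
    bandwidth: float = DEFAULT_BANDWIDTH,
    lo: float | None = None,
    hi: float | None = None,
) -> SmoothedLandscape:
    """Bin per-flower ``values`` by phenotype, then smooth over bin centres.

    The smoother replaces each occupied bin's value by the mean of occupied
    bins whose centres lie within ``bandwidth * (hi - lo)`` of it; empty bins
    are recorded as NaN and skipped.  Before smoothing, the occupancy-
    weighted mean of the binned values equals the overall per-flower mean.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be at least 3")
    if not 0.0 < bandwidth < 1.0:
        raise ValueError("bandwidth must lie strictly between 0 and 1")
    z = np.asarray(phenotypes, dtype=float)
    v = np.asarray(values, dtype=float)
    lo = float(z.min()) if lo is None else lo
    hi = float(z.max()) if hi is None else hi
    if not lo < hi:
        raise ValueError("degenerate phenotype range")

    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        binned = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    centres = 0.5 * (edges[:-1] + edges[1:])
    window = bandwidth * (hi - lo)
    smoothed = np.full(n_bins, np.nan)
    occupied = counts > 0
    for i in range(n_bins):
        if not occupied[i]:
            continue
        near = occupied & (np.abs(centres - centres[i]) <= window)
        smoothed[i] = binned[near].mean()

    return SmoothedLandscape(
        metric=metric,
        bin_centres=centres,
        binned=binned,
        smoothed=smoothed,
        counts=counts,
        n_bins=n_bins,
        bandwidth=bandwidth,
    )


def bin_and_smooth(
    result: SimulationResult | AdditiveBaseline,
    metric: str,
    n_bins: int = DEFAULT_BINS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> SmoothedLandscape:
    """Binned/smoothed landscape of a simulation or additive baseline.

    ``metric`` is one of ``visits``, ``removal``, ``export``.
    """
    values = result.per_flower_mean(metric)
    pop: FlowerPopulation = result.population
    return bin_and_smooth_values(
        pop.phenotype_array, values, metric=metric, n_bins=n_bins, bandwidth=bandwidth
    )


def summarize_optima(smoothed: SmoothedLandscape) -> tuple[float, float]:
    """Bin-centre phenotype and value of the smoothed maximum.

    Ties are broken toward the lowest phenotype; an all-empty landscape is a
    domain error.
    """
    s = smoothed.smoothed
    if np.all(np.isnan(s)):
        raise ValueError("smoothed landscape has no occupied bins")
    i = int(np.nanargmax(s))
    return float(smoothed.bin_centres[i]), float(s[i])
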