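"""Reproducible randomised guilds and populations for testing.

Property-based tests need many plausible pollinator guilds; this module
draws them reproducibly from stated parameter ranges.  Seed 0 is reserved
for the exact canonical bee/hummingbird guild so the printed
parameterisation is always fixture 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import calibrate_gaussian_curve
from .simulate import (
    FlowerPopulation,
    PollinatorSpec,
    build_population,
    fig_guild,
    fig_population,
)

__all__ = ["FixtureRanges", "GuildFixture", "generate_fixture_guild"]


@dataclass(frozen=True)
class FixtureRanges:
    """Inclusive sampling ranges for randomised guild parameters."""

    optimum: tuple[float, float] = (0.1, 0.9)
    attraction_peak: tuple[float, float] = (0.5, 1.0)
    removal_peak: tuple[float, float] = (5_000.0, 20_000.0)
    cross_fraction: tuple[float, float] = (0.05, 0.5)  # reference / peak
    efficiency: tuple[float, float] = (0.01, 0.10)
    n_flowers: int = 100
    pollen_budget: float = 160_000.0

    def __post_init__(self) -> None:
        for name in ("optimum", "attraction_peak", "removal_peak", "cross_fraction", "efficiency"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name!r} requires lo < hi")
        lo, hi = self.cross_fraction
        if not (0 < lo and hi < 1):
            raise ValueError("cross_fraction must lie strictly inside (0, 1)")
        if not 0 <= self.efficiency[0] and self.efficiency[1] <= 1:
            raise ValueError("efficiency range must lie in [0, 1]")
        if self.n_flowers < 2 or self.pollen_budget <= 0:
            raise ValueError("invalid population parameters")


@dataclass(frozen=True)
class GuildFixture:
    guild: tuple[PollinatorSpec, ...]
    population: FlowerPopulation
    mixture: tuple[float, ...]
    seed: int


def generate_fixture_guild(
    seed: int,
    n_pollinators: int = 2,
    ranges: FixtureRanges | None = None,
) -> GuildFixture:
    """Reproducible random guild + population; seed 0 is the canonical guild.

    For ``seed == 0`` the exact bee/hummingbird parameterisation is returned
    verbatim (``n_pollinators`` must then be 2).  Other seeds draw each
    pollinator's optimum, peaks, cross-values and efficiency uniformly from
    ``ranges``; mixture weights are uniform.
    """
    if n_pollinators < 1:
        raise ValueError("n_pollinators must be at least 1")
    ranges = ranges or FixtureRanges()
    if seed == 0:
        if n_pollinators != 2:
            raise ValueError("fixture 0 is the canonical two-pollinator guild")
        return GuildFixture(
            guild=fig_guild(),
            population=fig_population(),
            mixture=(0.5, 0.5),
            seed=0,
        )

    rng = np.random.default_rng(seed)
    guild = []
    # Reference point: the farther phenotype-range endpoint, so the
    # calibration reference is always distinct from the optimum.
    for k in range(n_pollinators):
        opt = float(rng.uniform(*ranges.optimum))
        ref = 0.0 if opt > 0.5 else 1.0
        a_peak = float(rng.uniform(*ranges.attraction_peak))
        r_peak = float(rng.uniform(*ranges.removal_peak))
        a_cross = a_peak * float(rng.uniform(*ranges.cross_fraction))
        r_cross = r_peak * float(rng.uniform(*ranges.cross_fraction))
        eff = float(rng.uniform(*ranges.efficiency))
        guild.append(
            PollinatorSpec(
                label=f"pollinator_{k}",
                attraction=calibrate_gaussian_curve(
                    opt, a_peak, ref, a_cross, f"pollinator_{k} attraction"
                ),
                removal=calibrate_gaussian_curve(
                    opt, r_peak, ref, r_cross, f"pollinator_{k} removal"
                ),
                transfer_efficiency=eff,
            )
        )
    population = build_population(ranges.n_flowers, 0.0, 1.0, ranges.pollen_budget)
    mixture = tuple([1.0 / n_pollinators] * n_pollinators)
    return GuildFixture(
        guild=tuple(guild), population=population, mixture=mixture, seed=seed
    )
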