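"""Stochastic pollinator-visitation and pollen-export simulator.

The model: a population of flowers with a uniform spread of phenotypes and a
finite pollen budget each is visited by a guild of pollinator types (e.g.
bees and hummingbirds).  Each visit event (1) draws a pollinator from the
guild's abundance mixture, (2) draws a target flower with probability
proportional to that pollinator's attraction at each flower's phenotype,
(3) removes pollen according to the pollinator's removal curve, capped by
the flower's remaining pollen, and (4) exports (deposits elsewhere) a
pollinator-specific fraction of what it removed; the rest is lost from the
system — groomed, eaten, or dropped.

Because pollen removed by one visitor cannot be removed by another, the
visitor types interact: a poor-quality visitor pre-empts pollen and visits
that a better vector would otherwise have exported, an *opportunity
trade-off* that makes the mixed-guild landscape non-additive.  The additive
baseline (each pollinator simulated alone, results summed) quantifies what
a naive per-visitor decomposition would predict.

Default parameterisation (module constants below): 100 flowers, 160 000
grains each; two visitor types with optima at 0.25 and 0.75 on the
normalised phenotype axis, 90 % attraction at their own optimum and 10 % at
the other's, removing 10 000 grains per visit at their own optimum and
2 500 at the other's, exporting 2 % (bees) or 4 % (hummingbirds) of removed
pollen; 3 500 visits per iteration, 10 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import FitnessCurve, calibrate_gaussian_curve

__all__ = [
    "PollinatorSpec",
    "FlowerPopulation",
    "EnvironmentConfig",
    "SimulationResult",
    "AdditiveBaseline",
    "ConfigurationError",
    "build_population",
    "simulate_environment",
    "additive_baseline",
    "fig_guild",
    "fig_population",
    "fig_environment",
]

# Canonical two-visitor parameterisation (bee / hummingbird).
BEE_OPTIMUM = 0.25
BIRD_OPTIMUM = 0.75
ATTRACTION_PEAK = 0.9
ATTRACTION_CROSS = 0.1
REMOVAL_PEAK = 10_000.0
REMOVAL_CROSS = 2_500.0
BEE_EFFICIENCY = 0.02
BIRD_EFFICIENCY = 0.04
POLLEN_BUDGET = 160_000.0
N_FLOWERS = 100
TOTAL_VISITS = 3_500
N_ITERATIONS = 10

#: Seed offset between the single-pollinator runs of the additive baseline.
BASELINE_SEED_STRIDE = 10_000

METRICS = ("visits", "removal", "export")


class ConfigurationError(ValueError):
    """The environment configuration admits no valid visit event."""


@dataclass(frozen=True)
class PollinatorSpec:
    """One visitor type: attraction, removal, and pollen-transfer efficiency.

    ``attraction`` gives the per-phenotype visitation-probability weight in
    [0, 1]; ``removal`` the grains taken per visit; ``transfer_efficiency``
    the fraction of removed pollen subsequently deposited rather than lost.
    """

    label: str
    attraction: FitnessCurve
    removal: FitnessCurve
    transfer_efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_efficiency <= 1.0:
            raise ValueError("transfer_efficiency must lie in [0, 1]")


@dataclass(frozen=True)
class FlowerPopulation:
    """Phenotypes and the common per-flower pollen budget."""

    phenotypes: tuple[float, ...]
    pollen_budget: float

    def __post_init__(self) -> None:
        z = np.asarray(self.phenotypes, dtype=float)
        if z.size < 1:
            raise ValueError("population must contain at least one flower")
        if np.any(np.diff(z) < 0):
            raise ValueError("phenotypes must be sorted ascending")
        if self.pollen_budget <= 0:
            raise ValueError("pollen budget must be positive")
        object.__setattr__(self, "phenotypes", tuple(float(p) for p in z))

    @property
    def n_flowers(self) -> int:
        return len(self.phenotypes)

    @property
    def phenotype_array(self) -> np.ndarray:
        return np.asarray(self.phenotypes, dtype=float)


@dataclass(frozen=True)
class EnvironmentConfig:
    """A pollinator climate: guild, abundance mixture, visit schedule, seed."""

    guild: tuple[PollinatorSpec, ...]
    mixture: tuple[float, ...]
    total_visits: int = TOTAL_VISITS
    n_iterations: int = N_ITERATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.guild) == 0:
            raise ValueError("guild must be nonempty")
        w = np.asarray(self.mixture, dtype=float)
        if w.size != len(self.guild):
            raise ValueError("mixture must have one weight per pollinator")
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if self.total_visits < 1:
            raise ValueError("total_visits must be at least 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        object.__setattr__(self, "guild", tuple(self.guild))
        object.__setattr__(self, "mixture", tuple(float(x) for x in w))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.guild)

    def single_pollinator(self, index: int, seed: int | None = None) -> "EnvironmentConfig":
        """This environment restricted to one guild member at full abundance."""
        return EnvironmentConfig(
            guild=(self.guild[index],),
            mixture=(1.0,),
            total_visits=self.total_visits,
            n_iterations=self.n_iterations,
            seed=self.seed if seed is None else seed,
        )


@dataclass(frozen=True)
class SimulationResult:
    """Per-iteration, per-flower, per-pollinator tallies of a seeded run.

    Arrays are shaped ``(n_iterations, n_flowers, n_pollinators)``; the
    ``metadata`` dict echoes the configuration and seed so results are
    self-describing.
    """

    visits: np.ndarray
    removed: np.ndarray
    exported: np.ndarray
    population: FlowerPopulation
    env: EnvironmentConfig
    metadata: dict = field(default_factory=dict)

    def per_flower_mean(self, metric: str) -> np.ndarray:
        """Mean over iterations, summed over pollinators; shape (n_flowers,)."""
        arr = {"visits": self.visits, "removal": self.removed, "export": self.exported}[
            metric
        ]
        return arr.sum(axis=2).mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: iteration, flower_id, phenotype, pollinator, tallies."""
        n_it, n_fl, n_pol = self.visits.shape
        it, fl, pol = np.meshgrid(
            np.arange(n_it), np.arange(n_fl), np.arange(n_pol), indexing="ij"
        )
        return pd.DataFrame(
            {
                "iteration": it.ravel(),
                "flower_id": fl.ravel(),
                "phenotype": self.population.phenotype_array[fl.ravel()],
                "pollinator": np.asarray(self.env.labels)[pol.ravel()],
                "visits": self.visits.ravel(),
                "pollen_removed": self.removed.ravel(),
                "pollen_exported": self.exported.ravel(),
            }
        )


@dataclass(frozen=True)
class AdditiveBaseline:
    """Sum across single-pollinator environments of per-flower means.

    ``per_flower`` maps each metric to an ``(n_flowers,)`` array.  Because
    the component runs do not share a pollen pool, the summed removal can
    exceed the physical per-flower budget — that unrealism is the point of
    the comparison.
    """

    per_flower: dict[str, np.ndarray]
    components: tuple[SimulationResult, ...]
    population: FlowerPopulation
    notice: str | None = None

    def per_flower_mean(self, metric: str) -> np.ndarray:
        return self.per_flower[metric]


def build_population(
    n_flowers: int, range_lo: float, range_hi: float, pollen_budget: float
) -> FlowerPopulation:
    """Evenly spaced flower phenotypes from ``range_lo`` to ``range_hi``."""
    if n_flowers < 2:
        raise ValueError("need at least 2 flowers to span a phenotype range")
    if not range_lo < range_hi:
        raise ValueError("range_lo must be below range_hi")
    if pollen_budget <= 0:
        raise ValueError("pollen budget must be positive")
    z = np.linspace(range_lo, range_hi, n_flowers)
    return FlowerPopulation(phenotypes=tuple(z), pollen_budget=float(pollen_budget))


def _categorical(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    """Inverse-CDF categorical draws.

    One uniform block per call, so the consumed random stream depends only on
    ``size`` — a mixture of (1, 0) therefore reproduces a single-pollinator
    run bit-for-bit.
    """
    cum = np.cumsum(weights / weights.sum())
    u = rng.random(size)
    return np.searchsorted(cum, u, side="right").astype(np.intp)


def simulate_environment(
    population: FlowerPopulation, env: EnvironmentConfig
) -> SimulationResult:
    """Run the seeded visit simulation for every iteration of ``env``.

    Each iteration i uses an independent stream seeded with ``env.seed + i``
    and executes exactly ``env.total_visits`` visit events.  Attraction does
    not change as pollen depletes (depletion caps removal, not choice), so
    within an iteration the pollinator and flower draws are made up front and
    depletion is applied along each flower's visit sequence.  Visits to an
    empty flower are allowed and remove nothing.
    """
    z = population.phenotype_array
    n_fl = population.n_flowers
    n_pol = len(env.guild)

    attr = np.empty((n_pol, n_fl))
    remv = np.empty((n_pol, n_fl))
    eff = np.asarray([p.transfer_efficiency for p in env.guild])
    for k, spec in enumerate(env.guild):
        a = np.asarray(spec.attraction(z), dtype=float)
        r = np.asarray(spec.removal(z), dtype=float)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError(
                f"attraction values of {spec.label!r} fall outside [0, 1] "
                "over the population"
            )
        if np.any(r < 0):
            raise ValueError(f"removal values of {spec.label!r} are negative")
        if env.mixture[k] > 0 and a.sum() <= 0:
            raise ConfigurationError(
                f"pollinator {spec.label!r} has zero attraction to every "
                "flower; no flower can be chosen"
            )
        attr[k] = a
        remv[k] = r

    mixture = np.asarray(env.mixture)
    visits = np.zeros((env.n_iterations, n_fl, n_pol), dtype=np.int64)
    removed = np.zeros((env.n_iterations, n_fl, n_pol))
    exported = np.zeros((env.n_iterations, n_fl, n_pol))

    for it in range(env.n_iterations):
        rng = np.random.default_rng(env.seed + it)
        pol_idx = _categorical(rng, mixture, env.total_visits)
        fl_idx = np.empty(env.total_visits, dtype=np.intp)
        for k in range(n_pol):
            mask = pol_idx == k
            m = int(mask.sum())
            if m:
                fl_idx[mask] = _categorical(rng, attr[k], m)

        np.add.at(visits[it], (fl_idx, pol_idx), 1)
        for f in np.unique(fl_idx):
            ev = np.flatnonzero(fl_idx == f)
            pk = pol_idx[ev]
            desired = remv[pk, f]
            cum = np.minimum(np.cumsum(desired), population.pollen_budget)
            taken = np.diff(cum, prepend=0.0)
            row = np.bincount(pk, weights=taken, minlength=n_pol)
            # Re-summing per pollinator can overshoot the budget by a few
            # ulps; push any excess back onto the largest share so the
            # physical cap holds exactly.
            excess = row.sum() - population.pollen_budget
            if excess > 0:
                row[int(np.argmax(row))] -= excess
            removed[it, f] = row
            exported[it, f] = row * eff

    metadata = {
        "seed": env.seed,
        "n_iterations": env.n_iterations,
        "total_visits": env.total_visits,
        "guild": list(env.labels),
        "mixture": list(env.mixture),
        "n_flowers": n_fl,
        "pollen_budget": population.pollen_budget,
    }
    return SimulationResult(
        visits=visits,
        removed=removed,
        exported=exported,
        population=population,
        env=env,
        metadata=metadata,
    )


def additive_baseline(
    population: FlowerPopulation, env: EnvironmentConfig
) -> AdditiveBaseline:
    """Each pollinator simulated alone, per-flower means summed across them.

    Component runs keep ``env``'s visit schedule and iteration count but use
    derived seeds (``env.seed + 10000 * pollinator_index``) so their random
    streams are independent.  With a single-pollinator guild the baseline is
    simply that environment's means, returned with a ``notice``.
    """
    components = []
    for k in range(len(env.guild)):
        single = env.single_pollinator(k, seed=env.seed + BASELINE_SEED_STRIDE * k)
        components.append(simulate_environment(population, single))
    per_flower = {
        m: np.sum([c.per_flower_mean(m) for c in components], axis=0) for m in METRICS
    }
    notice = None
    if len(env.guild) == 1:
        notice = "single-pollinator guild: additive baseline equals the environment itself"
    return AdditiveBaseline(
        per_flower=per_flower,
        components=tuple(components),
        population=population,
        notice=notice,
    )


# -- canonical parameterisation --------------------------------------------


def fig_guild() -> tuple[PollinatorSpec, PollinatorSpec]:
    """The canonical bee + hummingbird guild (module constants above)."""
    bee = PollinatorSpec(
        label="bee",
        attraction=calibrate_gaussian_curve(
            BEE_OPTIMUM, ATTRACTION_PEAK, BIRD_OPTIMUM, ATTRACTION_CROSS, "bee attraction"
        ),
        removal=calibrate_gaussian_curve(
            BEE_OPTIMUM, REMOVAL_PEAK, BIRD_OPTIMUM, REMOVAL_CROSS, "bee removal"
        ),
        transfer_efficiency=BEE_EFFICIENCY,
    )
    bird = PollinatorSpec(
        label="hummingbird",
        attraction=calibrate_gaussian_curve(
            BIRD_OPTIMUM, ATTRACTION_PEAK, BEE_OPTIMUM, ATTRACTION_CROSS,
            "hummingbird attraction",
        ),
        removal=calibrate_gaussian_curve(
            BIRD_OPTIMUM, REMOVAL_PEAK, BEE_OPTIMUM, REMOVAL_CROSS, "hummingbird removal"
        ),
        transfer_efficiency=BIRD_EFFICIENCY,
    )
    return bee, bird


def fig_population() -> FlowerPopulation:
    """100 flowers evenly spaced on [0, 1], 160 000 grains each."""
    return build_population(N_FLOWERS, 0.0, 1.0, POLLEN_BUDGET)


def fig_environment(seed: int = 0, n_iterations: int = N_ITERATIONS) -> EnvironmentConfig:
    """The mixed bee/hummingbird environment with equal abundances."""
    return EnvironmentConfig(
        guild=fig_guild(),
        mixture=(0.5, 0.5),
        total_visits=TOTAL_VISITS,
        n_iterations=n_iterations,
        seed=seed,
    )
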