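"""Run configuration: JSON schema, validation, and model builders.

A run is described by one JSON document with four blocks — ``population``,
``guild``, ``environment`` and (optionally) ``analysis`` — validated
against a strict schema (unknown keys rejected, constraints reported by
key).  The bundled ``fig5.json`` encodes the canonical two-visitor
parameterisation: 100 flowers with 160 000 grains each, bee and hummingbird
attraction 0.9/0.1 and removal 10 000/2 500 at own/other optimum,
efficiencies 0.02/0.04, 3 500 visits, 10 iterations, equal mixture.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .curves import FitnessCurve, calibrate_gaussian_curve, make_flat_curve, make_tabulated_curve
from .simulate import EnvironmentConfig, FlowerPopulation, PollinatorSpec, build_population

__all__ = [
    "ConfigError",
    "CurveConfig",
    "PopulationConfig",
    "PollinatorConfig",
    "EnvironmentBlock",
    "AnalysisConfig",
    "RunConfig",
    "load_config",
    "fig5_config",
    "ENVIRONMENT_NAMES",
]

ENVIRONMENT_NAMES = ("bee_only", "bird_only", "mixed")


class ConfigError(ValueError):
    """Configuration file violates the schema; message names the key."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class CurveConfig(_StrictModel):
    """One fitness curve: parametric, or calibrated through two points.

    Gaussian curves accept either an explicit ``width`` or a two-point
    calibration (``reference_point``, ``reference_value``) — the value the
    curve must take away from its optimum, e.g. at the other pollinator's
    optimum.
    """

    form: Literal["gaussian", "flat", "tabulated"] = "gaussian"
    optimum: float | None = None
    peak_value: float | None = None
    width: float | None = Field(default=None, gt=0)
    reference_point: float | None = None
    reference_value: float | None = Field(default=None, gt=0)
    table: list[tuple[float, float]] | None = None
    label: str = ""

    @model_validator(mode="after")
    def _check_form(self) -> "CurveConfig":
        if self.form == "gaussian":
            if self.optimum is None or self.peak_value is None:
                raise ValueError("gaussian curve requires 'optimum' and 'peak_value'")
            has_width = self.width is not None
            has_ref = self.reference_point is not None and self.reference_value is not None
            if has_width == has_ref:
                raise ValueError(
                    "gaussian curve requires exactly one of 'width' or "
                    "('reference_point', 'reference_value')"
                )
        elif self.form == "flat":
            if self.peak_value is None or self.peak_value < 0:
                raise ValueError("flat curve requires a nonnegative 'peak_value'")
        else:
            if not self.table:
                raise ValueError("tabulated curve requires a nonempty 'table'")
        return self

    def build(self) -> FitnessCurve:
        if self.form == "flat":
            return make_flat_curve(self.peak_value, label=self.label)
        if self.form == "tabulated":
            return make_tabulated_curve(
                [p for p, _ in self.table], [v for _, v in self.table], label=self.label
            )
        if self.width is not None:
            return FitnessCurve(
                form="gaussian",
                optimum=self.optimum,
                peak_value=self.peak_value,
                width=self.width,
                label=self.label,
            )
        return calibrate_gaussian_curve(
            self.optimum,
            self.peak_value,
            self.reference_point,
            self.reference_value,
            label=self.label,
        )


class PopulationConfig(_StrictModel):
    n_flowers: int = Field(ge=2)
    range_lo: float = 0.0
    range_hi: float = 1.0
    pollen_budget: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_range(self) -> "PopulationConfig":
        if not self.range_lo < self.range_hi:
            raise ValueError("range_lo must be below range_hi")
        return self

    def build(self) -> FlowerPopulation:
        return build_population(
            self.n_flowers, self.range_lo, self.range_hi, self.pollen_budget
        )


class PollinatorConfig(_StrictModel):
    label: str
    attraction: CurveConfig
    removal: CurveConfig
    transfer_efficiency: float = Field(ge=0, le=1)

    def build(self) -> PollinatorSpec:
        return PollinatorSpec(
            label=self.label,
            attraction=self.attraction.build(),
            removal=self.removal.build(),
            transfer_efficiency=self.transfer_efficiency,
        )


class EnvironmentBlock(_StrictModel):
    mixture: list[float]
    total_visits: int = Field(default=3500, ge=1)
    n_iterations: int = Field(default=10, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_mixture(self) -> "EnvironmentBlock":
        if any(w < 0 for w in self.mixture):
            raise ValueError("mixture weights must be nonnegative")
        total = sum(self.mixture)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture weights must sum to 1 (got {total})")
        return self


class AnalysisConfig(_StrictModel):
    n_bins: int = Field(default=20, ge=3)
    bandwidth: float = Field(default=0.15, gt=0, lt=1)
    grid_points: int = Field(default=1001, ge=3)


class RunConfig(_StrictModel):
    """Validated run description with defaults applied and echoed."""

    population: PopulationConfig
    guild: list[PollinatorConfig] = Field(min_length=1)
    environment: EnvironmentBlock
    analysis: AnalysisConfig = AnalysisConfig()
    out_dir: str | None = None

    @model_validator(mode="after")
    def _check_mixture_length(self) -> "RunConfig":
        if len(self.environment.mixture) != len(self.guild):
            raise ValueError(
                "mixture must list one weight per guild member "
                f"({len(self.environment.mixture)} weights for {len(self.guild)} pollinators)"
            )
        return self

    # -- builders -----------------------------------------------------------

    def build_population(self) -> FlowerPopulation:
        return self.population.build()

    def build_guild(self) -> tuple[PollinatorSpec, ...]:
        return tuple(p.build() for p in self.guild)

    def build_environment(
        self,
        name: str = "mixed",
        seed: int | None = None,
        n_iterations: int | None = None,
    ) -> EnvironmentConfig:
        """Environment for one of the named pollinator climates.

        ``mixed`` uses the configured mixture; ``bee_only`` / ``bird_only``
        put all abundance on the first / second guild member.
        """
        guild = self.build_guild()
        env = self.environment
        if name == "mixed":
            mixture = tuple(env.mixture)
        elif name == "bee_only":
            mixture = tuple(1.0 if i == 0 else 0.0 for i in range(len(guild)))
        elif name == "bird_only":
            if len(guild) < 2:
                raise ConfigError("bird_only requires a guild of at least two pollinators")
            mixture = tuple(1.0 if i == 1 else 0.0 for i in range(len(guild)))
        else:
            raise ConfigError(f"unknown environment name {name!r}")
        return EnvironmentConfig(
            guild=guild,
            mixture=mixture,
            total_visits=env.total_visits,
            n_iterations=env.n_iterations if n_iterations is None else n_iterations,
            seed=env.seed if seed is None else seed,
        )

    # -- serialisation ------------------------------------------------------

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(**kwargs)

    def config_hash(self) -> str:
        """Short stable hash of the canonical JSON form."""
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Raises :class:`ConfigError` with a message naming the offending key and
    constraint on any schema violation.
    """
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"configuration file not found: {path}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"configuration file is not valid JSON: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def fig5_config() -> RunConfig:
    """The bundled canonical two-visitor run configuration."""
    text = resources.files("floralscape.data").joinpath("fig5.json").read_text()
    return RunConfig.model_validate(json.loads(text))
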