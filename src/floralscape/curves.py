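"""Visitor-specific fitness curves and their combination.

A floral adaptive landscape is built from per-visitor fitness contributions:
each pollinator type contributes fitness (visitation probability, pollen
grains removed per visit, or relative fitness) as a function of a floral
phenotype such as corolla-tube length.  The phenotype axis is dimensionless
and normalised to [0, 1] throughout the package.

Three curve families cover the shapes used in practice:

``gaussian``
    ``value(z) = peak_value * exp(-(z - optimum)^2 / (2 * width^2))`` —
    a visitor with a clear phenotypic preference.
``flat``
    a constant contribution, for visitors whose fitness contribution changes
    little across the trait range.
``tabulated``
    arbitrary nonnegative values at increasing phenotype knots, evaluated by
    linear interpolation and clamped to the endpoint values outside the knots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FitnessCurve",
    "CalibrationError",
    "calibrate_gaussian_curve",
    "make_flat_curve",
    "make_tabulated_curve",
    "combine_additive",
    "combine_components",
]


class CalibrationError(ValueError):
    """A two-point Gaussian calibration is degenerate or out of domain."""


@dataclass(frozen=True)
class FitnessCurve:
    """A nonnegative fitness contribution as a function of phenotype.

    Parameters
    ----------
    form : {"gaussian", "flat", "tabulated"}
        Curve family.
    peak_value : float
        Maximum value of the curve (the constant value for ``flat``).
    optimum : float or None
        Phenotype at which the maximum is attained.  ``None`` for flat
        curves, which have no optimum; for tabulated curves it is the
        knot of the (first) maximal value.
    width : float or None
        Gaussian standard deviation on the phenotype axis; ``None`` for the
        other forms.
    table : tuple of (float, float) or None
        Knots of a tabulated curve, strictly increasing in phenotype.
    label : str
        Free-text name (e.g. ``"bee attraction"``).
    """

    form: str
    peak_value: float
    optimum: float | None = None
    width: float | None = None
    table: tuple[tuple[float, float], ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.form not in ("gaussian", "flat", "tabulated"):
            raise ValueError(f"unknown curve form {self.form!r}")
        if self.form == "gaussian":
            if self.optimum is None or self.width is None:
                raise ValueError("gaussian curve requires optimum and width")
            if self.width <= 0:
                raise ValueError("gaussian width must be positive")
            if self.peak_value < 0:
                raise ValueError("peak_value must be nonnegative")
        elif self.form == "flat":
            if self.peak_value < 0:
                raise ValueError("flat curve value must be nonnegative")
        else:  # tabulated
            if not self.table:
                raise ValueError("tabulated curve requires a nonempty table")
            x = np.asarray([p for p, _ in self.table], dtype=float)
            y = np.asarray([v for _, v in self.table], dtype=float)
            if np.any(np.diff(x) <= 0):
                raise ValueError("tabulated phenotypes must be strictly increasing")
            if np.any(y < 0):
                raise ValueError("tabulated values must be nonnegative")
            # Derived fields kept consistent with the table.
            object.__setattr__(self, "peak_value", float(y.max()))
            object.__setattr__(self, "optimum", float(x[int(np.argmax(y))]))

    # -- evaluation ---------------------------------------------------------

    def __call__(self, z):
        """Evaluate the curve at phenotype(s) ``z`` (scalar or array)."""
        z_arr = np.asarray(z, dtype=float)
        if self.form == "gaussian":
            out = self.peak_value * np.exp(
                -((z_arr - self.optimum) ** 2) / (2.0 * self.width**2)
            )
        elif self.form == "flat":
            out = np.full_like(z_arr, self.peak_value)
        else:
            x = np.asarray([p for p, _ in self.table], dtype=float)
            y = np.asarray([v for _, v in self.table], dtype=float)
            out = np.interp(z_arr, x, y)  # np.interp clamps outside the knots
        return out if out.ndim else float(out)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"form": self.form, "label": self.label}
        if self.form == "gaussian":
            d.update(optimum=self.optimum, peak_value=self.peak_value, width=self.width)
        elif self.form == "flat":
            d.update(peak_value=self.peak_value)
        else:
            d.update(table=[list(p) for p in self.table])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessCurve":
        form = d.get("form")
        if form == "gaussian":
            return cls(
                form="gaussian",
                optimum=float(d["optimum"]),
                peak_value=float(d["peak_value"]),
                width=float(d["width"]),
                label=d.get("label", ""),
            )
        if form == "flat":
            return cls(form="flat", peak_value=float(d["peak_value"]), label=d.get("label", ""))
        if form == "tabulated":
            table = tuple((float(p), float(v)) for p, v in d["table"])
            return cls(form="tabulated", peak_value=0.0, table=table, label=d.get("label", ""))
        raise ValueError(f"unknown curve form {form!r}")

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_csv(self, path) -> None:
        """Write a tabulated curve as two-column CSV (phenotype,value)."""
        if self.form != "tabulated":
            raise ValueError("only tabulated curves export to CSV")
        with open(path, "w") as fh:
            fh.write("phenotype,value\n")
            for p, v in self.table:
                fh.write(f"{p!r},{v!r}\n")


def calibrate_gaussian_curve(
    optimum: float,
    peak_value: float,
    reference_point: float,
    reference_value: float,
    label: str = "",
) -> FitnessCurve:
    """Build a Gaussian curve through two points.

    The curve attains ``peak_value`` at ``optimum`` and ``reference_value``
    at ``reference_point``; the width follows in closed form::

        width = |reference_point - optimum| / sqrt(2 * ln(peak_value / reference_value))

    This is the calibration used for the simulator's visitor curves, where a
    pollinator's attraction or removal is specified by its value at its own
    optimum and at the other pollinator's optimum.

    Raises
    ------
    CalibrationError
        If ``reference_value >= peak_value`` (a Gaussian cannot rise, or stay
        level, away from its optimum — request a flat curve explicitly via
        :func:`make_flat_curve` instead).
    ValueError
        For nonpositive values or a reference point equal to the optimum.
    """
    if reference_point == optimum:
        raise ValueError("reference_point must differ from optimum")
    if peak_value <= 0 or reference_value <= 0:
        raise ValueError("peak_value and reference_value must be positive")
    if reference_value >= peak_value:
        raise CalibrationError(
            "reference_value must be strictly below peak_value; equal values "
            "imply an infinite width (use make_flat_curve for a constant curve)"
        )
    width = abs(reference_point - optimum) / math.sqrt(
        2.0 * math.log(peak_value / reference_value)
    )
    return FitnessCurve(
        form="gaussian", optimum=optimum, peak_value=peak_value, width=width, label=label
    )


def make_flat_curve(value: float, label: str = "") -> FitnessCurve:
    """Constant fitness contribution ``value`` at every phenotype."""
    if value < 0:
        raise ValueError("flat curve value must be nonnegative")
    return FitnessCurve(form="flat", peak_value=value, label=label)


def make_tabulated_curve(
    phenotypes: Sequence[float], values: Sequence[float], label: str = ""
) -> FitnessCurve:
    """Tabulated curve from parallel knot/value sequences."""
    table = tuple((float(p), float(v)) for p, v in zip(phenotypes, values, strict=True))
    return FitnessCurve(form="tabulated", peak_value=0.0, table=table, label=label)


def combine_additive(
    curves: Iterable[FitnessCurve], grid, label: str = "combined"
) -> FitnessCurve:
    """Pointwise sum of fitness curves, tabulated on ``grid``.

    The additive combined adaptive surface: total fitness at each phenotype
    is the sum of every visitor's contribution there.  Commutative and
    associative up to floating-point tolerance.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("combine_additive requires at least one curve")
    points = np.asarray(getattr(grid, "points", grid), dtype=float)
    total = np.zeros_like(points)
    for c in curves:
        total = total + np.asarray(c(points), dtype=float)
    return make_tabulated_curve(points, total, label=label)


def combine_components(
    female: FitnessCurve,
    male: FitnessCurve,
    grid,
    mode: str = "sum",
    label: str = "total fitness",
) -> FitnessCurve:
    """Combine female (seed set) and male (pollen export) fitness components.

    ``mode="sum"`` (default) treats the components as two pathways of
    reproductive output added together; ``mode="product"`` multiplies them,
    so a zero in either component zeroes total fitness.  Under ``sum`` a flat
    female component cannot move the optimum away from the male optimum.
    """
    if mode not in ("sum", "product"):
        raise ValueError(f"mode must be 'sum' or 'product', got {mode!r}")
    points = np.asarray(getattr(grid, "points", grid), dtype=float)
    f = np.asarray(female(points), dtype=float)
    m = np.asarray(male(points), dtype=float)
    if np.any(f < 0) or np.any(m < 0):
        raise ValueError("fitness components must be nonnegative")
    vals = f + m if mode == "sum" else f * m
    return make_tabulated_curve(points, vals, label=label)
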