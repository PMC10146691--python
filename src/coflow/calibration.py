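"""Correction-factor calibration for the two-stream coflow viscometer.

The lumped-circuit model treats the interface between the two parallel
streams as a virtual wall, splitting the coflowing channel into two
rectangular resistors. A dimensionless correction factor CF(α) compensates
that idealization against the real three-dimensional flow. CF is measured
with a test fluid of known viscosity: rearranging the steady-state
viscometry law gives

    CF = (µ_t/µ_r) · (1−α_t)/α_t · (Q_t/Q_r),

and a low-order polynomial in α is fitted to the measured points for each
channel depth. Linearizing the transient governing equation further requires
a single constant CF₀, obtained as the weighted mean of CF(α) with weight
α/(1−α) over the working interface range.

The module ships the calibrated polynomials and CF₀ constants for the three
stock channel depths (h = 4, 10 and 20 µm) as authoritative constants; they
can be re-derived from raw observations with :func:`fit_cf_polynomial` and
:func:`cf0_constant`, but recomputation never silently overrides the shipped
values (the exact averaging set behind the stock CF₀ numbers is part of the
original calibration campaign, not of this package).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .errors import DegenerateStreamError, FitError, InvalidInputError

__all__ = [
    "CFObservation",
    "CorrectionFactorModel",
    "cf_point",
    "fit_cf_polynomial",
    "cf0_constant",
    "builtin_cf_models",
    "DEFAULT_CF0_GRID",
]

#: Default α grid for CF₀ averaging: the stated viscometry validity range.
DEFAULT_CF0_GRID: np.ndarray = np.round(np.arange(0.10, 0.90 + 1e-9, 0.01), 10)

#: Default polynomial degree per stock channel depth (µm).
DEFAULT_DEGREE_BY_DEPTH: dict[float, int] = {4.0: 3, 10.0: 2, 20.0: 5}


@dataclass(frozen=True)
class CFObservation:
    """One calibration measurement with a test fluid of known viscosity.

    Parameters
    ----------
    alpha_t : interface fraction occupied by the test fluid, in (0, 1).
    mu_t, mu_r : test- and reference-fluid viscosities, mPa·s.
    Q_t, Q_r : test- and reference-fluid flow rates (any common unit).
    """

    alpha_t: float
    mu_t: float
    mu_r: float
    Q_t: float = 1.0
    Q_r: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_t < 1.0:
            raise DegenerateStreamError(
                f"alpha_t must lie strictly in (0, 1), got {self.alpha_t}"
            )
        for name in ("mu_t", "mu_r", "Q_t", "Q_r"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class CorrectionFactorModel:
    """Polynomial correction factor CF(α) with validity range and CF₀.

    ``coefficients`` are in ascending order of degree. ``cf0`` is the scalar
    used to linearize the transient equation; for the stock depths it is the
    shipped calibration constant.
    """

    coefficients: tuple[float, ...]
    depth: float | None = None
    valid_range: tuple[float, float] = (0.1, 0.9)
    cf0: float | None = None
    r_squared: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise InvalidInputError("coefficients must be non-empty")
        if len(self.coefficients) - 1 > 5:
            raise InvalidInputError("CF polynomial degree must be <= 5")
        lo, hi = self.valid_range
        if not 0.0 <= lo < hi <= 1.0:
            raise InvalidInputError(f"invalid validity range {self.valid_range}")
        grid = np.linspace(lo, hi, 257)
        if np.any(self._poly(grid) <= 0):
            raise InvalidInputError(
                "CF(α) must be positive over the validity range"
            )

    @property
    def _poly(self) -> Polynomial:
        return Polynomial(self.coefficients)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, alpha):
        """Evaluate CF(α)."""
        return self._poly(alpha)

    def derivative(self, alpha):
        """Evaluate dCF/dα."""
        return self._poly.deriv()(alpha)

    @classmethod
    def constant(
        cls,
        value: float,
        valid_range: tuple[float, float] = (0.0, 1.0),
        depth: float | None = None,
    ) -> "CorrectionFactorModel":
        """A constant correction factor CF(α) ≡ value (so CF₀ = value)."""
        if value <= 0:
            raise InvalidInputError("constant CF must be > 0")
        return cls(
            coefficients=(float(value),),
            depth=depth,
            valid_range=valid_range,
            cf0=float(value),
        )

    def with_cf0(self, cf0: float) -> "CorrectionFactorModel":
        return replace(self, cf0=float(cf0))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "coeffs": list(self.coefficients),
            "range": list(self.valid_range),
            "cf0": self.cf0,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CorrectionFactorModel":
        return cls(
            coefficients=tuple(float(c) for c in d["coeffs"]),
            depth=d.get("depth"),
            valid_range=tuple(d.get("range", (0.1, 0.9))),
            cf0=d.get("cf0"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionFactorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def cf_point(obs: CFObservation) -> float:
    """Correction factor implied by a single calibration observation.

    CF = (µ_t/µ_r) · (1−α_t)/α_t · (Q_t/Q_r).
    """
    return (
        (obs.mu_t / obs.mu_r)
        * ((1.0 - obs.alpha_t) / obs.alpha_t)
        * (obs.Q_t / obs.Q_r)
    )


def fit_cf_polynomial(
    points: Sequence[tuple[float, float]],
    degree: int | None = None,
    depth: float | None = None,
    valid_range: tuple[float, float] = (0.1, 0.9),
) -> CorrectionFactorModel:
    """Least-squares polynomial fit of CF against interface fraction.

    Parameters
    ----------
    points : sequence of (α, CF) pairs.
    degree : polynomial degree; defaults per stock depth (3 for h=4 µm,
        2 for h=10 µm, 5 for h=20 µm) and to 3 otherwise.
    depth : channel depth label (µm), stored on the model.

    Returns a :class:`CorrectionFactorModel` with ``r_squared`` filled in and
    ``cf0`` computed from the fitted polynomial on the default grid.
    """
    if degree is None:
        degree = DEFAULT_DEGREE_BY_DEPTH.get(
            float(depth) if depth is not None else -1.0, 3
        )
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (α, CF) pairs")
    alpha, cf = pts[:, 0], pts[:, 1]
    if len(alpha) < degree + 1:
        raise FitError(
            f"need at least {degree + 1} points for degree {degree}, "
            f"got {len(alpha)}"
        )
    if np.linalg.matrix_rank(np.vander(alpha, degree + 1)) < degree + 1:
        raise FitError("design matrix is rank deficient (duplicate α values?)")
    # fit in the natural (unscaled) basis so coefficients are comparable to
    # published calibration polynomials
    coef = np.polynomial.polynomial.polyfit(alpha, cf, deg=degree)
    poly = Polynomial(coef)
    pred = poly(alpha)
    ss_res = float(np.sum((cf - pred) ** 2))
    ss_tot = float(np.sum((cf - np.mean(cf)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    model = CorrectionFactorModel(
        coefficients=tuple(poly.coef),
        depth=depth,
        valid_range=valid_range,
        cf0=None,
        r_squared=r2,
    )
    return replace(model, cf0=cf0_constant(model))


def cf0_constant(
    model: CorrectionFactorModel, alpha_grid: np.ndarray | None = None
) -> float:
    """Interface-averaged constant CF₀ for linearizing the transient model.

    CF₀ = Σ CF(α)·α/(1−α) / Σ α/(1−α) over the grid — the weighted mean of
    CF with weight α/(1−α), so the linearized term α·CF₀/(1−α) matches the
    nonlinear term α·CF(α)/(1−α) on average over the working range.
    """
    if alpha_grid is None:
        lo, hi = model.valid_range
        alpha_grid = DEFAULT_CF0_GRID[
            (DEFAULT_CF0_GRID >= lo) & (DEFAULT_CF0_GRID <= hi)
        ]
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("empty CF₀ averaging grid")
    if np.any((grid <= 0) | (grid >= 1)):
        raise InvalidInputError("CF₀ grid must lie strictly inside (0, 1)")
    weight = grid / (1.0 - grid)
    return float(np.sum(model(grid) * weight) / np.sum(weight))


# Stock calibration constants for the three fabricated channel depths:
# polynomial CF(α) coefficients (ascending) and the associated CF₀.
_BUILTIN: dict[float, CorrectionFactorModel] = {
    4.0: CorrectionFactorModel(
        coefficients=(-0.1289, 4.1983, -7.669, 7.5698),
        depth=4.0,
        cf0=1.637,
        r_squared=0.9858,
    ),
    10.0: CorrectionFactorModel(
        coefficients=(0.38, 0.9378, 0.6931),
        depth=10.0,
        cf0=1.41,
        r_squared=0.9525,
    ),
    20.0: CorrectionFactorModel(
        coefficients=(0.4163, 2.5117, -11.062, 36.954, -54.452, 27.95),
        depth=20.0,
        cf0=1.183,
        r_squared=0.9354,
    ),
}


def builtin_cf_models() -> dict[float, CorrectionFactorModel]:
    """Shipped correction-factor models keyed by channel depth (µm)."""
    return dict(_BUILTIN)


def builtin_cf_model(depth: float) -> CorrectionFactorModel:
    """Shipped model for one channel depth; raises for unknown depths."""
    try:
        return _BUILTIN[float(depth)]
    except KeyError:
        raise InvalidInputError(
            f"no shipped correction-factor model for depth {depth} µm "
            f"(available: {sorted(_BUILTIN)})"
        ) from None
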