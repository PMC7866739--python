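"""Synthetic elicitation experiments with the study's factorial structure.

The wet experiment this package models doses *Corylus avellana* cell
suspension cultures with two fungal elicitor fractions — cell extract
(CE) and culture filtrate (CF) — at five CE:CF volume ratios and three
total doses, added at mid (day 13) or late (day 17) log phase, with
cultures harvested at two-day intervals after elicitation through day
23, in three replicates.  This module reproduces that design and lays a
smooth parametric "true" response surface over it, so that every
downstream stage (bandwidth tuning, cross-validated evaluation,
sensitivity ranking, input optimization) can be tested against a known
ground truth.

Each primitive response (dry weight, intracellular paclitaxel per
litre, extracellular paclitaxel) is a separable quadratic-exponential
bump — a product of Gaussian factors, one per input — placed at the
optimum the study reports, plus a small positive baseline.  Derived
responses follow the exact identities

    intracellular (µg/g DW) = intracellular (µg/l) / dry weight,
    total (µg/l)            = intracellular (µg/l) + extracellular (µg/l),
    portion (%)             = 100 · extracellular / total,

which hold exactly at zero noise.  The default surface is calibrated so
the maximum total paclitaxel yield over the feasible input box equals
372.89 µg/l, the study's reported optimum, used here as a calibration
constant.  Measurement noise is multiplicative Gaussian on the
primitives with a 10% coefficient of variation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import INPUT_COLUMNS, RESPONSE_COLUMNS

__all__ = [
    "Bump",
    "DesignSpec",
    "TrueSurface",
    "default_design",
    "default_surface",
    "simulate",
    "true_argmax",
    "DEFAULT_BOUNDS",
    "TOTAL_YIELD_CALIBRATION",
]

# reported maximum total paclitaxel yield, used as calibration constant (µg/l)
TOTAL_YIELD_CALIBRATION = 372.89

# experimental input box: CE, CF in % v/v; adding day mid-to-late log
# phase; harvest between elicitation and culture day 23
DEFAULT_BOUNDS = {
    "ce_pct": (0.0, 10.0),
    "cf_pct": (0.0, 10.0),
    "adding_day": (13.0, 17.0),
    "harvest_day": (13.0, 23.0),
}


@dataclass
class Bump:
    """Separable quadratic-exponential bump over the four culture inputs.

    ``value(x) = base + height · Π_j exp(−(x_j − center_j)² / (2 width_j²))``
    """

    center: tuple[float, float, float, float]
    width: tuple[float, float, float, float]
    height: float
    base: float = 0.0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        c = np.asarray(self.center, dtype=float)
        w = np.asarray(self.width, dtype=float)
        z = (X - c) / w
        return self.base + self.height * np.exp(-0.5 * (z**2).sum(axis=1))

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "width": list(self.width),
            "height": self.height,
            "base": self.base,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Bump":
        return cls(
            center=tuple(d["center"]),
            width=tuple(d["width"]),
            height=float(d["height"]),
            base=float(d["base"]),
        )


@dataclass
class DesignSpec:
    """Factorial elicitation design.

    ``elicitor_ratios`` are CE:CF percentage splits of the total dose;
    ``harvest_days`` maps each adding day to its harvest schedule.
    Control arms (water for CE, potato dextrose broth for CF) carry no
    elicitor and enter the numeric design as ce = cf = 0 rows.
    """

    elicitor_ratios: list[tuple[float, float]] = field(
        default_factory=lambda: [(100, 0), (75, 25), (50, 50), (25, 75), (0, 100)]
    )
    dose_levels: list[float] = field(default_factory=lambda: [2.5, 5.0, 10.0])
    adding_days: list[float] = field(default_factory=lambda: [13.0, 17.0])
    harvest_days: dict[float, list[float]] = field(
        default_factory=lambda: {
            13.0: [15.0, 17.0, 19.0, 21.0, 23.0],
            17.0: [19.0, 21.0, 23.0],
        }
    )
    replicates: int = 3
    include_controls: bool = False

    def validate(self) -> None:
        if any(d <= 0 for d in self.dose_levels):
            raise ValueError("all dose levels must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for day in self.adding_days:
            harvests = self.harvest_days.get(day)
            if not harvests:
                raise ValueError(f"no harvest days for adding day {day}")
            if any(h <= day for h in harvests):
                raise ValueError(
                    f"harvest days must be strictly after adding day {day}"
                )
            if any(h > 23 for h in harvests):
                raise ValueError("harvest days must not exceed culture day 23")

    def rows(self) -> pd.DataFrame:
        """Enumerate the design grid as input rows (inputs only)."""
        self.validate()
        recs = []
        for r_ce, r_cf in self.elicitor_ratios:
            for dose in self.dose_levels:
                for day in self.adding_days:
                    for harvest in self.harvest_days[day]:
                        for _rep in range(self.replicates):
                            recs.append(
                                (dose * r_ce / 100.0, dose * r_cf / 100.0, day, harvest)
                            )
        if self.include_controls:
            # water and PDB arms: no elicitor, ce = cf = 0
            for _arm in ("water", "pdb"):
                for day in self.adding_days:
                    for harvest in self.harvest_days[day]:
                        for _rep in range(self.replicates):
                            recs.append((0.0, 0.0, day, harvest))
        return pd.DataFrame(recs, columns=INPUT_COLUMNS)


@dataclass
class TrueSurface:
    """Deterministic ground-truth surfaces for the six responses.

    ``dw``, ``intra_l`` and ``extra`` are the primitive surfaces (dry
    weight g/l, intracellular µg/l, extracellular µg/l); the other three
    responses are derived through the exact identity chain.  ``scale``
    multiplies the two paclitaxel primitives and is set by total-yield
    calibration.  ``noise_cv`` is the relative standard deviation of the
    multiplicative measurement noise applied by :func:`simulate`.
    """

    dw: Bump
    intra_l: Bump
    extra: Bump
    noise_cv: float = 0.1
    scale: float = 1.0

    def primitives(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dw = self.dw(X)
        intra_l = self.scale * self.intra_l(X)
        extra = self.scale * self.extra(X)
        return dw, intra_l, extra

    def responses(self, X: np.ndarray) -> pd.DataFrame:
        """Evaluate all six noiseless responses at input rows ``X``."""
        dw, intra_l, extra = self.primitives(X)
        return _derive(dw, intra_l / dw, extra)

    def to_dict(self) -> dict:
        return {
            "dw": self.dw.to_dict(),
            "intra_l": self.intra_l.to_dict(),
            "extra": self.extra.to_dict(),
            "noise_cv": self.noise_cv,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueSurface":
        return cls(
            dw=Bump.from_dict(d["dw"]),
            intra_l=Bump.from_dict(d["intra_l"]),
            extra=Bump.from_dict(d["extra"]),
            noise_cv=float(d["noise_cv"]),
            scale=float(d["scale"]),
        )


def _derive(dw: np.ndarray, intra_g: np.ndarray, extra: np.ndarray) -> pd.DataFrame:
    """Build the six-response table from the measured primitives."""
    intra_l = intra_g * dw
    total = intra_l + extra
    portion = np.where(total > 0, 100.0 * extra / np.where(total > 0, total, 1.0), 0.0)
    return pd.DataFrame(
        {
            "dw_g_l": dw,
            "intra_ug_g": intra_g,
            "intra_ug_l": intra_l,
            "extra_ug_l": extra,
            "total_ug_l": total,
            "portion_pct": portion,
        },
        columns=RESPONSE_COLUMNS,
    )


def default_design(include_controls: bool = False) -> DesignSpec:
    """The study's grid: 5 CE:CF ratios × 3 doses × 2 adding days ×
    biennial harvests through day 23 × 3 replicates (360 elicitor rows)."""
    return DesignSpec(include_controls=include_controls)


def default_surface(noise_cv: float = 0.1, calibrate: bool = True) -> TrueSurface:
    """Ground truth calibrated to the reported response magnitudes.

    Peak locations sit at the reported per-response optima; peak heights
    at the reported optimum values; widths are chosen so the responses
    vary severalfold across the design box while staying unimodal.  When
    ``calibrate`` is true the paclitaxel primitives are jointly rescaled
    so the feasible-box maximum of the total yield equals
    ``TOTAL_YIELD_CALIBRATION`` exactly (up to grid resolution).
    """
    surface = TrueSurface(
        dw=Bump(
            center=(4.26, 0.54, 16.33, 20.58),
            width=(5.0, 25.0, 2.5, 1.8),
            height=9.57,
            base=3.0,
        ),
        intra_l=Bump(
            center=(4.43, 5.69, 16.09, 20.47),
            width=(2.4, 2.8, 4.0, 4.0),
            height=222.78,
            base=2.0,
        ),
        extra=Bump(
            center=(4.58, 4.71, 15.91, 22.06),
            width=(2.8, 3.0, 5.0, 2.9),
            height=151.15,
            base=1.0,
        ),
        noise_cv=noise_cv,
    )
    if calibrate:
        _x, peak = true_argmax(surface, "total_ug_l")
        surface = replace(surface, scale=TOTAL_YIELD_CALIBRATION / peak)
    return surface


def simulate(
    design: DesignSpec, surface: TrueSurface, seed: int | None = 0
) -> pd.DataFrame:
    """Draw one noisy dataset from the design and surface.

    Multiplicative Gaussian noise of CV ``surface.noise_cv`` is applied
    independently to the three measured primitives (dry weight,
    intracellular content per g DW, extracellular concentration); the
    derived responses are then recomputed, so the identity chain holds
    exactly in the emitted table.  Negative draws are clipped at 0.
    Deterministic under a fixed seed.
    """
    if surface.noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    inputs = design.rows()
    X = inputs.to_numpy()
    dw, intra_l, extra = surface.primitives(X)
    intra_g = intra_l / dw
    rng = np.random.default_rng(seed)
    noisy = []
    for vals in (dw, intra_g, extra):
        draw = vals * (1.0 + surface.noise_cv * rng.standard_normal(vals.shape))
        noisy.append(np.clip(draw, 0.0, None))
    responses = _derive(*noisy)
    return pd.concat([inputs.reset_index(drop=True), responses], axis=1)


def _grid(bounds: dict[str, tuple[float, float]], resolution: int) -> np.ndarray:
    axes = [np.linspace(lo, hi, resolution) for lo, hi in (bounds[c] for c in INPUT_COLUMNS)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def true_argmax(
    surface: TrueSurface,
    response: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    resolution: int = 41,
) -> tuple[np.ndarray, float]:
    """Dense-grid argmax of one noiseless response (oracle).

    Infeasible grid points (harvest on or before the adding day) are
    excluded.  Returns ``(input vector, value)``.
    """
    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"unknown response {response!r}")
    bounds = bounds or DEFAULT_BOUNDS
    X = _grid(bounds, resolution)
    feasible = X[:, 3] > X[:, 2]
    X = X[feasible]
    vals = surface.responses(X)[response].to_numpy()
    best = int(np.argmax(vals))
    return X[best], float(vals[best])
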