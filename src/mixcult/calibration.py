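"""Fluorescence-to-absorbance calibration from single-marker control wells.

Conversion factors are estimated per (day, marker, medium, channel) as
slopes of linear fits of raw fluorescence against raw absorbance restricted
to a low-OD range where the relation is linear, then averaged over
replicates.  The stored factor has units of absorbance-equivalent per
fluorescence a.u., so that multiplying raw fluorescence by the factor
yields raw-absorbance equivalents.

Two orientations are supported: ``"reciprocal"`` (default) stores the
reciprocal of the fluorescence-versus-OD slope; ``"inverse_regression"``
regresses OD on fluorescence directly.  For noiseless proportional data the
two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationError",
    "MissingCalibrationError",
    "ConversionFit",
    "CalibrationModel",
    "fit_conversion_factor",
    "average_factors",
    "convert_fluorescence",
]


class CalibrationError(ValueError):
    """Calibration could not be performed (e.g. too few in-range points)."""


class MissingCalibrationError(KeyError):
    """A conversion was requested for a key with no calibration."""


@dataclass
class ConversionFit:
    """One replicate's linear fit and the derived conversion factor."""

    factor: float  # absorbance-equivalent per a.u.
    slope: float  # a.u. per raw OD (fluor-vs-OD orientation)
    intercept: float
    n_points: int
    valid: bool
    fit_range: tuple[float, float]


@dataclass
class CalibrationModel:
    """Replicate-averaged factors keyed by (day, marker, medium, channel)."""

    factors: dict = field(default_factory=dict)
    n_replicates: dict = field(default_factory=dict)
    fit_range: tuple[float, float] = (0.0, 0.3)

    def factor(self, key) -> float:
        try:
            return self.factors[key]
        except KeyError:
            raise MissingCalibrationError(f"no calibration for key {key!r}")


def fit_conversion_factor(
    raw_fluor,
    raw_od,
    fit_range: tuple[float, float] = (0.0, 0.3),
    orientation: str = "reciprocal",
) -> ConversionFit:
    """Linear fit of one control well restricted to ``fit_range`` of raw OD.

    The fit includes an intercept (background fluorescence is nonzero);
    only the slope is used.  A non-positive slope yields an invalid factor
    (flagged, not raised); fewer than 2 in-range points raises
    :class:`CalibrationError`.
    """
    fluor = np.asarray(raw_fluor, dtype=float)
    od = np.asarray(raw_od, dtype=float)
    if fluor.shape != od.shape:
        raise ValueError("series must have equal length")
    lo, hi = fit_range
    mask = (od >= lo) & (od <= hi) & np.isfinite(od) & np.isfinite(fluor)
    n = int(mask.sum())
    if n < 2:
        raise CalibrationError(
            f"need >=2 points with raw OD in [{lo}, {hi}]; got {n}"
        )
    if orientation == "reciprocal":
        slope, intercept = np.polyfit(od[mask], fluor[mask], 1)
        factor = 1.0 / slope if slope > 0 else np.nan
    elif orientation == "inverse_regression":
        inv_slope, _ = np.polyfit(fluor[mask], od[mask], 1)
        slope, intercept = np.polyfit(od[mask], fluor[mask], 1)
        factor = inv_slope if inv_slope > 0 else np.nan
    else:
        raise ValueError("orientation must be 'reciprocal' or 'inverse_regression'")
    valid = np.isfinite(factor) and factor > 0
    if not valid:
        warnings.warn("non-positive calibration slope; factor flagged invalid")
    return ConversionFit(
        factor=float(factor),
        slope=float(slope),
        intercept=float(intercept),
        n_points=n,
        valid=bool(valid),
        fit_range=(lo, hi),
    )


def average_factors(per_replicate: dict, fit_range=(0.0, 0.3)) -> CalibrationModel:
    """Arithmetic mean of valid replicate factors per key.

    ``per_replicate`` maps key -> list of :class:`ConversionFit`.  Invalid
    replicates are excluded with a warning; a key with no valid replicate
    raises :class:`CalibrationError`.
    """
    model = CalibrationModel(fit_range=fit_range)
    for key, fits in per_replicate.items():
        valid = [f.factor for f in fits if f.valid]
        if len(valid) < len(fits):
            warnings.warn(f"excluding {len(fits) - len(valid)} invalid factor(s) for {key!r}")
        if not valid:
            raise CalibrationError(f"no valid calibration replicate for key {key!r}")
        model.factors[key] = float(np.mean(valid))
        model.n_replicates[key] = len(valid)
    return model


def convert_fluorescence(raw_fluor, model: CalibrationModel, key) -> np.ndarray:
    """Raw fluorescence -> raw-absorbance equivalents: elementwise x * factor."""
    return np.asarray(raw_fluor, dtype=float) * model.factor(key)
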