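"""Growth-rate, lag-time and yield extraction from abundance trajectories.

The processing chain mirrors the standard plate-reader workflow for mixed
cultures read out in absorbance plus two fluorescence channels:

1. pathlength correction (raw absorbance-equivalents -> bacterial units,
   b.u.; 1 b.u. = blank-corrected OD600 of 1 at 1 cm),
2. blank subtraction (well-specific for absorbance, using the known
   inoculum; global over marker-free wells for fluorescence channels),
3. centered rolling-mean smoothing (window 7, shrinking to 1 at the edges)
   and truncation to the analysis horizon,
4. Theil-Sen estimation of the exponential rate on log abundances within a
   fixed abundance band or a dynamically selected exponential-phase window,
5. lag time by back-interpolation of the fitted line to the known inoculum,
   and yield as the smoothed abundance at 24 h.

Rates are set to zero (and lag to -infinity) when fewer than
``min_points`` observations fall in the estimation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthFit",
    "UndefinedFitError",
    "pathlength_correct",
    "estimate_blank_absorbance",
    "estimate_blank_fluorescence",
    "smooth_and_truncate",
    "theil_sen_loglinear",
    "rolling_rate",
    "select_fit_window",
    "growth_rate",
    "lag_time",
    "growth_yield",
]

# default estimation-window constants
ABUNDANCE_LOWER = 1.5e-2  # b.u.
ABUNDANCE_UPPER = 6e-2  # b.u.
RATE_THRESHOLD = 0.1  # 1/h, rolling-rate cutoff for the dynamic window
MIN_POINTS = 7


class UndefinedFitError(ValueError):
    """Too few usable points for a slope estimate."""


@dataclass
class GrowthFit:
    """Result of rate/lag extraction for one trajectory."""

    rate: float  # 1/h
    intercept: float  # ln(b.u.) at t = 0
    lag: float = np.nan  # h; -inf for nongrowing populations
    yield_24h: float = np.nan  # b.u.
    window_mode: str = "dynamic"
    n_points_used: int = 0


def pathlength_correct(values, correction_factor: float) -> np.ndarray:
    """Raw absorbance-equivalents -> b.u. by dividing out the pathlength factor."""
    if correction_factor <= 0:
        raise ValueError("pathlength correction factor must be positive")
    return np.asarray(values, dtype=float) / correction_factor


def estimate_blank_absorbance(values, known_initial_abundance: float) -> float:
    """Well-specific blank: mean of the first two readings minus the inoculum."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 time points for blank estimation")
    if known_initial_abundance < 0:
        raise ValueError("known initial abundance must be >= 0")
    return float(values[:2].mean() - known_initial_abundance)


def estimate_blank_fluorescence(well_values: dict, marker_wells) -> float:
    """Global fluorescence blank: grand mean over wells lacking the marker.

    ``well_values`` maps well id -> array of channel readings (any common
    processing stage); ``marker_wells`` is the set of wells whose cultures
    carry the marker matching this channel.
    """
    marker_wells = set(marker_wells)
    eligible = [np.asarray(v, float) for w, v in well_values.items() if w not in marker_wells]
    if not eligible:
        raise ValueError("no marker-free wells available for blank estimation")
    return float(np.concatenate(eligible).mean())


def smooth_and_truncate(
    times, values, window: int = 7, horizon: float = 24.0
) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling mean (min width 1 at the edges), then drop t > horizon."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty series")
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    smoothed = (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    keep = times <= horizon + 1e-12
    return times[keep], smoothed[keep]


def theil_sen_loglinear(times, abundance, point_mask=None) -> tuple[float, float]:
    """Theil-Sen slope/intercept of ln(abundance) versus time.

    Slope is the median of all pairwise slopes (pairs at identical times
    excluded); intercept is median(ln a) - slope * median(t).  Non-positive
    abundances inside the mask are dropped with a warning; fewer than 2
    remaining points raise :class:`UndefinedFitError`.
    """
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if point_mask is not None:
        mask = np.asarray(point_mask, dtype=bool)
        times, abundance = times[mask], abundance[mask]
    pos = abundance > 0
    if not np.all(pos):
        warnings.warn("dropping non-positive abundances before log transform")
        times, abundance = times[pos], abundance[pos]
    if times.size < 2:
        raise UndefinedFitError("need >=2 positive points for a Theil-Sen fit")
    res = stats.theilslopes(np.log(abundance), times)
    return float(res.slope), float(res.intercept)


def rolling_rate(
    times, abundance, window: int = 19, min_window: int = 10
) -> np.ndarray:
    """Per-point Theil-Sen rate over a centered rolling window.

    Windows truncate at the series edges; positions whose window holds
    fewer than ``min_window`` points get NaN.  A series shorter than
    ``min_window`` is an error.
    """
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    n = times.size
    if n < min_window:
        raise UndefinedFitError(f"series length {n} below minimal window {min_window}")
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if hi - lo < min_window:
            continue
        t, a = times[lo:hi], abundance[lo:hi]
        pos = a > 0
        if pos.sum() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.theilslopes(np.log(a[pos]), t[pos])
        out[i] = res.slope
    return out


def select_fit_window(
    abundance,
    mode: str = "dynamic",
    rolling_rates=None,
    lower: float = ABUNDANCE_LOWER,
    upper: float = ABUNDANCE_UPPER,
    rate_threshold: float = RATE_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of points used for the rate estimate.

    ``fixed``: points with lower < abundance < upper (strict).
    ``dynamic``: contiguous run from the first point above ``lower`` through
    the latest point whose rolling rate exceeds ``rate_threshold``.
    """
    a = np.asarray(abundance, dtype=float)
    if mode == "fixed":
        return (a > lower) & (a < upper)
    if mode != "dynamic":
        raise ValueError("mode must be 'fixed' or 'dynamic'")
    if rolling_rates is None:
        raise ValueError("dynamic mode requires rolling_rates")
    rr = np.asarray(rolling_rates, dtype=float)
    mask = np.zeros(a.size, dtype=bool)
    above = np.nonzero(a > lower)[0]
    fast = np.nonzero(np.nan_to_num(rr, nan=-np.inf) > rate_threshold)[0]
    if above.size == 0 or fast.size == 0:
        return mask
    start, end = above[0], fast[-1]
    if end >= start:
        mask[start : end + 1] = True
    return mask


def growth_rate(
    times,
    abundance,
    mode: str = "dynamic",
    lower: float = ABUNDANCE_LOWER,
    upper: float = ABUNDANCE_UPPER,
    rate_threshold: float = RATE_THRESHOLD,
    rolling_window: int = 19,
    rolling_min_window: int = 10,
    min_points: int = MIN_POINTS,
) -> GrowthFit:
    """Rate and intercept on the selected window; zero rate if the window is thin.

    The trajectory is expected preprocessed (calibrated, blank-corrected,
    smoothed, truncated).  Fewer than ``min_points`` in-window observations
    set the rate to zero and the lag to -infinity.
    """
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    rr = None
    if mode == "dynamic":
        try:
            rr = rolling_rate(times, abundance, rolling_window, rolling_min_window)
        except UndefinedFitError:
            return GrowthFit(0.0, -np.inf, lag=-np.inf, window_mode=mode, n_points_used=0)
    mask = select_fit_window(abundance, mode, rr, lower, upper, rate_threshold)
    n_used = int(mask.sum())
    if n_used < min_points:
        return GrowthFit(0.0, -np.inf, lag=-np.inf, window_mode=mode, n_points_used=n_used)
    slope, intercept = theil_sen_loglinear(times, abundance, mask)
    if slope <= 0:
        # declining or flat window: treated as nongrowing
        return GrowthFit(0.0, intercept, lag=-np.inf, window_mode=mode, n_points_used=n_used)
    return GrowthFit(
        rate=float(slope),
        intercept=intercept,
        window_mode=mode,
        n_points_used=n_used,
    )


def lag_time(fit: GrowthFit, known_initial_abundance: float) -> float:
    """Back-interpolate the fitted line to the known inoculum abundance.

    lag = (ln a0 - intercept) / rate; -infinity for nongrowing populations.
    """
    if known_initial_abundance <= 0:
        raise ValueError("known initial abundance must be positive")
    if fit.rate == 0:
        return -np.inf
    return float((np.log(known_initial_abundance) - fit.intercept) / fit.rate)


def growth_yield(times, abundance, at: float = 24.0) -> float:
    """Smoothed abundance at the time point closest to ``at`` hours."""
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if times.size == 0 or times.max() < at - 1e-9:
        raise ValueError(f"trajectory does not cover {at} h")
    return float(abundance[np.argmin(np.abs(times - at))])
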