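"""End-to-end growth pipeline: calibrate, deconvolve, extract kinetics.

Binds the calibration and growth modules into one deterministic pass over a
plate: fluorescence-to-absorbance conversion factors are fitted from
single-marker control wells, every well/channel is converted to
blank-corrected bacterial units, smoothed and truncated, and a growth fit
(rate, intercept, lag, 24-h yield) is extracted per trajectory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationModel,
    average_factors,
    convert_fluorescence,
    fit_conversion_factor,
)
from .config import ExperimentConfig
from .growth import (
    estimate_blank_absorbance,
    estimate_blank_fluorescence,
    growth_rate,
    growth_yield,
    lag_time,
    pathlength_correct,
    smooth_and_truncate,
)
from .plates import PlateTimeSeries

__all__ = ["calibrate_plate", "fluorescence_blanks", "fit_growth", "run_growth_pipeline"]

FLUOR_CHANNELS = ("CFP", "YFP")


def calibrate_plate(plate: PlateTimeSeries, config: ExperimentConfig) -> CalibrationModel:
    """Fit conversion factors from the plate's single-marker control wells.

    Each control well is one replicate; factors are averaged per
    (day, marker, medium, channel) key.
    """
    per_key: dict = {}
    for well, marker in plate.single_marker_wells().items():
        info = plate.wells[well]
        fit = fit_conversion_factor(
            plate.values(well, marker),
            plate.values(well, "A600"),
            fit_range=config.calibration_fit_range,
            orientation=config.calibration_orientation,
        )
        key = (info.day, marker, info.medium, marker)
        per_key.setdefault(key, []).append(fit)
    return average_factors(per_key, fit_range=config.calibration_fit_range)


def _converted_bu(plate, well, channel, model, config) -> np.ndarray:
    """One well's channel in b.u. before blank subtraction."""
    info = plate.wells[well]
    if channel == "A600":
        return pathlength_correct(plate.values(well, "A600"), config.pathlength_factor)
    key = (info.day, channel, info.medium, channel)
    converted = convert_fluorescence(plate.values(well, channel), model, key)
    return pathlength_correct(converted, config.pathlength_factor)


def fluorescence_blanks(
    plate: PlateTimeSeries, model: CalibrationModel, config: ExperimentConfig
) -> dict[str, float]:
    """Global per-channel blanks from wells lacking the matching marker."""
    blanks = {}
    for channel in FLUOR_CHANNELS:
        marker_wells = {w for w, info in plate.wells.items() if info.has_marker(channel)}
        if not marker_wells or marker_wells == set(plate.wells):
            # channel unused on this plate, or no marker-free well to blank it
            continue
        well_values = {
            w: _converted_bu(plate, w, channel, model, config)
            for w in plate.wells
            if w not in marker_wells
        }
        blanks[channel] = estimate_blank_fluorescence(well_values, marker_wells)
    return blanks


def fit_growth(
    plate: PlateTimeSeries,
    config: ExperimentConfig,
    model: CalibrationModel | None = None,
) -> pd.DataFrame:
    """Full per-well, per-channel growth analysis of one plate.

    Absorbance trajectories are analysed for every well; each fluorescence
    channel is analysed for wells carrying the matching marker (requires a
    calibration model, fitted from the plate's own control wells when not
    supplied).  Returns one row per trajectory with rate, intercept, lag,
    24-h yield and window bookkeeping.
    """
    any_marker = any(info.has_marker(c) for info in plate.wells.values() for c in FLUOR_CHANNELS)
    if model is None and any_marker:
        model = calibrate_plate(plate, config)
    blanks = fluorescence_blanks(plate, model, config) if any_marker else {}

    rows = []
    for well in plate.well_ids():
        info = plate.wells[well]
        n_strains = max(len(info.strains), 1)
        channels = ["A600"] + [c for c in FLUOR_CHANNELS if info.has_marker(c)]
        for channel in channels:
            times = plate.times(well, channel)
            bu = _converted_bu(plate, well, channel, model, config)
            if channel == "A600":
                blank = estimate_blank_absorbance(bu, config.known_initial_abundance)
                a0_known = config.known_initial_abundance
                strain = "total"
            else:
                if channel not in blanks:
                    raise ValueError(
                        f"no marker-free wells to blank channel {channel} (well {well})"
                    )
                blank = blanks[channel]
                a0_known = config.known_initial_abundance / n_strains
                strain = info.strains[info.markers.index(channel)]
            t, a = smooth_and_truncate(
                times, bu - blank, window=config.smoothing_window, horizon=config.horizon_h
            )
            fit = growth_rate(
                t,
                a,
                mode=config.window_mode,
                lower=config.abundance_lower,
                upper=config.abundance_upper,
                rate_threshold=config.rate_threshold,
                rolling_window=config.rolling_window,
                rolling_min_window=config.rolling_min_window,
                min_points=config.min_points,
            )
            fit.lag = lag_time(fit, a0_known)
            fit.yield_24h = (
                growth_yield(t, a, at=24.0) if config.horizon_h >= 24.0 else np.nan
            )
            rows.append(
                {
                    "well": well,
                    "source_channel": channel,
                    "strain": strain,
                    "rate": fit.rate,
                    "intercept": fit.intercept,
                    "lag": fit.lag,
                    "yield_24h": fit.yield_24h,
                    "n_points_used": fit.n_points_used,
                    "window_mode": fit.window_mode,
                }
            )
    return pd.DataFrame(rows)


def run_growth_pipeline(
    plate: PlateTimeSeries, config: ExperimentConfig, out_dir=None
) -> dict:
    """Calibrate and fit a plate; optionally write CSV outputs and a manifest."""
    any_marker = any(
        info.has_marker(c) for info in plate.wells.values() for c in FLUOR_CHANNELS
    )
    model = calibrate_plate(plate, config) if any_marker else None
    fits = fit_growth(plate, config, model)
    calib_df = (
        pd.DataFrame(
            [
                {
                    "day": k[0],
                    "marker": k[1],
                    "medium": k[2],
                    "channel": k[3],
                    "factor": v,
                    "n_replicates": model.n_replicates[k],
                }
                for k, v in model.factors.items()
            ]
        )
        if model is not None
        else pd.DataFrame(columns=["day", "marker", "medium", "channel", "factor", "n_replicates"])
    )
    bundle = {"calibration": calib_df, "growth_fits": fits, "config": config.to_dict()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calib_df.to_csv(out / "calibration.csv", index=False)
        fits.to_csv(out / "growth_fits.csv", index=False)
        manifest = {
            "package": "mixcult",
            "version": __version__,
            "config": config.to_dict(),
            "outputs": ["calibration.csv", "growth_fits.csv"],
            "n_wells": len(plate.wells),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
    return bundle
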