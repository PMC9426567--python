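"""Synthetic data with known ground truth for every pipeline stage.

Generates (i) multichannel plate-reader time series of one- or two-strain
cultures (lag -> exponential -> hard saturation latent growth, linear
channel readout with background, crosstalk and noise), (ii) dose-response
panels whose growth rates follow the 4PL equation, (iii) two-color flow
cytometry event tables as bivariate log-normal clusters plus blank
contamination, and (iv) deterministic serial-transfer competition
trajectories under a shared yield cap.

All randomness flows through ``numpy.random.default_rng`` (PCG64); the same
seed reproduces output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import DoseResponseParams, four_pl
from .plates import MARKERS, PlateTimeSeries, WellInfo, combine_plates

__all__ = [
    "StrainParams",
    "ReadoutParams",
    "EventCluster",
    "latent_abundance",
    "simulate_growth_curve",
    "simulate_plate",
    "simulate_dose_response_panel",
    "simulate_event_table",
    "simulate_serial_transfers",
    "salvager_cluster",
    "dependent_cluster",
    "BLANK_CLUSTER",
    "default_time_grid",
]


@dataclass(frozen=True)
class StrainParams:
    """Latent growth parameters of one subpopulation.

    Abundances are in bacterial units (b.u.; 1 b.u. = blank-corrected,
    pathlength-corrected OD600 of 1).  Growth is a(t) = a0 for t < lag,
    a0*exp(mu*(t-lag)) afterwards, hard-capped at ``yield_cap``.
    """

    name: str
    growth_rate: float  # mu, 1/h
    lag: float = 0.0  # h
    initial_abundance: float = 1e-2  # b.u.
    yield_cap: float = 0.55  # b.u.
    marker: str = "none"  # CFP | YFP | none

    def __post_init__(self):
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if not (0 < self.initial_abundance <= self.yield_cap):
            raise ValueError("need 0 < initial_abundance <= yield_cap")
        if self.marker not in MARKERS:
            raise ValueError(f"marker must be one of {MARKERS}")


@dataclass(frozen=True)
class ReadoutParams:
    """Plate-reader readout model: linear gains, backgrounds, noise.

    raw A600 = od_per_bu * total_abundance + od_blank; each fluorescence
    channel reads gain * marked_abundance + background + crosstalk * (the
    other channel's specific signal).  Noise is multiplicative Gaussian
    (fraction of the clean signal) plus additive Gaussian read noise in the
    channel's own units.  ``yfp_saturation_od``, if set, flattens the YFP
    response once the raw OD exceeds that value (the YFP channel of the
    emulated instrument under-reads dense cultures).
    """

    od_per_bu: float = 0.56  # raw OD per b.u. (96-well pathlength factor)
    od_blank: float = 0.04  # raw OD of medium + plate
    channel_gain: dict = field(default_factory=lambda: {"CFP": 180.0, "YFP": 220.0})
    channel_background: dict = field(default_factory=lambda: {"CFP": 30.0, "YFP": 40.0})
    crosstalk: float = 0.001  # a.u. leaked per a.u. of the other specific signal
    noise_sd_multiplicative: float = 0.02
    noise_sd_additive: dict = field(
        default_factory=lambda: {"A600": 0.001, "CFP": 0.5, "YFP": 0.5}
    )
    yfp_saturation_od: float | None = None

    def __post_init__(self):
        if any(g <= 0 for g in self.channel_gain.values()):
            raise ValueError("channel gains must be positive")
        if self.crosstalk < 0 or self.noise_sd_multiplicative < 0:
            raise ValueError("crosstalk and noise sds must be >= 0")
        if any(s < 0 for s in self.noise_sd_additive.values()):
            raise ValueError("additive noise sds must be >= 0")

    def noiseless(self) -> "ReadoutParams":
        """Same readout with both noise terms switched off."""
        return ReadoutParams(
            od_per_bu=self.od_per_bu,
            od_blank=self.od_blank,
            channel_gain=dict(self.channel_gain),
            channel_background=dict(self.channel_background),
            crosstalk=self.crosstalk,
            noise_sd_multiplicative=0.0,
            noise_sd_additive={k: 0.0 for k in self.noise_sd_additive},
            yfp_saturation_od=self.yfp_saturation_od,
        )

    def ideal(self) -> "ReadoutParams":
        """Noiseless readout with crosstalk off too (backgrounds retained).

        This is the readout for exact parameter-recovery checks: every
        channel is an affine function of one subpopulation's abundance, so
        the pipeline should invert it to numerical precision.
        """
        r = self.noiseless()
        return ReadoutParams(
            od_per_bu=r.od_per_bu,
            od_blank=r.od_blank,
            channel_gain=dict(r.channel_gain),
            channel_background=dict(r.channel_background),
            crosstalk=0.0,
            noise_sd_multiplicative=0.0,
            noise_sd_additive=dict(r.noise_sd_additive),
            yfp_saturation_od=r.yfp_saturation_od,
        )


@dataclass(frozen=True)
class EventCluster:
    """A bivariate log-normal cloud of cytometry events."""

    n_events: int
    fitc_log_mean: float  # log10 a.u.
    fitc_log_sd: float
    amcyan_log_mean: float
    amcyan_log_sd: float
    label: str = "cluster"

    def __post_init__(self):
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.fitc_log_sd <= 0 or self.amcyan_log_sd <= 0:
            raise ValueError("log-sds must be positive")


# Cluster templates placed inside the salvager (CFP -> high AmCyan) and
# dependent (YFP -> high FITC) gates.
def salvager_cluster(n_events: int) -> EventCluster:
    return EventCluster(n_events, 2.3, 0.15, 4.0, 0.15, label="salvager")


def dependent_cluster(n_events: int) -> EventCluster:
    return EventCluster(n_events, 4.0, 0.15, 2.3, 0.15, label="dependent")


#: unlabeled debris in blanks: dim in both channels (YNCN region)
BLANK_CLUSTER = EventCluster(1, 2.0, 0.25, 2.0, 0.25, label="blank")


def default_time_grid(horizon_h: float = 24.0, step_min: float = 10.0) -> np.ndarray:
    """10-minute sampling from 0 to the horizon, inclusive."""
    return np.arange(0.0, horizon_h + 1e-9, step_min / 60.0)


def latent_abundance(strain: StrainParams, t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    a = strain.initial_abundance * np.exp(
        strain.growth_rate * np.clip(t - strain.lag, 0.0, None)
    )
    return np.minimum(a, strain.yield_cap)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_growth_curve(
    strains: list[StrainParams],
    readout: ReadoutParams,
    t_grid: np.ndarray,
    seed=0,
    well: str = "A1",
    day: int = 0,
    medium: str = "glycerol-minimal",
) -> PlateTimeSeries:
    """Simulate one well: latent growth of each strain plus channel readout.

    Returns a single-well plate whose ``latent`` frame holds the per-strain
    ground-truth abundances.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    marked = [s.marker for s in strains if s.marker != "none"]
    if len(marked) != len(set(marked)):
        raise ValueError("strains in one well must carry distinct markers")
    if len(strains) >= 2 and len(marked) < len(strains):
        # unmarked strains are allowed alone but mixtures must be separable
        pass
    rng = _as_rng(seed)

    latent = {s.name: latent_abundance(s, t) for s in strains}
    total = np.sum(list(latent.values()), axis=0)
    raw_od = readout.od_per_bu * total + readout.od_blank

    specific = {"CFP": np.zeros_like(t), "YFP": np.zeros_like(t)}
    for s in strains:
        if s.marker != "none":
            specific[s.marker] = readout.channel_gain[s.marker] * latent[s.name]
    if readout.yfp_saturation_od is not None:
        scale = np.minimum(1.0, readout.yfp_saturation_od / raw_od)
        specific["YFP"] = specific["YFP"] * scale

    clean = {
        "A600": raw_od,
        "CFP": specific["CFP"]
        + readout.channel_background["CFP"]
        + readout.crosstalk * specific["YFP"],
        "YFP": specific["YFP"]
        + readout.channel_background["YFP"]
        + readout.crosstalk * specific["CFP"],
    }

    frames = []
    for channel in ("A600", "CFP", "YFP"):
        value = clean[channel]
        if readout.noise_sd_multiplicative > 0:
            value = value * (1.0 + rng.normal(0.0, readout.noise_sd_multiplicative, t.size))
        add_sd = readout.noise_sd_additive.get(channel, 0.0)
        if add_sd > 0:
            value = value + rng.normal(0.0, add_sd, t.size)
        frames.append(
            pd.DataFrame({"time_h": t, "well": well, "channel": channel, "value": value})
        )
    data = pd.concat(frames, ignore_index=True)
    latent_df = pd.concat(
        [
            pd.DataFrame({"time_h": t, "well": well, "strain": name, "abundance": a})
            for name, a in latent.items()
        ],
        ignore_index=True,
    )
    info = WellInfo(
        strains=[s.name for s in strains],
        markers=[s.marker for s in strains],
        day=day,
        medium=medium,
    )
    return PlateTimeSeries(data=data, wells={well: info}, latent=latent_df)


def simulate_plate(
    layout: dict[str, list[StrainParams]],
    readout: ReadoutParams,
    t_grid: np.ndarray,
    seed=0,
    day: int = 0,
    medium: str = "glycerol-minimal",
) -> PlateTimeSeries:
    """Simulate several wells (well id -> strain list) with independent noise."""
    children = np.random.SeedSequence(seed).spawn(len(layout))
    plates = []
    for (well, strains), ss in zip(sorted(layout.items()), children):
        rng = np.random.default_rng(ss)
        plates.append(
            simulate_growth_curve(strains, readout, t_grid, seed=rng, well=well, day=day, medium=medium)
        )
    return combine_plates(plates)


def simulate_dose_response_panel(
    base: StrainParams,
    doses,
    fourpl: DoseResponseParams,
    readout: ReadoutParams,
    t_grid: np.ndarray | None = None,
    seed=0,
) -> tuple[list[PlateTimeSeries], np.ndarray]:
    """One growth curve per dose, with mu(dose) given by the 4PL equation.

    Returns the list of single-well plates and the array of true rates.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if t_grid is None:
        t_grid = default_time_grid()
    true_rates = np.atleast_1d(four_pl(doses, fourpl))
    children = np.random.SeedSequence(seed).spawn(len(doses))
    plates = []
    for i, (dose, mu, ss) in enumerate(zip(doses, true_rates, children)):
        strain = StrainParams(
            name=base.name,
            growth_rate=float(mu),
            lag=base.lag,
            initial_abundance=base.initial_abundance,
            yield_cap=base.yield_cap,
            marker=base.marker,
        )
        plate = simulate_growth_curve(
            [strain], readout, t_grid, seed=np.random.default_rng(ss), well="A1"
        )
        plate.wells["A1"].extra.update({"dose_M": float(dose), "true_rate": float(mu)})
        plates.append(plate)
    return plates, true_rates


def simulate_event_table(
    clusters: list[EventCluster],
    blank_rate: int = 0,
    seed=0,
    sample_id: str = "S1",
    transfer: int = 1,
    is_blank: bool = False,
) -> pd.DataFrame:
    """Draw cytometry events from bivariate log-normal clusters.

    ``blank_rate`` dim contaminating events are appended from
    :data:`BLANK_CLUSTER`.  The ground-truth cluster label is retained per
    event in the ``true_cluster`` column.
    """
    rng = _as_rng(seed)
    all_clusters = list(clusters)
    if blank_rate > 0:
        all_clusters.append(
            EventCluster(
                blank_rate,
                BLANK_CLUSTER.fitc_log_mean,
                BLANK_CLUSTER.fitc_log_sd,
                BLANK_CLUSTER.amcyan_log_mean,
                BLANK_CLUSTER.amcyan_log_sd,
                label="blank",
            )
        )
    total = sum(c.n_events for c in all_clusters)
    if total <= 0:
        raise ValueError("total event count must be positive")
    frames = []
    for c in all_clusters:
        if c.n_events == 0:
            continue
        fitc = 10.0 ** rng.normal(c.fitc_log_mean, c.fitc_log_sd, c.n_events)
        amcyan = 10.0 ** rng.normal(c.amcyan_log_mean, c.amcyan_log_sd, c.n_events)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "transfer": transfer,
                    "is_blank": is_blank,
                    "FITC": fitc,
                    "AmCyan": amcyan,
                    "true_cluster": c.label,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _abundance_at(a0: float, mu: float, lag: float, t: float) -> float:
    return a0 if t <= lag else a0 * np.exp(mu * (t - lag))


def simulate_serial_transfers(
    strain_a: StrainParams,
    strain_b: StrainParams,
    n_transfers: int = 8,
    dilution: float = 100.0,
    shared_yield_cap: float = 0.6,
    cycle_h: float = 24.0,
    initial_abundances: tuple[float, float] | None = None,
    seed=None,
) -> pd.DataFrame:
    """Deterministic two-strain proliferation-dilution cycles.

    Each cycle both strains grow exponentially (after their lags) from
    their post-dilution abundances until the *summed* abundance reaches
    ``shared_yield_cap`` (shared limiting resource) or the cycle ends; then
    both are diluted 1:``dilution``.  Returns a frame with columns
    transfer, abundance_a, abundance_b, ratio (a:b), t_grow_h.  Transfer 0
    is the initial mixture.  ``seed`` is accepted for interface symmetry;
    the dynamics contain no stochastic term.
    """
    if dilution <= 1:
        raise ValueError("dilution must exceed 1")
    a0 = strain_a.initial_abundance if initial_abundances is None else initial_abundances[0]
    b0 = strain_b.initial_abundance if initial_abundances is None else initial_abundances[1]
    if a0 + b0 >= shared_yield_cap:
        raise ValueError("shared yield cap must exceed the total inoculum")

    rows = [{"transfer": 0, "abundance_a": a0, "abundance_b": b0, "ratio": a0 / b0, "t_grow_h": 0.0}]
    a, b = a0, b0
    for k in range(1, n_transfers + 1):
        def total(t, a=a, b=b):
            return (
                _abundance_at(a, strain_a.growth_rate, strain_a.lag, t)
                + _abundance_at(b, strain_b.growth_rate, strain_b.lag, t)
                - shared_yield_cap
            )

        if total(cycle_h) < 0:
            t_grow = cycle_h
        else:
            t_grow = brentq(total, 0.0, cycle_h)
        a = _abundance_at(a, strain_a.growth_rate, strain_a.lag, t_grow)
        b = _abundance_at(b, strain_b.growth_rate, strain_b.lag, t_grow)
        rows.append(
            {"transfer": k, "abundance_a": a, "abundance_b": b, "ratio": a / b, "t_grow_h": t_grow}
        )
        a, b = a / dilution, b / dilution
    return pd.DataFrame(rows)
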