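"""Experiment configuration with the workflow's standard defaults.

Defaults: smoothing window 7, rolling-rate window 19 (minimum 10),
estimation band 1.5e-2 .. 6e-2 b.u., rolling-rate cutoff 0.1 1/h,
pathlength factor 0.56, known inoculum 1e-2 b.u. per well, horizon 24 h,
1e5 cytometry events per sample, alpha 0.05, dilution 1:100.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    # calibration
    calibration_fit_range: tuple[float, float] = (0.0, 0.3)
    calibration_orientation: str = "reciprocal"
    # growth kinetics
    pathlength_factor: float = 0.56
    known_initial_abundance: float = 1e-2  # total b.u. per well
    smoothing_window: int = 7
    rolling_window: int = 19
    rolling_min_window: int = 10
    window_mode: str = "dynamic"  # or "fixed"
    abundance_lower: float = 1.5e-2
    abundance_upper: float = 6e-2
    rate_threshold: float = 0.1
    min_points: int = 7
    horizon_h: float = 24.0
    # cytometry
    marker_map: dict = field(default_factory=lambda: {"salvager": "CFP", "dependent": "YFP"})
    total_events: int = 100_000
    alpha: float = 0.05
    dilution: float = 100.0
    # randomness
    seed: int = 0

    def __post_init__(self):
        if self.pathlength_factor <= 0 or self.known_initial_abundance <= 0:
            raise ValueError("pathlength factor and known inoculum must be positive")
        if self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if self.window_mode not in ("fixed", "dynamic"):
            raise ValueError("window_mode must be 'fixed' or 'dynamic'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.dilution <= 1:
            raise ValueError("dilution must exceed 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration_fit_range"] = list(self.calibration_fit_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "calibration_fit_range" in d:
            d["calibration_fit_range"] = tuple(d["calibration_fit_range"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        """Read a JSON or YAML config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
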