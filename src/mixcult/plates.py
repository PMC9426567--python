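"""In-memory container for multichannel plate-reader time series.

A plate holds long-format readings (time_h, well, channel, value) plus
per-well metadata (which strains and fluorescent markers are present, the
medium and the measurement day).  Simulated plates additionally carry the
latent per-strain abundances so downstream estimates can be checked against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("A600", "CFP", "YFP")
MARKERS = ("CFP", "YFP", "none")


@dataclass
class WellInfo:
    """Metadata for one well: strain names, their markers, context."""

    strains: list[str]
    markers: list[str]
    day: int = 0
    medium: str = "glycerol-minimal"
    extra: dict = field(default_factory=dict)

    def has_marker(self, marker: str) -> bool:
        return marker in self.markers


@dataclass
class PlateTimeSeries:
    """Long-format plate readings with per-well metadata.

    ``data`` columns: time_h, well, channel, value.  ``latent`` (optional,
    simulated plates only) columns: time_h, well, strain, abundance (b.u.).
    """

    data: pd.DataFrame
    wells: dict[str, WellInfo]
    latent: pd.DataFrame | None = None

    def well_ids(self) -> list[str]:
        return sorted(self.wells)

    def values(self, well: str, channel: str) -> np.ndarray:
        sub = self.data[(self.data["well"] == well) & (self.data["channel"] == channel)]
        return sub.sort_values("time_h")["value"].to_numpy(dtype=float)

    def times(self, well: str, channel: str = "A600") -> np.ndarray:
        sub = self.data[(self.data["well"] == well) & (self.data["channel"] == channel)]
        return np.sort(sub["time_h"].to_numpy(dtype=float))

    def latent_abundance(self, well: str, strain: str) -> np.ndarray:
        if self.latent is None:
            raise ValueError("plate carries no latent ground truth")
        sub = self.latent[(self.latent["well"] == well) & (self.latent["strain"] == strain)]
        return sub.sort_values("time_h")["abundance"].to_numpy(dtype=float)

    def single_marker_wells(self) -> dict[str, str]:
        """Wells containing exactly one fluorescently marked strain.

        Returns a mapping well -> marker; these are the calibration controls.
        """
        out = {}
        for well, info in self.wells.items():
            marked = [m for m in info.markers if m != "none"]
            if len(marked) == 1 and len(set(info.markers)) == len(info.markers):
                if all(m == "none" for m in info.markers if m != marked[0]):
                    out[well] = marked[0]
        return out


def combine_plates(plates: list[PlateTimeSeries]) -> PlateTimeSeries:
    """Merge single-well (or multi-well) plates into one plate object."""
    wells: dict[str, WellInfo] = {}
    for p in plates:
        overlap = set(p.wells) & set(wells)
        if overlap:
            raise ValueError(f"duplicate wells when combining plates: {sorted(overlap)}")
        wells.update(p.wells)
    data = pd.concat([p.data for p in plates], ignore_index=True)
    latents = [p.latent for p in plates if p.latent is not None]
    latent = pd.concat(latents, ignore_index=True) if latents else None
    return PlateTimeSeries(data=data, wells=wells, latent=latent)
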