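"""Pipeline configuration: one YAML-serializable object with full defaults.

Every stage parameter lives here so a whole run is reproducible from one
file plus a seed; CLI flags override individual fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # filtering
    lowpass_hz: float = 1000.0
    notch_hz: float | None = 60.0
    downsample_to: float = 10000.0
    zero_phase: bool = True
    filter_order: int = 4
    # beat / LAT detection
    threshold_k: float = 8.0
    refractory_s: float = 0.2
    window_pre_s: float = 0.05
    window_post_s: float = 0.15
    lat_method: str = "slope"
    # waveform metrics
    fpd_blanking_s: float = 0.05
    repol_lowpass_hz: float = 30.0
    # layout / interpolation
    layout_path: str | None = None
    epsilon_cm: float | None = None      # None -> mean NN electrode spacing
    grid_n_lat: int = 64
    grid_n_lon: int = 128
    # calcium
    mask_threshold: float = 0.2
    neighborhood_px: int = 3
    pool_window: int = 5
    pool_mode: str = "max"
    smooth_window_um: float = 600.0
    # misc
    seed: int = 0
    output_dir: str = "out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def filter_config(self):
        from .sigproc import FilterConfig
        return FilterConfig(self.lowpass_hz, self.notch_hz,
                            self.downsample_to, self.zero_phase,
                            self.filter_order)
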