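"""Run configuration: every tunable constant of the pipeline in one record.

Unknown keys in a config file are rejected rather than ignored, so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .solar import DEFAULT_OVERPASS_TIMES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration of a full simulate-retrieve-downscale-analyze run."""

    seed: int = 0
    # index / fAPAR constants
    alpha: float = 0.1
    k: float = 0.79
    fcvi_min: float = 0.18
    ndvi_ref_max: float = 0.1
    # retrieval
    fit_window: tuple[float, float] = (750.0, 770.0)
    poly_degree: int = 2
    sif_peak: float = 740.0
    sif_sigma: float = 25.0
    # scene
    overpass_times: tuple[float, ...] = DEFAULT_OVERPASS_TIMES
    ny: int = 128
    nx: int = 128
    par_max: float = 438.0
    snr: float = math.inf
    true_distance: float = 1.0
    reflectance_mode: str = "consistent"
    # outputs
    output_dir: str = "sifpipe_output"
    write_cubes: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.k <= 1:
            raise ValueError("k must be in (0, 1]")
        if not 0 <= self.fcvi_min < 1:
            raise ValueError("fcvi_min must be in [0, 1)")
        if not 0 <= self.ndvi_ref_max < 1:
            raise ValueError("ndvi_ref_max must be in [0, 1)")
        if self.reflectance_mode not in ("consistent", "toy_rt"):
            raise ValueError(f"unknown reflectance mode {self.reflectance_mode!r}")
        if self.ny <= 0 or self.nx <= 0:
            raise ValueError("scene dimensions must be positive")
        self.fit_window = tuple(self.fit_window)
        self.overpass_times = tuple(self.overpass_times)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_window"] = list(self.fit_window)
        d["overpass_times"] = list(self.overpass_times)
        if math.isinf(self.snr):
            d["snr"] = ".inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("snr") in (".inf", "inf", None):
            d["snr"] = math.inf
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
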