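"""Run configuration: validated parameters for the end-to-end pipeline.

The defaults reproduce the reference analysis configuration: distances
1..10 pixels, the four directions, 256 gray levels, eight Haralick
parameters, reciprocal rating alignment of ASM/IDM/CORR, and explicit
exclusion of the CORR block before PCA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .glcm import DIRECTIONS
from .haralick import PARAMETERS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    distances: tuple[int, ...] = tuple(range(1, 11))
    directions: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 256
    symmetric: bool = True
    parameters: tuple[str, ...] = PARAMETERS
    reciprocal_blocks: tuple[str, ...] = ("ASM", "IDM", "CORR")
    selection_threshold: float = 0.8
    selection_mode: str = "explicit"          # "explicit" or "block"
    explicit_drop_blocks: tuple[str, ...] = ("CORR",)
    log_base: float | None = None             # None = natural log
    seed: int = 0
    ra_list: tuple[float, ...] = ()           # empty = simulator default grid
    roi: tuple[int, int] | None = None
    images_dir: str | None = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        self.distances = tuple(int(d) for d in self.distances)
        self.directions = tuple(int(t) for t in self.directions)
        self.parameters = tuple(self.parameters)
        self.reciprocal_blocks = tuple(self.reciprocal_blocks)
        self.explicit_drop_blocks = tuple(self.explicit_drop_blocks)
        self.ra_list = tuple(float(r) for r in self.ra_list)
        if self.roi is not None:
            self.roi = (int(self.roi[0]), int(self.roi[1]))
        self.validate()

    def validate(self) -> None:
        if not self.distances or any(d < 1 for d in self.distances):
            raise ValueError("distances must be positive integers")
        bad = [t for t in self.directions if t not in DIRECTIONS]
        if bad:
            raise ValueError(f"invalid directions: {bad}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        unknown = [p for p in self.parameters if p not in PARAMETERS]
        if unknown:
            raise ValueError(f"unknown parameters: {unknown}")
        if not (0.0 <= self.selection_threshold <= 1.0):
            raise ValueError("selection_threshold must be in [0, 1]")
        if self.selection_mode not in ("explicit", "block"):
            raise ValueError("selection_mode must be 'explicit' or 'block'")
        if self.log_base is not None and self.log_base <= 1.0:
            raise ValueError("log_base must be > 1")
        if any(r <= 0 for r in self.ra_list):
            raise ValueError("ra_list values must be > 0")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("distances", "directions", "parameters",
                    "reciprocal_blocks", "explicit_drop_blocks", "ra_list"):
            out[key] = list(out[key])
        if out["roi"] is not None:
            out["roi"] = list(out["roi"])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
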