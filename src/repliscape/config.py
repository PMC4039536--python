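"""Analysis configuration: every numeric threshold used by the pipeline.

Defaults follow the published analysis protocol for HU BrdU-IP-Seq in
budding yeast: 50 bp bins, 1 kb median smoothing, peak p < 0.01, origin-level
FDR q < 0.05, 1 kb origin windows, 20 kb pericentric/subtelomeric landmarks,
40 kb (chromosome-scale) or 5 kb (origin-scale) metaprofile windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    bin_width: int = 50
    smooth_window: int = 1000
    peak_p_threshold: float = 0.01
    fdr_q_threshold: float = 0.05
    origin_window: int = 1000
    landmark_threshold: int = 20000
    profile_window: int = 40000
    proximity_window: int = 1000
    # local background windows for the Poisson peak caller (bp)
    local_background_windows: tuple[int, ...] = (5000, 10000)
    merge_gap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {
            "bin_width": self.bin_width,
            "smooth_window": self.smooth_window,
            "origin_window": self.origin_window,
            "landmark_threshold": self.landmark_threshold,
            "profile_window": self.profile_window,
            "proximity_window": self.proximity_window,
            "merge_gap": self.merge_gap,
            **{f"local_background_windows[{i}]": w for i, w in enumerate(self.local_background_windows)},
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in (
            ("peak_p_threshold", self.peak_p_threshold),
            ("fdr_q_threshold", self.fdr_q_threshold),
        ):
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        for name in ("smooth_window", "origin_window"):
            if getattr(self, name) % self.bin_width != 0:
                raise ValueError(f"{name} must be a multiple of bin_width")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "local_background_windows" in raw:
            raw["local_background_windows"] = tuple(raw["local_background_windows"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["local_background_windows"] = list(self.local_background_windows)
        return d
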