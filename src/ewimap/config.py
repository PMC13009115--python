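"""Run configuration: one flat YAML/JSON schema with per-stage namespaces.

A run is reproducible from (config, seed) alone; every stage draws its
randomness from child seeds spawned from the global seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters for the end-to-end synthetic pipeline."""

    seed: int = 0
    outdir: str = "run"
    format_version: str = "1"
    # phantom namespace
    phantom: dict = field(
        default_factory=lambda: {
            "r_endo_mm": 25.0,
            "r_epi_mm": 35.0,
            "spacing_mm": 1.0,
            "source_segment": "LV-mid-anterior",
            "source_layer": "endo",
            "conduction_velocity_mm_ms": 0.5,
            "emd_mean_ms": 45.0,
            "emd_sd_ms": 28.0,
            "strain_noise_sd": 5e-5,
            "points_per_segment": 10,
            "nodes_per_segment": 3,
            "duration_ms": 650.0,
            "qrs_onset_ms": 150.0,
            "frame_rate_hz": 2000.0,
        }
    )
    # rf/strain estimator namespace
    strain: dict = field(
        default_factory=lambda: {"window_len": 64, "overlap": 0.8, "search": 8, "kernel_mm": 5.0}
    )
    # mapping namespace
    map: dict = field(
        default_factory=lambda: {
            "smoothing_ms": 5.0,
            "min_negative_ms": 20.0,
            "window_ms": [-100.0, 380.0],
            "early_window_ms": 5.0,
        }
    )
    # ecgi namespace
    ecgi: dict = field(default_factory=lambda: {"r_threshold": 0.1})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        known = set(base.to_dict())
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = base.to_dict()
        for k, v in d.items():
            if isinstance(v, dict):
                merged[k] = {**merged[k], **v}
            else:
                merged[k] = v
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Stable hash of the canonical config serialization."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
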