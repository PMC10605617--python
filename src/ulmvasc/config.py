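"""Pipeline configuration: one serializable object per run.

A resolved config round-trips losslessly through YAML and hashes to a
stable digest that every tabular output carries, so any result file can
be traced back to the exact parameters that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .datatypes import AcquisitionParams, TrackerParams

__all__ = ["DetectionParams", "MotionParams", "QuantParams", "UCTParams", "PipelineConfig"]


@dataclass
class DetectionParams:
    rel_threshold: float = 0.3
    min_separation_mm: float | None = None  # default: 2 px at load time
    window_px: int = 5


@dataclass
class MotionParams:
    reference_index: int = 0
    block_size_mm: float = 3.2
    search_radius_mm: float = 0.8


@dataclass
class QuantParams:
    sr_pixel_size_mm: float = 0.025
    patch_side_mm: float = 2.0
    overlap: float = 0.5


@dataclass
class UCTParams:
    voxel_size_um: float = 26.5
    noise_sigma: float = 0.02
    kidney_intensity: float = 0.3
    vessel_intensity: float = 1.0
    kidney_threshold: float = 0.15
    vessel_threshold: float = 0.6
    cortex_radius_threshold_vox: float = 10.0
    medulla_radius_threshold_vox: float = 6.0
    label_slice_stride: int = 5


@dataclass
class SceneParams:
    n_root_vessels: int = 8
    branching_depth: int = 2
    tortuosity_amp: float = 0.0
    keep_fraction: float = 1.0
    extent_mm: float = 12.8
    dims: int = 2


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; seeds included."""

    output_dir: str | None = None
    seed: int = 0
    scene: SceneParams = field(default_factory=SceneParams)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    motion: MotionParams = field(default_factory=MotionParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    quant: QuantParams = field(default_factory=QuantParams)
    uct: UCTParams = field(default_factory=UCTParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw = {}
        for name, sub_cls in (
            ("scene", SceneParams),
            ("acquisition", AcquisitionParams),
            ("detection", DetectionParams),
            ("motion", MotionParams),
            ("tracker", TrackerParams),
            ("quant", QuantParams),
            ("uct", UCTParams),
        ):
            if name in d:
                kw[name] = sub_cls(**d.pop(name))
        return cls(**d, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Digest of the scientific parameters (paths excluded), so two
        runs of the same configuration hash identically wherever their
        outputs land."""
        d = self.to_dict()
        d.pop("output_dir", None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
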