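"""Pipeline configuration: printed analysis constants and their defaults.

Defaults follow the acquisition-analysis workflow this package reproduces:
puncta must exceed 0.01 μm², MDV-sized objects are < 0.03 μm³, networks are
> 1 μm³, the vesselness semantic threshold is 1e-05, and the mitophagy
reporter criterion is mCherry 2:1 over background with absent GFP.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "MorphoConfig",
    "PunctaConfig",
    "DynamicsConfig",
    "StatsConfig",
    "PipelineConfig",
]


@dataclass
class MorphoConfig:
    #: intensity threshold in counts, or "auto" for Otsu on the volume histogram
    intensity_threshold: float | str = "auto"
    #: minimum component size in voxels ("clean filter" stand-in)
    clean_min_voxels: int = 5
    #: objects below this volume (μm³) are MDV-sized
    v_mdv: float = 0.03
    #: objects above this volume (μm³) are networks
    v_network: float = 1.0

    def validate(self) -> None:
        if not (0 < self.v_mdv < self.v_network):
            raise ValueError(f"need 0 < v_mdv < v_network, got {self.v_mdv}, {self.v_network}")
        if self.clean_min_voxels < 1:
            raise ValueError("clean_min_voxels must be >= 1")
        if self.intensity_threshold != "auto" and float(self.intensity_threshold) <= 0:
            raise ValueError("intensity_threshold must be positive or 'auto'")


@dataclass
class PunctaConfig:
    #: minimum punctum area (μm², strict lower bound)
    min_area: float = 0.01
    #: detection threshold in counts or "auto"
    threshold: float | str = "auto"
    #: rolling-ball background radius (μm)
    background_radius: float = 0.5
    #: mCherry-only criterion: (peak - background)/background >= this
    mcherry_ratio: float = 2.0
    #: GFP counted absent when its (peak - background)/background < this
    gfp_absent_ratio: float = 0.5
    #: cargo co-localization match radius (μm)
    match_radius: float = 0.15

    def validate(self) -> None:
        for name in ("min_area", "background_radius", "mcherry_ratio", "gfp_absent_ratio", "match_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DynamicsConfig:
    #: Frangi scales in pixels
    frangi_scales: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    #: zero out voxels whose Hessian Frobenius norm is below sqrt(max norm)
    frobenius_gate: bool = True
    #: threshold on normalized vesselness
    semantic_threshold: float = 1e-05
    #: tracking speed gate (μm/s)
    max_speed: float = 1.0
    #: Gaussian prefilter (px) standing in for denoising/deconvolution; 0 = off
    denoise_sigma: float = 1.0
    #: minimum instance size in pixels (clean step against noise specks)
    min_component_px: int = 20

    def validate(self) -> None:
        if len(self.frangi_scales) == 0:
            raise ValueError("frangi_scales must not be empty")
        if self.semantic_threshold <= 0 or self.max_speed <= 0:
            raise ValueError("semantic_threshold and max_speed must be positive")


@dataclass
class StatsConfig:
    #: ROUT false-discovery rate Q
    rout_q: float = 0.01
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.rout_q < 1:
            raise ValueError("rout_q must be in (0,1)")


@dataclass
class PipelineConfig:
    morpho: MorphoConfig = field(default_factory=MorphoConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for sub in (self.morpho, self.puncta, self.dynamics, self.stats):
            sub.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short stable digest of the resolved configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for name, sub_cls in (
            ("morpho", MorphoConfig),
            ("puncta", PunctaConfig),
            ("dynamics", DynamicsConfig),
            ("stats", StatsConfig),
        ):
            sub = dict(d.get(name, {}))
            if "frangi_scales" in sub:
                sub["frangi_scales"] = tuple(sub["frangi_scales"])
            kwargs[name] = sub_cls(**sub)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML or JSON (by extension; YAML parses both)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def provenance(self) -> dict:
        from . import __version__

        return {"config_hash": self.hash(), "mitoquant_version": __version__}
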