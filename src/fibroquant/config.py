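"""Pipeline configuration: one dataclass, YAML round-trip, stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .traits import GLCMSpec, REGISTRY_VERSION

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All stage parameters of the analysis pipeline.

    Defaults are the package's documented operating point: 50 um ROI
    margin, >90% fibrosis fragment-removal rule, Otsu collagen threshold
    with a concentration floor, 25 um^2 minimum fibre area, branch
    cutoff 21, GLCM on 32 grey levels at distance 2 px over four angles,
    20%/0.05 principal-qFT selection, 0-10 output scale, 0.5 um/px
    fallback pixel size (20X scans).
    """

    palette: str = "trichrome"
    mpp_default: float = 0.5
    margin_um: float = 50.0
    min_fragment_area_um2: float = 500.0
    fibrosis_fraction_cutoff: float = 0.90
    collagen_threshold: float | None = None  # None -> Otsu with floor
    min_fibre_area_um2: float = 25.0
    connectivity: int = 8
    branch_cutoff: int = 21
    glcm: GLCMSpec = field(default_factory=GLCMSpec)
    registry_version: str = REGISTRY_VERSION
    selection_change_threshold: float = 0.20
    selection_alpha: float = 0.05
    selection_test: str = "welch_t"
    output_scale: tuple[float, float] = (0.0, 10.0)
    bootstrap_reps: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glcm"] = asdict(self.glcm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("glcm"), dict):
            g = {k: tuple(v) if isinstance(v, list) else v for k, v in d["glcm"].items()}
            d["glcm"] = GLCMSpec(**g)
        if isinstance(d.get("output_scale"), list):
            d["output_scale"] = tuple(d["output_scale"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    @property
    def hash(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
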