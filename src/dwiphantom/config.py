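"""Run configuration: one serializable object describing a full simulation."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fixtures import FixtureSpec
from .model import ModelError
from .signal import DiffusivitySet, FiberKernel, NoiseSpec, DEFAULT_S0


@dataclass
class SchemeSpec:
    """Either generate a uniform scheme or read one from files."""

    n_per_shell: list[int] = field(default_factory=lambda: [100])
    bvals: list[float] = field(default_factory=lambda: [1000.0])
    n_b0: int = 1
    restarts: int = 20
    bval_path: str | None = None
    bvec_path: str | None = None
    mrtrix_path: str | None = None


@dataclass
class DistortionSpec:
    enabled: bool = False
    magnitude_mm: float = 6.0
    extent_mm: float = 20.0
    pe_axis: int = 1
    focus_center: list[float] | None = None  # voxel coords; default: grid center


@dataclass
class RunConfig:
    """Everything needed to (re)produce one simulated dataset."""

    subject: str = "01"
    seed: int = 0
    s0: float = DEFAULT_S0
    snr: float = 30.0
    kernel: FiberKernel = field(default_factory=FiberKernel)
    diffusivities: DiffusivitySet = field(default_factory=DiffusivitySet)
    scheme: SchemeSpec = field(default_factory=SchemeSpec)
    fixture: FixtureSpec | None = field(default_factory=FixtureSpec)
    model_manifest: str | None = None
    distortion: DistortionSpec = field(default_factory=DistortionSpec)
    out_dir: str = "phantom_out"
    overwrite: bool = False

    def noise_spec(self, seed: int) -> NoiseSpec:
        return NoiseSpec(snr=self.snr, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(self.snr):
            d["snr"] = "inf"
        if d.get("fixture"):
            d["fixture"]["shape"] = list(d["fixture"]["shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if str(d.get("snr", "")).lower() in ("inf", "infinity"):
            d["snr"] = math.inf
        if "kernel" in d and isinstance(d["kernel"], dict):
            d["kernel"] = FiberKernel(**d["kernel"])
        if "diffusivities" in d and isinstance(d["diffusivities"], dict):
            d["diffusivities"] = DiffusivitySet(**d["diffusivities"])
        if "scheme" in d and isinstance(d["scheme"], dict):
            d["scheme"] = SchemeSpec(**d["scheme"])
        if "distortion" in d and isinstance(d["distortion"], dict):
            d["distortion"] = DistortionSpec(**d["distortion"])
        if d.get("fixture") is not None and isinstance(d["fixture"], dict):
            fx = dict(d["fixture"])
            if "shape" in fx:
                fx["shape"] = tuple(fx["shape"])
            d["fixture"] = FixtureSpec(**fx)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ModelError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
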