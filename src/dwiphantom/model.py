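"""Microstructural model: data containers, validation and assembly.

The voxel-wise model mixes up to five isotropic tissue compartments
(cortical gray matter, deep gray matter, white matter, CSF and an optional
"abnormal" compartment) with up to three restricted fiber compartments,
each carrying a volume fraction map and a unit direction field. Per voxel
the fractions form a convex-combination weight vector: non-negative,
summing to one inside the brain and to zero in the background.

Conventions: voxel indices are 0-based; the world frame is RAS+; fiber
directions are stored as world-frame direction cosines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

TISSUE_NAMES = ("cGM", "dGM", "WM", "CSF", "abnormal")
#: index of each tissue in FractionMaps.T
TISSUE_INDEX = {name: i for i, name in enumerate(TISSUE_NAMES)}

_TOL = 1e-6


class ModelError(ValueError):
    """Structural or validation failure in a microstructural model."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D voxel grid with a voxel-to-world affine (mm, RAS+)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vsz = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vsz)
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", affine)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ModelError(f"shape must be 3 positive ints, got {shape}")
        if any(v <= 0 for v in vsz):
            raise ModelError(f"voxel_size must be positive, got {vsz}")
        if affine.shape != (4, 4):
            raise ModelError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ModelError("affine is singular")
        colnorm = np.linalg.norm(affine[:3, :3], axis=0)
        if not np.allclose(colnorm, vsz, atol=_TOL):
            raise ModelError(
                f"voxel_size {vsz} inconsistent with affine column norms {colnorm}"
            )

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float = 2.0) -> "GridGeometry":
        """Axis-aligned RAS+ grid centered at the world origin."""
        shape = tuple(int(s) for s in shape)
        v = float(voxel_size_mm)
        affine = np.diag([v, v, v, 1.0])
        affine[:3, 3] = -v * (np.asarray(shape) - 1) / 2.0
        return cls(shape=shape, voxel_size=(v, v, v), affine=affine)

    def same_grid(self, other: "GridGeometry") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_TOL
        )


def _zero_vol(shape):
    return np.zeros(shape, dtype=float)


@dataclass
class FractionMaps:
    """Hindered/free tissue fraction maps, ordered cGM, dGM, WM, CSF, abnormal.

    Absent maps are stored as all-zero volumes.
    """

    T: list[np.ndarray]

    @classmethod
    def from_dict(cls, shape, maps: dict[str, np.ndarray]) -> "FractionMaps":
        vols = [_zero_vol(shape) for _ in TISSUE_NAMES]
        for name, vol in maps.items():
            if name not in TISSUE_INDEX:
                raise ModelError(f"unknown tissue {name!r}; expected {TISSUE_NAMES}")
            vols[TISSUE_INDEX[name]] = np.asarray(vol, dtype=float)
        return cls(T=vols)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.T[TISSUE_INDEX[name]]

    def total(self) -> np.ndarray:
        return np.sum(self.T, axis=0)

    def copy(self) -> "FractionMaps":
        return FractionMaps(T=[t.copy() for t in self.T])


@dataclass
class FiberCompartments:
    """Restricted fiber compartments: fraction maps F_i and unit-direction fields V_i."""

    F: list[np.ndarray]
    V: list[np.ndarray]

    def __post_init__(self):
        if len(self.F) != len(self.V):
            raise ModelError("need one direction field per fiber fraction map")
        if len(self.F) > 3:
            raise ModelError("at most 3 fiber compartments supported")

    @classmethod
    def empty(cls, shape, n: int = 3) -> "FiberCompartments":
        return cls(
            F=[_zero_vol(shape) for _ in range(n)],
            V=[np.zeros(tuple(shape) + (3,), dtype=float) for _ in range(n)],
        )

    def total(self) -> np.ndarray:
        if not self.F:
            return 0.0
        return np.sum(self.F, axis=0)

    def copy(self) -> "FiberCompartments":
        return FiberCompartments(
            F=[f.copy() for f in self.F], V=[v.copy() for v in self.V]
        )


@dataclass
class MicrostructuralModel:
    """Complete voxel-wise compartment model on a common grid."""

    geometry: GridGeometry
    tissues: FractionMaps
    fibers: FiberCompartments

    def __post_init__(self):
        shape = self.geometry.shape
        for t in self.tissues.T:
            if t.shape != shape:
                raise ModelError(f"tissue map shape {t.shape} != grid {shape}")
        for f, v in zip(self.fibers.F, self.fibers.V):
            if f.shape != shape:
                raise ModelError(f"fiber fraction shape {f.shape} != grid {shape}")
            if v.shape != shape + (3,):
                raise ModelError(f"direction field shape {v.shape} != {shape + (3,)}")

    def fraction_total(self) -> np.ndarray:
        return self.tissues.total() + self.fibers.total()

    def brain_mask(self, threshold: float = _TOL) -> np.ndarray:
        return self.fraction_total() > threshold

    def copy(self) -> "MicrostructuralModel":
        return MicrostructuralModel(
            geometry=self.geometry,
            tissues=self.tissues.copy(),
            fibers=self.fibers.copy(),
        )


@dataclass
class RawModelInputs:
    """Raw ingredients for model assembly, all on one grid.

    ``raw_fiber_fractions`` are crude per-fiber volume fraction estimates
    (the first is discarded in favor of the FA-derived fraction),
    ``fa_map`` a fractional anisotropy map in [0, 1], and
    ``raw_tissue_fractions`` a macroscopic tissue segmentation.
    """

    geometry: GridGeometry
    raw_fiber_fractions: list[np.ndarray]
    fa_map: np.ndarray
    raw_tissue_fractions: FractionMaps
    directions: list[np.ndarray]


@dataclass
class ValidationReport:
    """Per-invariant violation counts; empty iff the model is valid."""

    violations: list[tuple[str, int]] = field(default_factory=list)

    def add(self, message: str, count: int) -> None:
        if count:
            self.violations.append((message, int(count)))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "model valid: no violations"
        return "\n".join(f"{n} voxel(s): {m}" for m, n in self.violations)


def normalize_fractions(model: MicrostructuralModel) -> MicrostructuralModel:
    """Rescale per-voxel fractions to sum to exactly 1; all-zero voxels untouched.

    Relative proportions between compartments are preserved.
    """
    total = model.fraction_total()
    scale = np.ones_like(total)
    nz = total > _TOL
    scale[nz] = 1.0 / total[nz]
    # below-tolerance residue is zeroed rather than blown up
    out = model.copy()
    for t in out.tissues.T:
        t *= scale
        t[~nz] = 0.0
    for f in out.fibers.F:
        f *= scale
        f[~nz] = 0.0
    return out


def assemble_model(raw: RawModelInputs) -> MicrostructuralModel:
    """Combine raw fiber/tissue fractions and an FA map into the final model.

    Combination rule (see docs/methods.md; a documented stand-in for the
    original derivation, which is not fully specified):

    * ``F_1 = FA * T'_WM``, clipped to [0, 1] — the dominant-fiber fraction
      is inferred from fractional anisotropy rather than from the noisy
      raw estimate.
    * ``F_i = F'_i * T'_WM`` for the secondary fibers (i = 2, 3), preserving
      their relative ratio.
    * If ``sum_i F_i`` exceeds ``T'_WM``, all F_i are rescaled
      proportionally so restricted fractions never exceed the WM fraction.
    * ``T_WM = T'_WM - sum_i F_i``; the other tissue fractions pass through.
    * Finally the per-voxel fractions are normalized to sum to 1 in brain
      voxels.

    Direction fields pass through unchanged.
    """
    shape = raw.geometry.shape
    fa = np.asarray(raw.fa_map, dtype=float)
    if fa.shape != shape:
        raise ModelError(f"FA map shape {fa.shape} != grid {shape}")
    bad_fa = int(np.sum((fa < 0) | (fa > 1)))
    if bad_fa:
        raise ModelError(f"FA outside [0, 1] in {bad_fa} voxel(s)")
    for vol in raw.raw_fiber_fractions:
        if vol.shape != shape:
            raise ModelError("raw fiber fraction grid mismatch")
    for vol in raw.raw_tissue_fractions.T:
        if vol.shape != shape:
            raise ModelError("raw tissue fraction grid mismatch")

    t_wm = raw.raw_tissue_fractions["WM"]
    n_fib = max(len(raw.raw_fiber_fractions), 1)
    n_fib = min(max(n_fib, len(raw.directions)), 3)

    F = [np.zeros(shape) for _ in range(n_fib)]
    F[0] = np.clip(fa * t_wm, 0.0, 1.0)
    for i in range(1, n_fib):
        if i < len(raw.raw_fiber_fractions):
            F[i] = np.clip(raw.raw_fiber_fractions[i], 0.0, 1.0) * t_wm

    fsum = np.sum(F, axis=0)
    over = fsum > t_wm
    if np.any(over):
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(over & (fsum > 0), t_wm / np.maximum(fsum, _TOL), 1.0)
        for f in F:
            f *= factor
        fsum = np.sum(F, axis=0)

    tissues = raw.raw_tissue_fractions.copy()
    tissues.T[TISSUE_INDEX["WM"]] = np.maximum(t_wm - fsum, 0.0)

    V = []
    for i in range(n_fib):
        if i < len(raw.directions):
            V.append(np.asarray(raw.directions[i], dtype=float).copy())
        else:
            V.append(np.zeros(shape + (3,)))
        # zero out directions where the compartment vanished
        V[i][F[i] <= _TOL] = 0.0

    model = MicrostructuralModel(
        geometry=raw.geometry,
        tissues=tissues,
        fibers=FiberCompartments(F=F, V=V),
    )
    return normalize_fractions(model)


def validate_model(
    model: MicrostructuralModel, require_normalized: bool = True
) -> ValidationReport:
    """Check every container invariant, reporting per-violation voxel counts."""
    report = ValidationReport()
    for name, t in zip(TISSUE_NAMES, model.tissues.T):
        report.add(
            f"tissue {name}: fraction outside [0, 1]",
            np.sum((t < -_TOL) | (t > 1 + _TOL)),
        )
    for i, (f, v) in enumerate(zip(model.fibers.F, model.fibers.V), start=1):
        report.add(
            f"fiber F{i}: fraction outside [0, 1]",
            np.sum((f < -_TOL) | (f > 1 + _TOL)),
        )
        norms = np.linalg.norm(v, axis=-1)
        active = f > _TOL
        report.add(
            f"fiber V{i}: non-unit direction where F{i} > 0",
            np.sum(active & (np.abs(norms - 1.0) > _TOL)),
        )
    total = model.fraction_total()
    report.add("fraction sum exceeds 1", np.sum(total > 1 + _TOL))
    if require_normalized:
        report.add(
            "fraction sum neither 0 nor 1 (unnormalized voxel)",
            np.sum((total > _TOL) & (np.abs(total - 1.0) > _TOL)),
        )
    return report
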