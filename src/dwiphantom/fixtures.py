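"""Synthetic microstructural models for testing and simulation.

Three generators of increasing complexity:

* ``make_single_voxel`` — a 1x1x1 model with an exact requested composition,
  the workhorse for closed-form signal checks.
* ``make_crossing_slab`` — two straight fiber bundles crossing at a
  configurable angle inside a WM-filled block, emulating the classic
  crossing-fiber benchmark geometry.
* ``make_mini_brain`` — a concentric head-like layout (cGM shell, WM
  interior, central CSF "ventricle", two dGM nuclei) threaded by a straight
  and an arc-shaped fiber bundle.

All fixtures are pure functions of their spec and pass ``validate_model``
with an empty report. Bundle cross-sections use a cosine taper so fiber
fractions fall off smoothly at bundle borders (partial-volume-like edges)
instead of hard steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    FiberCompartments,
    FractionMaps,
    GridGeometry,
    MicrostructuralModel,
    ModelError,
    TISSUE_INDEX,
    TISSUE_NAMES,
    normalize_fractions,
)

DEFAULT_VOXEL_MM = 2.0

_FIBER_KEYS = ("F1", "F2", "F3")


@dataclass
class FixtureSpec:
    """Parameters for a synthetic model fixture."""

    kind: str = "mini_brain"
    shape: tuple[int, int, int] = (32, 32, 32)
    crossing_angle: float = 60.0  # degrees, crossing_slab only
    fractions: dict = field(default_factory=dict)
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.kind == "crossing_slab" and not (0.0 < self.crossing_angle <= 90.0):
            raise ModelError(
                f"crossing_angle must be in (0, 90], got {self.crossing_angle}"
            )


def make_fixture(spec: FixtureSpec) -> MicrostructuralModel:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "single_voxel":
        fractions = dict(spec.fractions) or {"WM": 1.0}
        directions = {k: (0.0, 0.0, 1.0) for k in _FIBER_KEYS if k in fractions}
        return make_single_voxel(fractions, directions, voxel_size_mm=spec.voxel_size_mm)
    if spec.kind == "crossing_slab":
        return make_crossing_slab(spec)
    if spec.kind == "mini_brain":
        return make_mini_brain(spec)
    raise ModelError(f"unknown fixture kind {spec.kind!r}")


def make_single_voxel(
    fractions: dict,
    directions: dict | None = None,
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
) -> MicrostructuralModel:
    """1x1x1 model with exactly the requested composition, normalized.

    Parameters
    ----------
    fractions
        Mapping of compartment name to volume fraction. Tissue keys are
        ``cGM, dGM, WM, CSF, abnormal``; fiber keys are ``F1, F2, F3``.
    directions
        Mapping of fiber key to a unit 3-vector; required for every fiber
        with a nonzero fraction.
    """
    directions = directions or {}
    geom = GridGeometry.isotropic((1, 1, 1), voxel_size_mm)
    tissues = FractionMaps.from_dict(geom.shape, {})
    fibers = FiberCompartments.empty(geom.shape)
    total = 0.0
    for key, frac in fractions.items():
        frac = float(frac)
        if frac < 0:
            raise ModelError(f"negative fraction for {key}")
        total += frac
        if key in TISSUE_INDEX:
            tissues.T[TISSUE_INDEX[key]][...] = frac
        elif key in _FIBER_KEYS:
            i = _FIBER_KEYS.index(key)
            fibers.F[i][...] = frac
            if frac > 0:
                if key not in directions:
                    raise ModelError(f"fiber {key} has no direction")
                v = np.asarray(directions[key], dtype=float)
                n = np.linalg.norm(v)
                if not np.isclose(n, 1.0, atol=1e-6):
                    raise ModelError(f"direction for {key} is not unit (|v|={n:.4f})")
                fibers.V[i][...] = v
        else:
            raise ModelError(f"unknown compartment {key!r}")
    if total > 1.0 + 1e-6:
        raise ModelError(f"fractions sum to {total:.4f} > 1")
    model = MicrostructuralModel(geometry=geom, tissues=tissues, fibers=fibers)
    return normalize_fractions(model)


def _cosine_taper(dist: np.ndarray, radius: float, edge: float) -> np.ndarray:
    """1 inside ``radius - edge``, smooth cosine falloff to 0 at ``radius``."""
    inner = radius - edge
    w = np.zeros_like(dist)
    w[dist <= inner] = 1.0
    ramp = (dist > inner) & (dist < radius)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (dist[ramp] - inner) / edge))
    return w


def _smoothstep(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Cosine smoothstep: 0 below ``lo``, 1 above ``hi``."""
    t = np.clip((x - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def make_crossing_slab(spec: FixtureSpec) -> MicrostructuralModel:
    """Two straight bundles crossing at ``spec.crossing_angle`` in the center.

    Both bundles lie in the x-y plane and pass through the grid center;
    they carry fractions F1 and F2 with cosine-tapered cross-sections. The
    hindered WM compartment fills the remainder, so every voxel sums to 1.
    """
    if any(s < 8 for s in spec.shape):
        raise ModelError(f"crossing_slab needs shape >= 8 per axis, got {spec.shape}")
    if not (0.0 < spec.crossing_angle <= 90.0):
        raise ModelError(f"crossing_angle must be in (0, 90], got {spec.crossing_angle}")
    geom = GridGeometry.isotropic(spec.shape, spec.voxel_size_mm)
    shape = geom.shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )
    rel = idx - center  # voxel units

    half = np.deg2rad(spec.crossing_angle) / 2.0
    dirs = [
        np.array([np.cos(half), np.sin(half), 0.0]),
        np.array([np.cos(half), -np.sin(half), 0.0]),
    ]
    peak = float(spec.fractions.get("fiber_peak", 0.45))
    radius = max(2.0, min(shape) / 5.0)

    fibers = FiberCompartments.empty(shape)
    for i, d in enumerate(dirs):
        along = rel @ d
        perp = rel - along[..., None] * d
        dist = np.linalg.norm(perp, axis=-1)
        w = _cosine_taper(dist, radius, edge=radius / 2.0)
        fibers.F[i] = peak * w
        fibers.V[i][w > 0] = d

    tissues = FractionMaps.from_dict(shape, {})
    tissues.T[TISSUE_INDEX["WM"]] = 1.0 - fibers.total()
    model = MicrostructuralModel(geometry=geom, tissues=tissues, fibers=fibers)
    return normalize_fractions(model)


def make_mini_brain(spec: FixtureSpec) -> MicrostructuralModel:
    """Concentric head-like fixture with two fiber bundles.

    Layout (radii relative to head radius R = 0.45 * min(shape)): a crisp
    spherical head boundary; a ~2.5-voxel cortical GM shell; a central CSF
    sphere (0.15 R); two deep-GM nuclei (0.18 R) offset along x; hindered
    WM filling the rest. A straight bundle runs along x and an arc bundle
    follows a half-circle in the axial plane, its direction field tangent
    to the arc. Fiber fractions carve into the local WM fraction so the
    per-voxel sum stays 1 inside the head and 0 outside.
    """
    if any(s < 24 for s in spec.shape):
        raise ModelError(f"mini_brain needs shape >= 24 per axis, got {spec.shape}")
    geom = GridGeometry.isotropic(spec.shape, spec.voxel_size_mm)
    shape = geom.shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )
    rel = idx - center
    r = np.linalg.norm(rel, axis=-1)

    R = 0.45 * min(shape)
    head = r <= R

    # partition of unity inside the head
    w_cgm = _smoothstep(r, R - 2.5, R - 0.5)
    interior = 1.0 - w_cgm
    u_csf = 1.0 - _smoothstep(r, 0.15 * R, 0.15 * R + 1.5)
    nuclei_centers = [center + np.array([0.35 * R, 0.0, 0.0]),
                      center - np.array([0.35 * R, 0.0, 0.0])]
    u_dgm = np.zeros(shape)
    for nc in nuclei_centers:
        d = np.linalg.norm(idx - nc, axis=-1)
        u_dgm = np.maximum(u_dgm, 1.0 - _smoothstep(d, 0.18 * R, 0.18 * R + 1.5))

    t_csf = interior * u_csf
    t_dgm = interior * (1.0 - u_csf) * u_dgm
    t_wm = interior * (1.0 - u_csf) * (1.0 - u_dgm)

    # fiber bundles carved out of the WM fraction
    fibers = FiberCompartments.empty(shape)
    tube = max(1.5, 0.12 * R)

    # straight bundle along x, offset below the ventricle
    offset = np.array([0.0, 0.0, -0.35 * R])
    perp = rel - offset
    perp[..., 0] = 0.0
    dist_straight = np.linalg.norm(perp, axis=-1)
    a1 = 0.85 * _cosine_taper(dist_straight, tube + 1.5, edge=1.5)

    # arc bundle: half-circle of radius 0.6 R in the axial (z = center) plane
    r_arc = 0.6 * R
    rho = np.linalg.norm(rel[..., :2], axis=-1)
    dist_arc = np.sqrt((rho - r_arc) ** 2 + rel[..., 2] ** 2)
    a2 = 0.85 * _cosine_taper(dist_arc, tube + 1.5, edge=1.5)
    a2[rel[..., 1] < 0] = 0.0  # keep only the y >= 0 half: an arc, not a ring

    fibers.F[0] = a1 * t_wm
    fibers.F[1] = a2 * t_wm
    fibers.V[0][a1 > 0] = np.array([1.0, 0.0, 0.0])
    # tangent to the circle: (-y, x, 0) / rho
    with np.errstate(invalid="ignore", divide="ignore"):
        tang = np.stack(
            [-rel[..., 1] / rho, rel[..., 0] / rho, np.zeros(shape)], axis=-1
        )
    tang[rho < 1e-9] = np.array([1.0, 0.0, 0.0])
    sel = fibers.F[1] > 0
    fibers.V[1][sel] = tang[sel]

    t_wm = t_wm - fibers.F[0] - fibers.F[1]

    tissues = FractionMaps.from_dict(shape, {})
    tissues.T[TISSUE_INDEX["cGM"]] = w_cgm
    tissues.T[TISSUE_INDEX["dGM"]] = t_dgm
    tissues.T[TISSUE_INDEX["WM"]] = np.maximum(t_wm, 0.0)
    tissues.T[TISSUE_INDEX["CSF"]] = t_csf

    for t in tissues.T:
        t[~head] = 0.0
    for f in fibers.F:
        f[~head] = 0.0
    for v in fibers.V:
        v[~head] = 0.0

    model = MicrostructuralModel(geometry=geom, tissues=tissues, fibers=fibers)
    return normalize_fractions(model)
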