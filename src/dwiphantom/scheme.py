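"""Gradient sampling schemes: uniform-coverage generation and table I/O.

Directions are optimized per shell by minimizing the antipodally symmetric
electrostatic (Coulomb) energy

    E = sum_{i<j} 1/|v_i - v_j| + 1/|v_i + v_j|

which treats each direction and its antipode as one electrode pair — the
standard criterion for "uniform coverage" of diffusion gradient tables.
Optimization runs projected L-BFGS from several seeded random starts and
keeps the lowest-energy solution, so generation is deterministic given the
seed.

Supported table dialects: FSL (separate bval/bvec text files, bvec as 3
rows) and MRtrix (single 4-column ``x y z b`` table, ``#`` comments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

_UNIT_TOL = 1e-6


class SchemeError(ValueError):
    """Malformed gradient scheme or table."""


@dataclass
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Zero vectors are allowed (and conventional) on b=0 volumes only.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise SchemeError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise SchemeError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > _UNIT_TOL):
            raise SchemeError("non-unit gradient direction on a b > 0 volume")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def shells(self) -> dict[float, np.ndarray]:
        """Indices of the volumes in each nonzero shell, keyed by b-value."""
        out: dict[float, np.ndarray] = {}
        for b in np.unique(self.bvals[self.dwi_mask]):
            out[float(b)] = np.flatnonzero(self.bvals == b)
        return out


def electrostatic_energy(points: np.ndarray) -> float:
    """Antipodal Coulomb energy of a set of unit vectors."""
    p = np.asarray(points, dtype=float)
    iu = np.triu_indices(len(p), 1)
    dd = np.linalg.norm(p[iu[0]] - p[iu[1]], axis=1)
    ds = np.linalg.norm(p[iu[0]] + p[iu[1]], axis=1)
    return float(np.sum(1.0 / dd) + np.sum(1.0 / ds))


def minimal_antipodal_angle(points: np.ndarray) -> float:
    """Smallest pairwise angle (degrees) treating v and -v as identical."""
    p = np.asarray(points, dtype=float)
    dots = np.abs(p @ p.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))


def _energy_and_grad(x: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    p = x.reshape(n, 3)
    r = np.linalg.norm(p, axis=1, keepdims=True)
    u = p / r
    diff = u[:, None, :] - u[None, :, :]
    sums = u[:, None, :] + u[None, :, :]
    dd = np.linalg.norm(diff, axis=2)
    ds = np.linalg.norm(sums, axis=2)
    iu = np.triu_indices(n, 1)
    energy = np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu])
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    gu = -(diff / dd[..., None] ** 3).sum(axis=1) - (sums / ds[..., None] ** 3).sum(
        axis=1
    )
    # project onto the tangent space of the sphere, chain rule through u = p/|p|
    gx = (gu - np.sum(gu * u, axis=1, keepdims=True) * u) / r
    return float(energy), gx.ravel()


def uniform_directions(n: int, seed: int = 0, restarts: int = 20) -> np.ndarray:
    """n unit vectors minimizing the antipodal electrostatic energy.

    Deterministic given ``seed``; the best of ``restarts`` L-BFGS runs from
    random starting configurations is returned.
    """
    if n < 1:
        raise SchemeError("need at least one direction")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    best = None
    best_e = np.inf
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        x0 = rng.standard_normal(n * 3)
        res = minimize(
            _energy_and_grad,
            x0,
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res.fun < best_e:
            best_e = res.fun
            best = res.x
    p = best.reshape(n, 3)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    # canonical hemisphere (z >= 0) for reproducible sign conventions
    flip = p[:, 2] < 0
    p[flip] *= -1.0
    return p


def generate_uniform_scheme(
    n_per_shell,
    bvals,
    n_b0: int = 1,
    seed: int = 0,
    restarts: int = 20,
) -> GradientScheme:
    """Uniform-coverage single- or multi-shell scheme.

    ``n_b0`` non-weighted volumes are placed first, then each shell in the
    order given. The default protocol is a single shell of 100 directions
    at b = 1000 s/mm^2 plus one b=0 volume.
    """
    n_per_shell = [int(n) for n in np.atleast_1d(n_per_shell)]
    bvals = [float(b) for b in np.atleast_1d(bvals)]
    if len(n_per_shell) != len(bvals):
        raise SchemeError("need one direction count per shell b-value")
    if any(n < 1 for n in n_per_shell):
        raise SchemeError("shell direction counts must be >= 1")
    if any(b <= 0 for b in bvals):
        raise SchemeError("shell b-values must be > 0")
    if len(set(bvals)) != len(bvals):
        raise SchemeError(f"shell b-values must be distinct, got {bvals}")
    if n_b0 < 0:
        raise SchemeError("n_b0 must be >= 0")

    all_b = [np.zeros(n_b0)]
    all_v = [np.zeros((n_b0, 3))]
    for k, (n, b) in enumerate(zip(n_per_shell, bvals)):
        all_b.append(np.full(n, b))
        all_v.append(uniform_directions(n, seed=seed + k, restarts=restarts))
    return GradientScheme(bvals=np.concatenate(all_b), bvecs=np.vstack(all_v))


def default_scheme(seed: int = 0, restarts: int = 20) -> GradientScheme:
    """The default protocol: 100 directions on one b=1000 shell + 1 b=0."""
    return generate_uniform_scheme([100], [1000.0], n_b0=1, seed=seed, restarts=restarts)


# ---------------------------------------------------------------------------
# table I/O


def write_fsl_scheme(scheme: GradientScheme) -> tuple[str, str]:
    """Serialize to FSL dialect: one bval line, three bvec lines."""
    bval_text = " ".join(f"{b:.6g}" for b in scheme.bvals) + "\n"
    rows = []
    for axis in range(3):
        rows.append(" ".join(f"{v:.8f}" for v in scheme.bvecs[:, axis]))
    return bval_text, "\n".join(rows) + "\n"


def read_fsl_scheme(bval_text: str, bvec_text: str) -> GradientScheme:
    """Parse FSL bval/bvec text; bvec orientation (3xN or Nx3) auto-detected."""
    bvals = np.array([float(t) for t in bval_text.split()])
    rows = [
        [float(t) for t in line.split()]
        for line in bvec_text.strip().splitlines()
        if line.strip()
    ]
    arr = np.array(rows, dtype=float)
    if arr.ndim != 2:
        raise SchemeError("bvec text is not a 2D table")
    n = bvals.size
    if arr.shape == (3, 3):
        arr = arr.T  # ambiguous; FSL row convention wins
    elif arr.shape[0] == 3 and arr.shape[1] != 3:
        arr = arr.T
    if arr.shape[1] != 3 or arr.shape[0] != n:
        raise SchemeError(
            f"bvec table with {arr.shape[0]} vectors does not match {n} b-values"
        )
    return GradientScheme(bvals=bvals, bvecs=arr)


def write_mrtrix_scheme(scheme: GradientScheme) -> str:
    """Serialize to the MRtrix 4-column gradient table (x y z b)."""
    lines = ["# x y z b"]
    for (x, y, z), b in zip(scheme.bvecs, scheme.bvals):
        lines.append(f"{x:.8f} {y:.8f} {z:.8f} {b:.6g}")
    return "\n".join(lines) + "\n"


def read_mrtrix_scheme(grad_text: str) -> GradientScheme:
    """Parse an MRtrix gradient table; ``#`` starts a comment line."""
    rows = []
    for line in grad_text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        vals = [float(t) for t in line.replace(",", " ").split()]
        if len(vals) != 4:
            raise SchemeError(
                f"gradient table row has {len(vals)} columns, expected 4: {line!r}"
            )
        rows.append(vals)
    if not rows:
        raise SchemeError("empty gradient table")
    arr = np.array(rows, dtype=float)
    return GradientScheme(bvals=arr[:, 3], bvecs=arr[:, :3])
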