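"""Multi-compartment diffusion signal synthesis with Rician noise.

Per voxel the noise-free signal is the convex mixture

    S(g, b) = s0 * [ sum_i F_i exp(-b (l_perp + (l_par - l_perp)(g.v_i)^2))
                   + sum_j T_j exp(-b D_j) ]

with restricted fiber compartments modeled by an axially symmetric Gaussian
tensor kernel (axial diffusivity l_par, radial l_perp) and hindered/free
tissue compartments by mono-exponential isotropic decay. The defaults are
l_par = 2.2e-3, l_perp = 0.2e-3 mm^2/s for the fiber kernel and
D_WM = 2.0e-4, D_cGM = 7.0e-4, D_dGM = 9.0e-4, D_CSF = 3.0e-3 mm^2/s for the
isotropic compartments; all are user-configurable.

Fiber compartments can alternatively be represented as a fiber orientation
distribution (FOD) in the real even spherical-harmonic basis and convolved
with the kernel's rotational harmonics; the discrete tensor sum is exact and
is the default path, the FOD path matching it to truncation error.

Rician noise: each sample is replaced by sqrt((S + n1)^2 + n2^2) with n1, n2
independent N(0, sigma), sigma = mean in-brain b=0 signal / SNR
(default SNR 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import sh
from .model import GridGeometry, MicrostructuralModel, TISSUE_NAMES
from .scheme import GradientScheme

DEFAULT_S0 = 1000.0
_UNIT_TOL = 1e-6


class SignalError(ValueError):
    """Invalid simulation inputs or configuration."""


@dataclass(frozen=True)
class FiberKernel:
    """Axially symmetric Gaussian single-fiber response (mm^2/s)."""

    lambda_par: float = 2.2e-3
    lambda_perp: float = 0.2e-3

    def __post_init__(self):
        if not (self.lambda_par >= self.lambda_perp > 0):
            raise SignalError(
                f"need lambda_par >= lambda_perp > 0, got "
                f"({self.lambda_par}, {self.lambda_perp})"
            )

    @property
    def delta(self) -> float:
        return self.lambda_par - self.lambda_perp


@dataclass(frozen=True)
class DiffusivitySet:
    """Isotropic diffusivities of the hindered and free compartments (mm^2/s).

    ``D_abnormal`` has no default and must be supplied if the abnormal
    tissue compartment is populated.
    """

    D_WM: float = 2.0e-4
    D_cGM: float = 7.0e-4
    D_dGM: float = 9.0e-4
    D_CSF: float = 3.0e-3
    D_abnormal: float | None = None

    def __post_init__(self):
        for name in ("D_WM", "D_cGM", "D_dGM", "D_CSF"):
            if getattr(self, name) <= 0:
                raise SignalError(f"{name} must be > 0")
        if self.D_abnormal is not None and self.D_abnormal <= 0:
            raise SignalError("D_abnormal must be > 0")

    def for_tissue(self, name: str) -> float | None:
        """Diffusivity for a tissue-map name (cGM, dGM, WM, CSF, abnormal)."""
        return {
            "cGM": self.D_cGM,
            "dGM": self.D_dGM,
            "WM": self.D_WM,
            "CSF": self.D_CSF,
            "abnormal": self.D_abnormal,
        }[name]


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level: SNR = mean in-brain b0 / Gaussian sigma."""

    snr: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (self.snr > 0):
            raise SignalError(f"snr must be > 0 (use math.inf for noise-free), got {self.snr}")

    @property
    def noise_free(self) -> bool:
        return math.isinf(self.snr)


@dataclass
class DiffusionVolume:
    """4D diffusion-weighted dataset tied to its geometry and scheme."""

    data: np.ndarray
    geometry: GridGeometry
    scheme: GradientScheme
    s0: float = DEFAULT_S0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != len(self.scheme):
            raise SignalError(
                f"data shape {self.data.shape} does not match scheme length "
                f"{len(self.scheme)}"
            )
        if np.any(self.data < 0):
            raise SignalError("negative signal values")

    def b0_mean(self) -> np.ndarray:
        """Mean over the b=0 volumes, per voxel."""
        return self.data[..., self.scheme.b0_mask].mean(axis=-1)


@dataclass
class FodField:
    """Per-voxel real even-SH coefficients of the fiber orientation distribution."""

    coefficients: np.ndarray  # (..., n_coef)
    max_order: int

    def __post_init__(self):
        n = sh.n_coefficients(self.max_order)
        if self.coefficients.shape[-1] != n:
            raise SignalError(
                f"expected {n} SH coefficients for order {self.max_order}, "
                f"got {self.coefficients.shape[-1]}"
            )


def _check_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise SignalError(f"{name} must be a unit vector")
    return v


def fiber_attenuation(kernel: FiberKernel, v, g, b: float) -> float:
    """Attenuation of one fiber compartment: exp(-b (l_perp + delta (g.v)^2))."""
    if b < 0:
        raise SignalError("b must be >= 0")
    if b == 0:
        return 1.0
    v = _check_unit(v, "fiber direction v")
    g = _check_unit(g, "gradient direction g")
    c = float(np.dot(g, v))
    return math.exp(-b * (kernel.lambda_perp + kernel.delta * c * c))


def isotropic_attenuation(D: float, b: float) -> float:
    """Mono-exponential isotropic decay exp(-b D)."""
    if D <= 0:
        raise SignalError("diffusivity must be > 0")
    if b < 0:
        raise SignalError("b must be >= 0")
    return math.exp(-b * D)


def voxel_signal(
    tissue_fractions: dict,
    fiber_fractions,
    fiber_directions,
    scheme: GradientScheme,
    kernel: FiberKernel | None = None,
    diffusivities: DiffusivitySet | None = None,
    s0: float = DEFAULT_S0,
) -> np.ndarray:
    """Noise-free signal vector of one voxel across all scheme volumes.

    ``tissue_fractions`` maps tissue names to fractions; fiber compartments
    are given as parallel sequences of fractions and unit directions.
    """
    kernel = kernel or FiberKernel()
    diffusivities = diffusivities or DiffusivitySet()
    b = scheme.bvals
    g = scheme.bvecs
    signal = np.zeros(len(scheme))
    for name, frac in tissue_fractions.items():
        if frac == 0:
            continue
        D = diffusivities.for_tissue(name)
        if D is None:
            raise SignalError(
                f"compartment {name!r} present but no diffusivity configured"
            )
        signal += frac * np.exp(-b * D)
    for frac, v in zip(fiber_fractions, fiber_directions):
        if frac == 0:
            continue
        v = _check_unit(v, "fiber direction")
        c = g @ v
        signal += frac * np.exp(-b * (kernel.lambda_perp + kernel.delta * c * c))
    return s0 * signal


def simulate_volume(
    model: MicrostructuralModel,
    scheme: GradientScheme,
    kernel: FiberKernel | None = None,
    diffusivities: DiffusivitySet | None = None,
    s0: float = DEFAULT_S0,
) -> DiffusionVolume:
    """Noise-free 4D simulation: ``voxel_signal`` applied over the grid.

    Fully vectorized: each compartment contributes its attenuation weighted
    by its fraction map; the result is deterministic.
    """
    kernel = kernel or FiberKernel()
    diffusivities = diffusivities or DiffusivitySet()
    b = scheme.bvals
    g = scheme.bvecs
    shape = model.geometry.shape
    data = np.zeros(shape + (len(scheme),))

    for name, tmap in zip(TISSUE_NAMES, model.tissues.T):
        if not np.any(tmap > 0):
            continue
        D = diffusivities.for_tissue(name)
        if D is None:
            idx = tuple(np.argwhere(tmap > 0)[0])
            raise SignalError(
                f"tissue {name!r} present (e.g. voxel {idx}) but no "
                "diffusivity configured"
            )
        data += tmap[..., None] * np.exp(-b * D)[None, None, None, :]

    for fmap, vmap in zip(model.fibers.F, model.fibers.V):
        if not np.any(fmap > 0):
            continue
        # cos angle between every voxel direction and every gradient
        c = np.einsum("xyzk,nk->xyzn", vmap, g)
        att = np.exp(-b * kernel.lambda_perp - (b * kernel.delta) * c**2)
        data += fmap[..., None] * att

    data *= s0
    # background voxels (all fractions zero) must be exactly zero
    data[~model.brain_mask(0.0)] = 0.0
    return DiffusionVolume(data=data, geometry=model.geometry, scheme=scheme, s0=s0)


# ---------------------------------------------------------------------------
# FOD path


def project_fod(fiber_fractions, fiber_directions, max_order: int = 8) -> np.ndarray:
    """SH coefficients of the FOD: sum_i F_i * antipodal delta at V_i.

    The antipodally symmetrized delta has exactly the even-degree SH
    coefficients Y_lm(V_i), so the projection is a weighted sum of basis
    evaluations. The integral of the truncated FOD over the sphere equals
    sum_i F_i exactly (only the l=0 term contributes).
    """
    if max_order % 2 != 0 or max_order < 4:
        raise SignalError(f"max_order must be even and >= 4, got {max_order}")
    coeffs = np.zeros(sh.n_coefficients(max_order))
    for frac, v in zip(fiber_fractions, fiber_directions):
        if frac == 0:
            continue
        v = _check_unit(v, "fiber direction")
        coeffs += frac * sh.real_sh_basis(max_order, v)[0]
    return coeffs


def project_fod_field(model: MicrostructuralModel, max_order: int = 8) -> FodField:
    """Voxel-wise FOD projection of a model's fiber compartments."""
    if max_order % 2 != 0 or max_order < 4:
        raise SignalError(f"max_order must be even and >= 4, got {max_order}")
    shape = model.geometry.shape
    coeffs = np.zeros(shape + (sh.n_coefficients(max_order),))
    for fmap, vmap in zip(model.fibers.F, model.fibers.V):
        active = fmap > 0
        if not np.any(active):
            continue
        basis = sh.real_sh_basis(max_order, vmap[active])
        coeffs[active] += fmap[active][:, None] * basis
    return FodField(coefficients=coeffs, max_order=max_order)


def kernel_response_harmonics(
    kernel: FiberKernel, b: float, max_order: int
) -> np.ndarray:
    """Rotational harmonic transform of the fiber kernel at one b-value."""
    def radial(t):
        return np.exp(-b * (kernel.lambda_perp + kernel.delta * t**2))

    return sh.kernel_rotational_harmonics(radial, max_order)


def signal_from_fod(
    fod_coeffs: np.ndarray,
    kernel: FiberKernel,
    scheme: GradientScheme,
    max_order: int = 8,
) -> np.ndarray:
    """Fiber signal via spherical convolution of the FOD with the kernel.

    Attenuation only (multiply by s0 externally); agrees with the discrete
    tensor sum up to SH truncation error. b=0 volumes return the total
    fiber fraction (integral of the FOD).
    """
    fod_coeffs = np.asarray(fod_coeffs, dtype=float)
    if fod_coeffs.shape[-1] != sh.n_coefficients(max_order):
        raise SignalError(
            f"FOD coefficient count {fod_coeffs.shape[-1]} does not match "
            f"order {max_order}"
        )
    out = np.zeros(fod_coeffs.shape[:-1] + (len(scheme),))
    total_fraction = fod_coeffs[..., 0] * np.sqrt(4.0 * np.pi)
    for vol in np.flatnonzero(scheme.b0_mask):
        out[..., vol] = total_fraction
    for bval, idx in scheme.shells().items():
        rh = kernel_response_harmonics(kernel, bval, max_order)
        weights = sh.convolution_weights(rh, max_order)
        basis = sh.real_sh_basis(max_order, scheme.bvecs[idx])  # (nidx, ncoef)
        out[..., idx] = (fod_coeffs * weights) @ basis.T
    return out


# ---------------------------------------------------------------------------
# noise


def add_rician_noise(
    volume: DiffusionVolume,
    noise: NoiseSpec,
    brain_mask: np.ndarray | None = None,
) -> DiffusionVolume:
    """Corrupt a noise-free volume with Rician noise at the requested SNR.

    sigma is the mean noise-free b=0 intensity over in-brain voxels
    (fraction sum > 0.5, i.e. b0 > 0.5 s0 when ``brain_mask`` is not given)
    divided by the SNR. Deterministic given ``noise.seed``.
    """
    if noise.noise_free:
        return DiffusionVolume(
            data=volume.data.copy(),
            geometry=volume.geometry,
            scheme=volume.scheme,
            s0=volume.s0,
        )
    b0 = volume.b0_mean()
    if brain_mask is None:
        brain_mask = b0 > 0.5 * volume.s0
    if not np.any(brain_mask):
        raise SignalError("no in-brain b0 voxels: cannot calibrate noise sigma")
    sigma = float(b0[brain_mask].mean()) / noise.snr
    rng = np.random.default_rng(noise.seed)
    n1 = rng.normal(0.0, sigma, size=volume.data.shape)
    n2 = rng.normal(0.0, sigma, size=volume.data.shape)
    noisy = np.sqrt((volume.data + n1) ** 2 + n2**2)
    return DiffusionVolume(
        data=noisy, geometry=volume.geometry, scheme=volume.scheme, s0=volume.s0
    )
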