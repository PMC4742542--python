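"""Real even-order spherical harmonics for FOD representation.

The basis is the orthonormal real SH set restricted to even degrees l
(antipodally symmetric functions), indexed (l, m) with l = 0, 2, ..., L and
m = -l..l, giving (L+1)(L+2)/2 coefficients. Real parts/imaginary parts of
the complex harmonics with the Condon-Shortley phase folded in, so the
basis is orthonormal on the sphere.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y
from numpy.polynomial.legendre import leggauss, legval


def sh_index_list(max_order: int) -> list[tuple[int, int]]:
    """(l, m) pairs of the even real SH basis up to degree ``max_order``."""
    if max_order % 2 != 0:
        raise ValueError(f"max order must be even, got {max_order}")
    return [(l, m) for l in range(0, max_order + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(max_order: int) -> int:
    return (max_order + 1) * (max_order + 2) // 2


def _to_angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(dirs, dtype=float)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    theta = np.arccos(np.clip(d[..., 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[..., 1], d[..., 0])  # azimuth
    return theta, phi


def real_sh_basis(max_order: int, dirs: np.ndarray) -> np.ndarray:
    """Design matrix of the real even SH basis at unit directions.

    Returns an array of shape ``(len(dirs), n_coefficients(max_order))``.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta, phi = _to_angles(dirs)
    cols = []
    for l, m in sh_index_list(max_order):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.stack(cols, axis=-1)


def kernel_rotational_harmonics(
    radial_fn, max_order: int, n_quad: int = 64
) -> np.ndarray:
    """m=0 SH coefficients of an axially symmetric kernel ``radial_fn(cos t)``.

    ``radial_fn`` maps the cosine of the angle to the kernel value; the
    returned vector k_l (even l) satisfies
    ``K(g . v) = sum_l k_l * sqrt((2l+1)/(4 pi)) P_l(g . v)`` and drives
    the spherical convolution theorem
    ``(K * F)_{lm} = sqrt(4 pi / (2l+1)) k_l f_{lm}``.
    """
    t, w = leggauss(n_quad)
    vals = radial_fn(t)
    ks = []
    for l in range(0, max_order + 1, 2):
        coeffs = np.zeros(l + 1)
        coeffs[l] = 1.0
        pl = legval(t, coeffs)
        norm = np.sqrt((2 * l + 1) / (4.0 * np.pi))
        ks.append(2.0 * np.pi * norm * np.sum(w * vals * pl))
    return np.array(ks)


def convolution_weights(kernel_rh: np.ndarray, max_order: int) -> np.ndarray:
    """Expand per-degree convolution factors to the full coefficient vector."""
    out = np.empty(n_coefficients(max_order))
    pos = 0
    for i, l in enumerate(range(0, max_order + 1, 2)):
        factor = np.sqrt(4.0 * np.pi / (2 * l + 1)) * kernel_rh[i]
        out[pos : pos + 2 * l + 1] = factor
        pos += 2 * l + 1
    return out
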