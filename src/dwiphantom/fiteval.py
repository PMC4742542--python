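"""Self-validation estimators: tensor fit, FA, ADC and SNR.

These estimators close the loop on the simulator: a noise-free
single-compartment voxel must return exactly the generating parameters
(the generative model is itself a Gaussian tensor or a mono-exponential),
and the SNR estimate of a noisy volume must match the configured SNR.

The tensor fit is unweighted log-linear ordinary least squares on
-ln(S/s0) = b g^T D g, which is exact for noise-free tensor signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scheme import GradientScheme
from .signal import DiffusionVolume

_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


class EstimationError(ValueError):
    """Estimator preconditions violated (rank deficiency, empty masks, ...)."""


@dataclass
class TensorFit:
    """Symmetric diffusion tensor with sorted eigendecomposition (mm^2/s)."""

    tensor: np.ndarray  # (3, 3) symmetric
    eigenvalues: np.ndarray  # descending
    principal_direction: np.ndarray  # unit vector

    @property
    def md(self) -> float:
        """Mean diffusivity."""
        return float(self.eigenvalues.mean())

    @property
    def fa(self) -> float:
        return fa(self.eigenvalues)


def fit_tensor_loglinear(
    signal: np.ndarray, scheme: GradientScheme, s0: float
) -> TensorFit:
    """Ordinary least-squares tensor fit on the log signal.

    Uses only b > 0 volumes; requires at least 6 of them spanning a
    full-rank quadratic design. Negative eigenvalues are returned as-is
    (clamping is applied only inside :func:`fa`).
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != len(scheme):
        raise EstimationError("signal length does not match scheme")
    dw = scheme.dwi_mask
    if dw.sum() < 6:
        raise EstimationError("need at least 6 diffusion-weighted volumes")
    if np.any(signal[dw] <= 0):
        raise EstimationError("non-positive diffusion-weighted signal; cannot take log")
    g = scheme.bvecs[dw]
    b = scheme.bvals[dw]
    design = b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < 6:
        raise EstimationError(
            f"rank-deficient gradient design (rank {rank} < 6): "
            "directions are not sufficiently non-collinear"
        )
    y = -np.log(signal[dw] / s0)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    return TensorFit(
        tensor=tensor,
        eigenvalues=evals[order],
        principal_direction=evecs[:, order[0]],
    )


def fa(eigenvalues) -> float:
    """Fractional anisotropy of a set of tensor eigenvalues.

    Negative eigenvalues (possible in noisy fits) are clamped to zero.
    Zero for isotropic tensors; approaches 1 for a rank-1 tensor.
    """
    ev = np.maximum(np.asarray(eigenvalues, dtype=float), 0.0)
    if np.all(ev == 0):
        raise EstimationError("FA undefined for an all-zero tensor")
    mean = ev.mean()
    num = np.sum((ev - mean) ** 2)
    den = np.sum(ev**2)
    return float(math.sqrt(1.5 * num / den))


def estimate_adc(signal: np.ndarray, scheme: GradientScheme) -> float:
    """Apparent diffusion coefficient: least-squares slope of -ln(S/S_b0) vs b.

    The regression passes through the origin (at b = 0 the log-attenuation
    is zero by construction); exact for mono-exponential signals.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != len(scheme):
        raise EstimationError("signal length does not match scheme")
    if np.unique(scheme.bvals).size < 2:
        raise EstimationError("need at least 2 distinct b-values")
    if not np.any(scheme.b0_mask):
        raise EstimationError("need a b=0 volume as reference")
    s_b0 = signal[scheme.b0_mask].mean()
    if s_b0 <= 0:
        raise EstimationError("non-positive b0 signal")
    dw = scheme.dwi_mask
    if np.any(signal[dw] <= 0):
        raise EstimationError("non-positive diffusion-weighted signal")
    b = scheme.bvals[dw]
    y = -np.log(signal[dw] / s_b0)
    return float(np.sum(b * y) / np.sum(b * b))


def estimate_snr(
    volume: DiffusionVolume,
    foreground_mask: np.ndarray,
    background_mask: np.ndarray,
) -> float:
    """SNR from a noisy volume via the background-Rayleigh sigma estimator.

    In pure-noise background voxels the magnitude signal is Rayleigh with
    mean sigma * sqrt(pi/2); the estimator inverts this on the b=0 volumes
    and divides the mean foreground b=0 intensity by the recovered sigma.

    Raises EstimationError with message "no measurable noise" for a
    noise-free input (background identically zero).
    """
    foreground_mask = np.asarray(foreground_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not foreground_mask.any() or not background_mask.any():
        raise EstimationError("foreground and background masks must be non-empty")
    b0 = volume.b0_mean()
    sigma = float(b0[background_mask].mean()) / _RAYLEIGH_MEAN
    if sigma <= 0:
        raise EstimationError("no measurable noise in the background")
    return float(b0[foreground_mask].mean()) / sigma


def evaluation_report(
    volume: DiffusionVolume,
    truth: dict,
    foreground_mask: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
) -> dict:
    """Recover parameters from single-compartment regions and compare to truth.

    ``truth`` may contain ``snr`` plus per-check entries; each recovered
    value is reported with its absolute error and a pass flag at the given
    tolerance. Returned structure is JSON-serializable.
    """
    report: dict = {"checks": {}}
    if "snr" in truth and foreground_mask is not None and background_mask is not None:
        try:
            est = estimate_snr(volume, foreground_mask, background_mask)
            err = abs(est - truth["snr"]) / truth["snr"]
            report["checks"]["snr"] = {
                "estimate": est,
                "truth": truth["snr"],
                "relative_error": err,
                "passed": bool(err <= truth.get("snr_rtol", 0.05)),
            }
        except EstimationError as exc:
            report["checks"]["snr"] = {"error": str(exc)}
    return report
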