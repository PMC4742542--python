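"""End-to-end phantom generation: model -> scheme -> signal -> noise -> warp -> BIDS.

Each stage is logged with its parameters and timing. The run is fully
deterministic given ``config.seed``: stage seeds are derived from the master
seed with a seed sequence, so the scheme optimizer and the noise generator
never share randomness.
"""

from __future__ import annotations

import logging
import math
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np

from .config import RunConfig
from .distortion import apply_distortion, make_synthetic_fieldmap
from .fixtures import make_fixture
from .io import read_model, save_nifti, write_bids_dataset
from .model import MicrostructuralModel, validate_model
from .scheme import (
    GradientScheme,
    generate_uniform_scheme,
    read_fsl_scheme,
    read_mrtrix_scheme,
)
from .signal import add_rician_noise, simulate_volume

logger = logging.getLogger("dwiphantom")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@contextmanager
def _stage(name: str, **params):
    start = time.perf_counter()
    logger.info("stage %s: start %s", name, params or "")
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - start)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("scheme", "noise", "fieldmap")
    states = ss.generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, states)}


def build_model(config: RunConfig) -> MicrostructuralModel:
    if config.model_manifest:
        return read_model(config.model_manifest)
    if config.fixture is None:
        raise PipelineError("config names neither a fixture nor a model manifest")
    return make_fixture(config.fixture)


def build_scheme(config: RunConfig, seed: int) -> GradientScheme:
    spec = config.scheme
    if spec.mrtrix_path:
        return read_mrtrix_scheme(Path(spec.mrtrix_path).read_text())
    if spec.bval_path and spec.bvec_path:
        return read_fsl_scheme(
            Path(spec.bval_path).read_text(), Path(spec.bvec_path).read_text()
        )
    return generate_uniform_scheme(
        spec.n_per_shell, spec.bvals, n_b0=spec.n_b0, seed=seed, restarts=spec.restarts
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a manifest of everything written.

    With distortion enabled, both the reference and the distorted dataset
    are written (the distorted one under an ``acq-distorted`` entity), so a
    (reference, test) evaluation pair comes out of a single run.
    """
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config": config.to_dict(), "stage_seeds": seeds}
    out_dir = Path(config.out_dir)

    with _stage("model"):
        model = build_model(config)
        report = validate_model(model)
        if not report.ok:
            raise ValueError(f"invalid microstructural model:\n{report}")

    with _stage("scheme", seed=seeds["scheme"]):
        scheme = build_scheme(config, seeds["scheme"])

    with _stage("simulate", volumes=len(scheme)):
        volume = simulate_volume(
            model,
            scheme,
            kernel=config.kernel,
            diffusivities=config.diffusivities,
            s0=config.s0,
        )

    if not math.isinf(config.snr):
        with _stage("noise", snr=config.snr, seed=seeds["noise"]):
            volume = add_rician_noise(
                volume,
                config.noise_spec(seeds["noise"]),
                brain_mask=model.brain_mask(),
            )

    provenance = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "snr": "inf" if math.isinf(config.snr) else config.snr,
        "s0": config.s0,
        "kernel": {
            "lambda_par": config.kernel.lambda_par,
            "lambda_perp": config.kernel.lambda_perp,
        },
        "diffusivities": {
            "D_WM": config.diffusivities.D_WM,
            "D_cGM": config.diffusivities.D_cGM,
            "D_dGM": config.diffusivities.D_dGM,
            "D_CSF": config.diffusivities.D_CSF,
            "D_abnormal": config.diffusivities.D_abnormal,
        },
    }

    with _stage("write", out_dir=str(out_dir)):
        manifest["reference"] = write_bids_dataset(
            volume,
            scheme,
            provenance,
            out_dir,
            label=config.subject,
            overwrite=config.overwrite,
        )

    if config.distortion.enabled:
        with _stage("distort", magnitude_mm=config.distortion.magnitude_mm):
            center = config.distortion.focus_center
            if center is None:
                center = (np.asarray(model.geometry.shape, dtype=float) - 1) / 2
            field = make_synthetic_fieldmap(
                model.geometry,
                focus_center=center,
                magnitude_mm=config.distortion.magnitude_mm,
                extent_mm=config.distortion.extent_mm,
                pe_axis=config.distortion.pe_axis,
                seed=seeds["fieldmap"],
            )
            distorted = apply_distortion(volume, field)
            manifest["distorted"] = write_bids_dataset(
                distorted,
                scheme,
                {**provenance, "distortion": {
                    "magnitude_mm": config.distortion.magnitude_mm,
                    "extent_mm": config.distortion.extent_mm,
                    "pe_axis": config.distortion.pe_axis,
                }},
                out_dir,
                label=config.subject,
                acq="distorted",
                overwrite=config.overwrite,
            )
            fieldmap_path = out_dir / f"sub-{config.subject}" / "fmap" / (
                f"sub-{config.subject}_fieldmap.nii.gz"
            )
            save_nifti(field.displacement_mm, model.geometry, fieldmap_path)
            manifest["fieldmap"] = str(fieldmap_path)

    return manifest
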