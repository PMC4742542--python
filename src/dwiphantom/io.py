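"""NIfTI / manifest / BIDS dataset I/O.

Scalar maps and direction fields are stored one per NIfTI-1 file (direction
fields as 4D volumes with 3 components), tied together by a YAML manifest
naming each map's role. Simulated datasets are written as a minimal
BIDS-dwi layout: ``sub-<label>/dwi/sub-<label>_dwi.nii.gz`` with bval/bvec
and a JSON sidecar carrying the full simulation provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .model import (
    FiberCompartments,
    FractionMaps,
    GridGeometry,
    MicrostructuralModel,
    ModelError,
    TISSUE_NAMES,
)
from .scheme import GradientScheme, read_fsl_scheme, write_fsl_scheme
from .signal import DiffusionVolume

PROVENANCE_KEY = "DwiphantomSimulation"


def geometry_from_img(img) -> GridGeometry:
    shape = img.shape[:3]
    affine = np.asarray(img.affine, dtype=float)
    voxel_size = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    return GridGeometry(shape=shape, voxel_size=voxel_size, affine=affine)


def save_nifti(data: np.ndarray, geometry: GridGeometry, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), geometry.affine)
    img.header.set_zooms(geometry.voxel_size + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, GridGeometry]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), geometry_from_img(img)


def write_model(model: MicrostructuralModel, out_dir, prefix: str = "model") -> Path:
    """Write all maps + a YAML manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"voxel_size_mm": list(model.geometry.voxel_size), "maps": {}}
    for name, vol in zip(TISSUE_NAMES, model.tissues.T):
        if not np.any(vol):
            continue
        fname = f"{prefix}_tissue-{name}.nii.gz"
        save_nifti(vol, model.geometry, out_dir / fname)
        manifest["maps"][f"tissue_{name}"] = fname
    for i, (f, v) in enumerate(zip(model.fibers.F, model.fibers.V), start=1):
        if not np.any(f):
            continue
        f_name = f"{prefix}_fiber-{i}_fraction.nii.gz"
        v_name = f"{prefix}_fiber-{i}_direction.nii.gz"
        save_nifti(f, model.geometry, out_dir / f_name)
        save_nifti(v, model.geometry, out_dir / v_name)
        manifest["maps"][f"fiber_{i}_fraction"] = f_name
        manifest["maps"][f"fiber_{i}_direction"] = v_name
    manifest_path = out_dir / f"{prefix}_manifest.yml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def read_model(manifest_path) -> MicrostructuralModel:
    """Rebuild a model from a manifest written by :func:`write_model`."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    geometry = None
    tissues: dict[str, np.ndarray] = {}
    fibers_f: dict[int, np.ndarray] = {}
    fibers_v: dict[int, np.ndarray] = {}
    for role, fname in manifest["maps"].items():
        data, geom = load_nifti(base / fname)
        if geometry is None:
            geometry = geom
        elif not geometry.same_grid(geom):
            raise ModelError(f"map {fname} is not on the shared grid")
        if role.startswith("tissue_"):
            tissues[role.removeprefix("tissue_")] = data
        elif role.startswith("fiber_"):
            _, idx, kind = role.split("_")
            if kind == "fraction":
                fibers_f[int(idx)] = data
            else:
                fibers_v[int(idx)] = data
        else:
            raise ModelError(f"unknown map role {role!r} in manifest")
    if geometry is None:
        raise ModelError("manifest names no maps")
    shape = geometry.shape
    n_fib = max(list(fibers_f) + list(fibers_v) + [0])
    fibers = FiberCompartments.empty(shape, n=max(n_fib, 1))
    for idx, data in fibers_f.items():
        fibers.F[idx - 1] = data
    for idx, data in fibers_v.items():
        fibers.V[idx - 1] = data
    return MicrostructuralModel(
        geometry=geometry,
        tissues=FractionMaps.from_dict(shape, tissues),
        fibers=fibers,
    )


def write_bids_dataset(
    volume: DiffusionVolume,
    scheme: GradientScheme,
    provenance: dict,
    out_dir,
    label: str,
    acq: str | None = None,
    overwrite: bool = False,
) -> dict:
    """Write a minimal BIDS-dwi dataset; returns a manifest of written paths.

    Layout: ``sub-<label>/dwi/sub-<label>[_acq-<acq>]_dwi.{nii.gz,bval,bvec,json}``
    plus ``dataset_description.json`` at the root. The JSON sidecar embeds
    the simulation provenance (seed, SNR, diffusivities, kernel, scheme
    spec) under a vendor key.
    """
    if not label or not str(label).strip():
        raise ModelError("subject label must be non-empty")
    label = str(label)
    out_dir = Path(out_dir)
    stem = f"sub-{label}" + (f"_acq-{acq}" if acq else "") + "_dwi"
    dwi_dir = out_dir / f"sub-{label}" / "dwi"
    nii_path = dwi_dir / f"{stem}.nii.gz"
    if nii_path.exists() and not overwrite:
        raise FileExistsError(f"{nii_path} exists; pass overwrite=True to replace")
    dwi_dir.mkdir(parents=True, exist_ok=True)

    save_nifti(volume.data, volume.geometry, nii_path)
    bval_text, bvec_text = write_fsl_scheme(scheme)
    (dwi_dir / f"{stem}.bval").write_text(bval_text)
    (dwi_dir / f"{stem}.bvec").write_text(bvec_text)
    sidecar = {PROVENANCE_KEY: provenance}
    (dwi_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    desc_path = out_dir / "dataset_description.json"
    if not desc_path.exists():
        desc_path.write_text(
            json.dumps(
                {
                    "Name": "dwiphantom simulated dataset",
                    "BIDSVersion": "1.8.0",
                    "GeneratedBy": [{"Name": "dwiphantom"}],
                },
                indent=2,
            )
        )
    return {
        "dwi": str(nii_path),
        "bval": str(dwi_dir / f"{stem}.bval"),
        "bvec": str(dwi_dir / f"{stem}.bvec"),
        "sidecar": str(dwi_dir / f"{stem}.json"),
        "dataset_description": str(desc_path),
    }


def read_bids_dwi(nii_path) -> tuple[DiffusionVolume, dict]:
    """Load a written dataset back: volume (+scheme) and sidecar provenance."""
    nii_path = Path(nii_path)
    stem = nii_path.name.removesuffix(".nii.gz").removesuffix(".nii")
    data, geometry = load_nifti(nii_path)
    bval_text = (nii_path.parent / f"{stem}.bval").read_text()
    bvec_text = (nii_path.parent / f"{stem}.bvec").read_text()
    scheme = read_fsl_scheme(bval_text, bvec_text)
    sidecar = json.loads((nii_path.parent / f"{stem}.json").read_text())
    provenance = sidecar.get(PROVENANCE_KEY, {})
    s0 = float(provenance.get("s0", 1.0))
    volume = DiffusionVolume(data=data, geometry=geometry, scheme=scheme, s0=s0)
    return volume, provenance
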