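"""File I/O: the HDF5 k-space container and phantom/image writers.

The k-space container is a small versioned HDF5 schema so simulation and
reconstruction can run as separate CLI steps:

    /positions   float (n, dim)   sample k-vectors, cycles/m
    /values      complex (n,)     samples
    /shot_id     int (n,)
    /is_spi      bool-as-uint8 (n,)
    /delta_f     float (n_shots,) per-shot carrier offsets, Hz
    attrs: schema, scheme, fov, dim, k_gap, delta_k, dk_radial,
           n_radial_spokes, noise_seed

Images: NIfTI for 3D volumes (isocenter-origin affine, voxel units mm),
NPY plus 16-bit PNG for 2D.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .acquisition import KSpaceData
from .phantom import Phantom

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_image",
    "save_phantom",
    "save_report",
]

SCHEMA = "ztesim-kspace-1"


def save_kspace(path, data: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=data.positions)
        f.create_dataset("values", data=data.values)
        f.create_dataset("shot_id", data=data.shot_id)
        f.create_dataset("is_spi", data=data.is_spi.astype(np.uint8))
        f.create_dataset("delta_f", data=data.delta_f_per_shot)
        f.attrs["schema"] = SCHEMA
        f.attrs["scheme"] = data.scheme_mode
        f.attrs["fov"] = data.fov
        f.attrs["dim"] = data.dim
        f.attrs["k_gap"] = data.k_gap
        f.attrs["delta_k"] = data.delta_k
        f.attrs["dk_radial"] = data.dk_radial
        f.attrs["n_radial_spokes"] = data.n_radial_spokes
        f.attrs["noise_seed"] = -1 if data.noise_seed is None else int(data.noise_seed)


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema", "")
        if schema != SCHEMA:
            raise ValueError(f"unsupported k-space container schema {schema!r}")
        seed = int(f.attrs["noise_seed"])
        return KSpaceData(
            positions=f["positions"][()],
            values=f["values"][()],
            shot_id=f["shot_id"][()],
            is_spi=f["is_spi"][()].astype(bool),
            delta_f_per_shot=f["delta_f"][()],
            scheme_mode=str(f.attrs["scheme"]),
            fov=float(f.attrs["fov"]),
            dim=int(f.attrs["dim"]),
            k_gap=float(f.attrs["k_gap"]),
            delta_k=float(f.attrs["delta_k"]),
            dk_radial=float(f.attrs["dk_radial"]),
            n_radial_spokes=int(f.attrs["n_radial_spokes"]),
            noise_seed=None if seed < 0 else seed,
        )


def _save_png16(path, array: np.ndarray) -> None:
    from PIL import Image

    a = np.abs(np.asarray(array, dtype=float))
    peak = a.max()
    scaled = (a / peak * 65535.0).astype(np.uint16) if peak > 0 else a.astype(np.uint16)
    Image.fromarray(np.ascontiguousarray(scaled.T[::-1])).save(path)


def save_image(path, array: np.ndarray, fov: float | None = None) -> Path:
    """Write a 2D image as NPY (+PNG alongside) or a 3D volume as NIfTI.

    The format follows the file suffix (.npy/.png/.nii/.nii.gz); a bare stem
    gets .npy (2D) or .nii.gz (3D).
    """
    path = Path(path)
    array = np.asarray(array)
    if array.ndim == 2:
        if path.suffix == ".png":
            _save_png16(path, array)
        else:
            if path.suffix != ".npy":
                path = path.with_suffix(".npy")
            np.save(path, array)
            _save_png16(path.with_suffix(".png"), array)
        return path
    if array.ndim == 3:
        import nibabel as nib

        if path.suffix not in (".nii", ".gz"):
            path = path.with_suffix(".nii.gz")
        vox_mm = 1.0 if fov is None else fov / array.shape[0] * 1000.0
        affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
        affine[:3, 3] = -vox_mm * np.array(array.shape) / 2.0
        nib.save(nib.Nifti1Image(np.abs(array).astype(np.float32), affine), path)
        return path
    raise ValueError(f"cannot write array of ndim {array.ndim}")


def save_phantom(path, ph: Phantom) -> Path:
    return save_image(path, ph.values, fov=ph.fov)


def save_report(path, report: dict) -> None:
    """Deterministic JSON report: sorted keys, no timestamps."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
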