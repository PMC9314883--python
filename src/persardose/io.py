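"""Reading and writing of volumes, field sets, Q-matrices and sidecars.

Labels and images travel as NIfTI-1 (int16 / float32) with the voxel size
on the affine diagonal and the axis-name convention in the header
description.  Field sets and Q-matrix volumes are HDF5.  Every artifact
can carry a YAML sidecar recording the config and seeds that produced it,
sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np
import yaml

from .dosimetry import QMatrixVolume
from .volumes import DEFAULT_ORIENTATION, FieldSet, ImageVolume, LabelVolume

__all__ = [
    "save_labels",
    "load_labels",
    "save_image",
    "load_image",
    "save_fieldset",
    "load_fieldset",
    "save_qmatrix",
    "load_qmatrix",
    "write_sidecar",
    "read_sidecar",
]


class FileFormatError(ValueError):
    """Raised for malformed or geometrically inconsistent files."""


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def _descrip(orientation) -> bytes:
    return json.dumps({"axes": list(orientation)}).encode()


def _parse_nifti(path, expected_voxel_size=None):
    try:
        img = nib.load(str(path))
    except Exception as e:  # noqa: BLE001
        raise FileFormatError(f"{path}: cannot read NIfTI ({e})") from e
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise FileFormatError(f"{path}: non-diagonal affine; unsupported orientation")
    voxel_size = tuple(float(v) for v in np.diag(aff[:3, :3]))
    if any(v <= 0 for v in voxel_size):
        raise FileFormatError(f"{path}: non-positive voxel size in affine")
    if expected_voxel_size is not None and not np.allclose(
        voxel_size, expected_voxel_size
    ):
        raise FileFormatError(
            f"{path}: voxel size {voxel_size} does not match expected "
            f"{tuple(expected_voxel_size)}"
        )
    try:
        meta = json.loads(bytes(img.header["descrip"]).split(b"\x00")[0].decode())
        orientation = tuple(meta["axes"])
    except Exception:  # noqa: BLE001 - absent/foreign description
        orientation = DEFAULT_ORIENTATION
    return img, voxel_size, orientation


def save_labels(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.grid.astype(np.int16), _affine(labels.voxel_size))
    img.header["descrip"] = _descrip(labels.orientation)
    nib.save(img, str(path))


def load_labels(path, expected_voxel_size=None) -> LabelVolume:
    img, voxel_size, orientation = _parse_nifti(path, expected_voxel_size)
    grid = np.asarray(img.dataobj).astype(np.int16)
    return LabelVolume(grid, voxel_size, orientation)


def save_image(image: ImageVolume, path) -> None:
    img = nib.Nifti1Image(image.grid.astype(np.float32), _affine(image.voxel_size))
    img.header["descrip"] = _descrip(image.orientation)
    nib.save(img, str(path))


def load_image(path, expected_voxel_size=None) -> ImageVolume:
    img, voxel_size, orientation = _parse_nifti(path, expected_voxel_size)
    grid = np.asarray(img.dataobj).astype(np.float64)
    return ImageVolume(grid, voxel_size, orientation)


def save_fieldset(fields: FieldSet, path, labels_ref: str = "") -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("E", data=fields.E)  # channel-major complex
        f.create_dataset("voxel_volume", data=fields.voxel_volume)
        f.create_dataset("normalization_w", data=fields.normalization)
        f.create_dataset("voxel_size_mm", data=np.asarray(fields.voxel_size))
        f.create_dataset("labels_ref", data=labels_ref)


def load_fieldset(path) -> FieldSet:
    with h5py.File(str(path), "r") as f:
        for key in ("E", "voxel_volume"):
            if key not in f:
                raise FileFormatError(f"{path}: missing dataset /{key}")
        E = f["E"][...]
        vv = float(f["voxel_volume"][()])
        norm = float(f["normalization_w"][()]) if "normalization_w" in f else 1.0
        vs = (
            tuple(f["voxel_size_mm"][...])
            if "voxel_size_mm" in f
            else (1.0, 1.0, 1.0)
        )
    return FieldSet(E, vv, norm, vs)


def save_qmatrix(q: QMatrixVolume, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("q10g", data=q.q)  # voxel-major packed upper triangle
        f.create_dataset("voxel_index_map", data=q.voxel_index)
        f.create_dataset("channels", data=q.channels)
        f.create_dataset("normalization_w", data=q.normalization)
        f.create_dataset("shape", data=np.asarray(q.shape))
        f.create_dataset("voxel_size_mm", data=np.asarray(q.voxel_size))


def load_qmatrix(path) -> QMatrixVolume:
    with h5py.File(str(path), "r") as f:
        for key in ("q10g", "voxel_index_map", "channels"):
            if key not in f:
                raise FileFormatError(f"{path}: missing dataset /{key}")
        return QMatrixVolume(
            f["q10g"][...],
            f["voxel_index_map"][...],
            int(f["channels"][()]),
            tuple(int(s) for s in f["shape"][...]),
            float(f["normalization_w"][()]),
            tuple(f["voxel_size_mm"][...]),
        )


def write_sidecar(path, config: dict) -> None:
    """YAML sidecar with the config/seeds that produced an artifact."""
    with open(str(path), "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def read_sidecar(path) -> dict:
    with open(str(path)) as f:
        return yaml.safe_load(f)
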