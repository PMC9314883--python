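"""Core in-memory containers shared by all pipeline stages.

Volumes follow a sagittal-first storage convention: axis 0 indexes
left-right (sagittal slice position), axis 1 anterior-posterior (coronal)
and axis 2 inferior-superior (transverse).  A transverse slice of a
``(192, 256, 256)`` volume therefore has shape ``(192, 256)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "TissueLabel",
    "TISSUE_NAMES",
    "DEFAULT_ORIENTATION",
    "LabelVolume",
    "ImageVolume",
    "FieldSet",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


class TissueLabel(IntEnum):
    """The nine output classes: eight tissues plus background (code 0)."""

    BACKGROUND = 0
    INTERNAL_AIR = 1
    BONE = 2
    MUSCLE = 3
    FAT = 4
    WHITE_MATTER = 5
    GRAY_MATTER = 6
    CSF = 7
    EYE = 8


TISSUE_NAMES: tuple[str, ...] = (
    "background",
    "internal_air",
    "bone",
    "muscle",
    "fat",
    "white_matter",
    "gray_matter",
    "csf",
    "eye",
)

#: axis names for the sagittal-first storage convention
DEFAULT_ORIENTATION: tuple[str, str, str] = ("sagittal", "coronal", "transverse")

#: axis index sliced over for each 2D network orientation
ORIENTATION_AXIS = {"sagittal": 0, "coronal": 1, "transverse": 2}


def _as_tuple3(v) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(v, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class LabelVolume:
    """3D integer grid of tissue codes with voxel geometry.

    Parameters
    ----------
    grid:
        3D integer array with values in ``0..8`` (see :class:`TissueLabel`).
    voxel_size:
        Edge length per axis in millimetres.
    orientation:
        Axis-name triple; defaults to sagittal/coronal/transverse.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: tuple[str, str, str] = DEFAULT_ORIENTATION

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be integer-typed")
        self.voxel_size = _as_tuple3(self.voxel_size)
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() > 8):
            raise ValueError("label codes must lie in 0..8")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_m3(self) -> float:
        """Voxel volume in cubic metres (voxel_size is in mm)."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz * 1e-9

    def body_mask(self) -> np.ndarray:
        """Non-background support (includes internal air)."""
        return self.grid != TissueLabel.BACKGROUND

    def tissue_mask(self) -> np.ndarray:
        """Voxels that carry mass and can absorb power.

        Background and internal air are excluded: neither contributes
        mass nor power to SAR averaging.
        """
        return (self.grid != TissueLabel.BACKGROUND) & (
            self.grid != TissueLabel.INTERNAL_AIR
        )

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid.copy(), self.voxel_size, self.orientation)


@dataclass
class ImageVolume:
    """3D real-valued intensity grid sharing geometry with a LabelVolume."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: tuple[str, str, str] = DEFAULT_ORIENTATION

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("image grid must be 3D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("image grid contains non-finite values")
        self.voxel_size = _as_tuple3(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid.copy(), self.voxel_size, self.orientation)

    def like(self, grid: np.ndarray) -> "ImageVolume":
        """New ImageVolume with this volume's geometry and the given data."""
        return ImageVolume(np.asarray(grid, dtype=np.float64), self.voxel_size, self.orientation)


@dataclass
class FieldSet:
    """Per-channel complex electric field volumes.

    Attributes
    ----------
    E:
        Complex array of shape ``(channels, 3, nx, ny, nz)`` in V/m
        (peak-amplitude phasor convention).
    voxel_volume:
        Voxel volume in cubic metres.
    normalization:
        Total RF input power (W) the fields are normalized to.
    """

    E: np.ndarray
    voxel_volume: float
    normalization: float = 1.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=np.complex128)
        if self.E.ndim != 5 or self.E.shape[1] != 3:
            raise ValueError("E must have shape (channels, 3, nx, ny, nz)")
        if not np.all(np.isfinite(self.E.view(np.float64))):
            raise ValueError("fields contain non-finite values")
        if self.normalization <= 0:
            raise ValueError("normalization power must be positive")
        self.voxel_size = _as_tuple3(self.voxel_size)

    @property
    def channels(self) -> int:
        return self.E.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.E.shape[2:]

    def combined(self, w: np.ndarray) -> np.ndarray:
        """Superposed field ``sum_c w_c E_c`` with shape ``(3, nx, ny, nz)``."""
        w = np.asarray(w, dtype=np.complex128)
        if w.shape != (self.channels,):
            raise ValueError(
                f"shim has {w.size} entries but field set has {self.channels} channels"
            )
        return np.tensordot(w, self.E, axes=(0, 0))


def check_same_geometry(a, b, what: str = "volumes") -> None:
    if a.shape != b.shape:
        raise GeometryError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    va = getattr(a, "voxel_size", None)
    vb = getattr(b, "voxel_size", None)
    if va is not None and vb is not None and not np.allclose(va, vb):
        raise GeometryError(f"{what}: voxel size mismatch {va} vs {vb}")
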