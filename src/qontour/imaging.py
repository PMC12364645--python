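"""Core raster types and image/mask I/O.

Conventions used throughout the package:

* 0-based indices, axis order ``(slice, row, col)`` for 3D volumes and
  ``(row, col)`` for 2D images.
* Masks are written to NIfTI as unsigned 8-bit 0/1 for interoperability.
* ``zscore_normalize`` uses the population (divide-by-N) standard deviation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "DegenerateInputError",
    "FormatError",
    "read_volume",
    "write_volume",
    "write_mask",
    "zscore_normalize",
    "minmax_scale",
]


class FormatError(ValueError):
    """Raised when a file cannot be read as a supported image format."""


class DegenerateInputError(ValueError):
    """Raised when an input is degenerate for the requested operation
    (e.g. zero intensity variance for z-scoring)."""


@dataclass(frozen=True)
class ImageVolume:
    """A 2D (H, W) or 3D (D, H, W) grayscale intensity grid with spacing.

    ``spacing`` holds the physical voxel size per axis in millimetres, in
    the same axis order as ``data``. ``affine`` is pass-through orientation
    metadata (NIfTI affine); PNG images get an identity affine.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = ()
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got {arr.ndim}D")
        if min(arr.shape) < 1:
            raise ValueError("every axis length must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "data", arr)
        spacing = tuple(float(s) for s in self.spacing) or (1.0,) * arr.ndim
        if len(spacing) != arr.ndim:
            raise ValueError("spacing must have one entry per axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid congruent with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, ...] = ()
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be exactly {0, 1}")
            arr = arr.astype(bool)
        if arr.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got {arr.ndim}D")
        object.__setattr__(self, "data", arr)
        spacing = tuple(float(s) for s in self.spacing) or (1.0,) * arr.ndim
        if len(spacing) != arr.ndim or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be strictly positive, one per axis")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def count(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return replace(self, data=np.asarray(data, dtype=bool))


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or single-channel PNG image.

    NIfTI spacing comes from the header zooms (reordered to match the
    (slice, row, col) axis convention); PNG images get unit spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error detail
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        arr = np.asanyarray(img.dataobj)
        if arr.ndim not in (2, 3):
            raise FormatError(f"{path}: expected 2D/3D image, got {arr.ndim}D")
        zooms = img.header.get_zooms()[: arr.ndim]
        # nibabel axis order is (x, y, z); flip to (slice, row, col)
        arr = arr.T
        spacing = tuple(float(z) for z in reversed(zooms))
        return ImageVolume(arr.astype(float), spacing, affine=img.affine)
    if path.suffix.lower() == ".png":
        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read PNG file {path}: {exc}") from exc
        if arr.ndim != 2:
            raise FormatError(f"{path}: multi-channel PNG is unsupported")
        return ImageVolume(arr.astype(float), (1.0, 1.0), affine=np.eye(4))
    raise FormatError(f"unsupported file format: {path}")


def _nifti_affine(vol_spacing: tuple[float, ...], affine: np.ndarray | None) -> np.ndarray:
    if affine is not None:
        return affine
    diag = list(reversed(vol_spacing)) + [1.0] * (4 - len(vol_spacing))
    return np.diag(diag)


def write_volume(img: ImageVolume, path: str | os.PathLike) -> None:
    """Write an image as NIfTI or 16-bit grayscale PNG (2D only)."""
    path = Path(path)
    try:
        if _is_nifti(path):
            nifti = nib.Nifti1Image(
                img.data.T.astype(np.float32), _nifti_affine(img.spacing, img.affine)
            )
            nifti.header.set_zooms(tuple(reversed(img.spacing)))
            nib.save(nifti, str(path))
        elif path.suffix.lower() == ".png":
            if img.ndim != 2:
                raise FormatError("PNG output supports 2D images only")
            lo, hi = img.data.min(), img.data.max()
            scale = (img.data - lo) / (hi - lo) if hi > lo else np.zeros_like(img.data)
            iio.imwrite(path, (scale * 65535).astype(np.uint16))
        else:
            raise FormatError(f"unsupported output format: {path}")
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a binary mask as uint8 0/1 NIfTI (or PNG for 2D)."""
    path = Path(path)
    try:
        if _is_nifti(path):
            nifti = nib.Nifti1Image(
                mask.data.T.astype(np.uint8), _nifti_affine(mask.spacing, mask.affine)
            )
            nifti.header.set_zooms(tuple(reversed(mask.spacing)))
            nib.save(nifti, str(path))
        elif path.suffix.lower() == ".png":
            if mask.ndim != 2:
                raise FormatError("PNG output supports 2D masks only")
            iio.imwrite(path, mask.data.astype(np.uint8) * 255)
        else:
            raise FormatError(f"unsupported output format: {path}")
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a mask file; any nonzero voxel becomes True."""
    vol = read_volume(path)
    return BinaryMask(vol.data != 0, vol.spacing, affine=vol.affine)


def zscore_normalize(img: ImageVolume) -> ImageVolume:
    """Z-score intensity normalization: output mean 0, population sd 1."""
    data = img.data
    if data.size < 2:
        raise DegenerateInputError("need at least 2 voxels to normalize")
    sd = data.std()  # population convention (ddof=0)
    if sd == 0:
        raise DegenerateInputError("zero intensity variance")
    return img.with_data((data - data.mean()) / sd)


def minmax_scale(data: np.ndarray) -> np.ndarray:
    """Scale an array onto [0, 1]; constant arrays map to all zeros."""
    lo = data.min()
    hi = data.max()
    if hi == lo:
        return np.zeros_like(data, dtype=float)
    return (data - lo) / (hi - lo)
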