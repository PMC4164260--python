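"""Image and label I/O plus the grid conventions shared by every stage.

All grids are row-major 2-D numpy arrays, 0-based, pixel (0, 0) at the
top-left.  Images carry an optional boolean brain mask (True = inside
brain); masked-out pixels are excluded from clustering and, when a mask is
passed, from metric counts.  Supported on-disk formats are NIfTI-1
(``.nii`` / ``.nii.gz``) and grayscale PNG.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image as PILImage

__all__ = [
    "IntensityImage",
    "LabelField",
    "compact_labels",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
]


@dataclasses.dataclass
class IntensityImage:
    """A 2-D scalar intensity field with an optional brain mask.

    Parameters
    ----------
    pixels : ndarray of float, shape (rows, cols)
        Intensities in arbitrary MR units.  Must be finite.
    mask : ndarray of bool, same shape, optional
        True marks pixels inside the brain.  ``None`` means every pixel
        participates.
    spacing : (float, float)
        Physical (row, col) pixel size in mm.  Informational only.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        bad = np.count_nonzero(~np.isfinite(self.pixels))
        if bad:
            raise ValueError(f"pixels contain {bad} non-finite value(s)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != pixels shape {self.pixels.shape}"
                )
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of participating pixels (all True when mask is None)."""
        if self.mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.mask


@dataclasses.dataclass
class LabelField:
    """A 2-D field of cluster labels.

    Labels are contiguous nonnegative integers ``0..n_clusters-1`` after
    :func:`compact_labels`; ``-1`` marks masked-out sites.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        self.labels = self.labels.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_clusters(self) -> int:
        used = np.unique(self.labels)
        return int(np.count_nonzero(used >= 0))


def compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel so that the used labels are exactly 0..K-1 (masked -1 kept)."""
    labels = np.asarray(labels)
    out = np.full(labels.shape, -1, dtype=np.int64)
    used = np.unique(labels[labels >= 0])
    for new, old in enumerate(used):
        out[labels == old] = new
    return out


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image(path, slice_index: int | None = None) -> IntensityImage:
    """Read a 2-D intensity image from NIfTI or grayscale PNG.

    For a 3-D NIfTI volume, ``slice_index`` selects the slice along the
    first axis; the remaining two axes form the image grid.  The NIfTI
    header is used only to set the pixel spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several exception types
            raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("3-D volume requires slice_index")
            if not 0 <= slice_index < data.shape[0]:
                raise IndexError(
                    f"slice_index {slice_index} out of range for {data.shape[0]} slices"
                )
            data = data[slice_index]
            spacing = (float(zooms[1]), float(zooms[2])) if len(zooms) >= 3 else (1.0, 1.0)
        elif data.ndim == 2:
            spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    else:
        try:
            with PILImage.open(path) as im:
                if im.mode not in ("L", "I", "I;16", "F"):
                    im = im.convert("L")
                data = np.asarray(im, dtype=np.float64)
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise ValueError(f"cannot read image file {path}: {exc}") from exc
        spacing = (1.0, 1.0)
    bad = np.count_nonzero(~np.isfinite(data))
    if bad:
        raise ValueError(f"{path} contains {bad} non-finite voxel(s)")
    return IntensityImage(pixels=data, spacing=spacing)


def save_image(image: IntensityImage, path) -> None:
    """Write an intensity image; PNG output is quantized to 16 bits."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float64), affine), str(path))
        return
    out = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    PILImage.fromarray(out).save(path)


def save_mask(mask, path) -> None:
    """Write a label field or binary mask as indexed PNG (8-bit) or NIfTI.

    PNG holds at most 256 labels; larger fields must go to NIfTI.
    """
    if isinstance(mask, LabelField):
        arr = mask.labels
    else:
        arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("negative labels cannot be saved; compact/mask first")
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr.astype(np.int32), np.eye(4)), str(path))
        return
    if arr.max(initial=0) > 255:
        raise ValueError(f"{arr.max()} exceeds the 255-label capacity of PNG")
    PILImage.fromarray(arr.astype(np.uint8), mode="L").save(path)


def load_mask(path) -> LabelField:
    """Read an integer label field saved by :func:`save_mask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        if data.ndim != 2:
            raise ValueError("label NIfTI must be 2-D")
        return LabelField(labels=np.rint(data).astype(np.int64))
    with PILImage.open(path) as im:
        return LabelField(labels=np.asarray(im, dtype=np.int64))
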