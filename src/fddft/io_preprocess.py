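"""Image/volume I/O, intensity normalization, and bounding boxes.

Conventions used throughout the package:

* 0-based row/col indices, row-major arrays of shape ``(H, W)``;
  volumes are ``(H, W, D)`` with axial slices along the last axis in the
  file's native order (no anatomical reorientation).
* Bounding boxes are inclusive at both ends, so a single pixel at
  ``(3, 4)`` has the box ``(3, 3, 4, 4)`` and side lengths of 1 pixel.
  The downstream 75 %-of-brain-box size filter consumes these side
  lengths, which is why the convention is pinned down here.
* Intensities are normalized to ``[0, 1]`` before any energy landscape is
  computed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    EmptyForegroundError,
    ImageReadError,
    NonFiniteInputError,
    VolumeReadError,
)

__all__ = [
    "ImageGrid",
    "VolumeStack",
    "BoundingBox",
    "normalize_intensity",
    "compute_bounding_box",
    "remove_small_components",
    "load_image",
    "load_volume",
    "load_mask",
    "write_mask",
    "write_volume",
]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass(frozen=True, eq=False)
class ImageGrid:
    """A 2-D intensity matrix rho in [0, 1]^(H x W)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"ImageGrid requires a 2-D matrix with H, W >= 2, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise NonFiniteInputError("ImageGrid values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass(frozen=True, eq=False)
class VolumeStack:
    """An ordered stack of axial slices plus an optional binary voxel mask."""

    slices: tuple[ImageGrid, ...]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("VolumeStack requires at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"all slices must share (H, W); found {shapes}")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.shape != self.shape:
                raise ValueError(f"mask shape {m.shape} != volume shape {self.shape}")
            object.__setattr__(self, "mask", (m != 0).astype(np.uint8))

    @property
    def depth(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int, int]:
        h, w = self.slices[0].shape
        return (h, w, len(self.slices))

    def to_array(self) -> np.ndarray:
        """Assemble the (H, W, D) intensity array."""
        return np.stack([s.values for s in self.slices], axis=-1)

    @classmethod
    def from_array(cls, volume: np.ndarray, mask: np.ndarray | None = None) -> "VolumeStack":
        volume = np.asarray(volume, dtype=float)
        if volume.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {volume.shape}")
        slices = tuple(ImageGrid(volume[:, :, k]) for k in range(volume.shape[2]))
        return cls(slices=slices, mask=mask)


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Inclusive axis-aligned pixel box."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min + 1

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1


def normalize_intensity(raw: np.ndarray) -> ImageGrid:
    """Min-max scale a raw intensity matrix into [0, 1].

    Degenerate cases: the all-zero matrix maps to itself, and a constant
    nonzero matrix maps to all ones (foreground-preserving — a flat bright
    frame is still foreground).

    Raises
    ------
    NonFiniteInputError
        If ``raw`` contains NaN or infinities.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise NonFiniteInputError("cannot normalize a matrix with non-finite entries")
    lo = raw.min()
    hi = raw.max()
    if hi == lo:
        if hi == 0.0:
            return ImageGrid(np.zeros_like(raw))
        return ImageGrid(np.ones_like(raw))
    return ImageGrid((raw - lo) / (hi - lo))


def compute_bounding_box(img: ImageGrid | np.ndarray, threshold: float = 0.0) -> BoundingBox:
    """Tightest inclusive box containing all pixels strictly above ``threshold``."""
    values = img.values if isinstance(img, ImageGrid) else np.asarray(img)
    rows, cols = np.nonzero(values > threshold)
    if rows.size == 0:
        raise EmptyForegroundError(f"no pixel exceeds threshold {threshold}")
    return BoundingBox(int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))


def remove_small_components(
    img: ImageGrid, min_size: int = 10, threshold: float = 0.0, connectivity: int = 8
) -> ImageGrid:
    """Zero out connected foreground components smaller than ``min_size`` pixels.

    Optional despeckling step; the default pipeline leaves it off.
    """
    values = img.values.copy()
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(values > threshold, structure=structure)
    if n == 0:
        return ImageGrid(values)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_size)
    small = small[small > 0]
    if small.size:
        values[np.isin(labels, small)] = 0.0
    return ImageGrid(values)


def load_image(path: str | Path) -> ImageGrid:
    """Read a PNG/JPEG as a float matrix scaled to [0, 1].

    Multi-channel inputs are converted to single-channel luminance; an
    alpha channel, if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of types
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    dtype = arr.dtype
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ImageReadError(f"unsupported channel count {arr.shape[2]} in {path}")
    elif arr.ndim != 2:
        raise ImageReadError(f"unsupported image rank {arr.ndim} in {path}")
    arr = arr.astype(float)
    if np.issubdtype(dtype, np.integer):
        arr = arr / float(np.iinfo(dtype).max)
    return ImageGrid(arr)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a 2-D binary mask as an 8-bit {0, 1} PNG, or a 3-D one as NIfTI uint8."""
    mask = (np.asarray(mask) != 0).astype(np.uint8)
    path = Path(path)
    if mask.ndim == 2:
        iio.imwrite(path, mask)
    elif mask.ndim == 3:
        nib.save(nib.Nifti1Image(mask, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"mask must be 2-D or 3-D, got rank {mask.ndim}")


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (PNG for 2-D, NIfTI for 3-D); nonzero -> 1."""
    path = Path(path)
    if path.suffix.lower() in {".nii", ".gz"}:
        return (_read_nifti(path) != 0).astype(np.uint8)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageReadError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (np.asarray(arr) != 0).astype(np.uint8)


def _read_nifti(path: Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise VolumeReadError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeReadError(f"expected a 3-D volume in {path}, got rank {data.ndim}")
    return np.asarray(data, dtype=float)


def load_volume(path: str | Path) -> VolumeStack:
    """Read a NIfTI volume into a slice stack along the native third axis."""
    return VolumeStack.from_array(_read_nifti(Path(path)))


def write_volume(vol: VolumeStack | np.ndarray, path: str | Path) -> None:
    """Write an intensity volume as float32 NIfTI with an identity affine."""
    arr = vol.to_array() if isinstance(vol, VolumeStack) else np.asarray(vol, dtype=float)
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)), str(Path(path)))
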