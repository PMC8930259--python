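"""Grayscale image input/output and preprocessing.

Images are plain 2-D ``numpy.uint8`` arrays (row-major, 0-based ``(row, col)``
indexing) with intensities on the 8-bit 0-255 scale — the representation both
optimizers encode into their antibodies. This module converts arbitrary inputs
(color, 16-bit, float, NIfTI) onto that scale and builds the 256-bin intensity
histogram that every objective function in the package is computed from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import ValidationError

__all__ = [
    "GrayImage",
    "Histogram",
    "as_gray_image",
    "load_image",
    "write_image",
    "write_labels",
    "normalize_quantize",
    "histogram",
]

#: A validated grayscale image: 2-D uint8 array, intensities in [0, 255].
GrayImage = np.ndarray

#: Luminance weights for color → gray conversion (ITU-R BT.709).
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def as_gray_image(img: np.ndarray) -> GrayImage:
    """Validate and coerce *img* to a grayscale image.

    Raises :class:`ValidationError` unless *img* is a non-empty 2-D array of
    integers in [0, 255]. Returns a ``uint8`` view/copy.
    """
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("image intensities must be integers")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("image intensities must lie in [0, 255]")
    return arr.astype(np.uint8)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; the package convention is half-up throughout
    return np.floor(x + 0.5)


def normalize_quantize(raw: np.ndarray) -> GrayImage:
    """Min-max normalize *raw* to [0, 1] and quantize onto the 8-bit scale.

    ``x -> round(255 * (x - min) / (max - min))`` with ties rounded half up.
    A constant image has zero range and maps to constant 0 by convention, so
    the operation is total on degenerate inputs.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("cannot normalize an empty array")
    lo, hi = float(arr.min()), float(arr.max())
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValidationError("image contains non-finite values")
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) / (hi - lo)
    return _round_half_up(255.0 * scaled).astype(np.uint8)


def load_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF (or single-slice NIfTI) file as a grayscale image.

    Color inputs are converted to luminance (0.2126 R + 0.7152 G + 0.0722 B).
    Inputs already on the 8-bit scale keep their values exactly; wider dtypes
    (16-bit, float) are min-max rescaled onto [0, 255] via
    :func:`normalize_quantize`.
    """
    path = Path(path)
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            data = np.asanyarray(nib.load(path).dataobj)
            data = np.squeeze(data)
            if data.ndim == 3:  # take the middle slice of a thin volume
                data = data[:, :, data.shape[2] // 2]
            if data.ndim != 2:
                raise ValidationError(
                    f"{path}: expected a 2-D slice, got shape {data.shape}"
                )
            arr = np.asarray(data)
        else:
            arr = np.asarray(iio.imread(path))
    except (ValidationError, FileNotFoundError):
        raise
    except OSError as exc:
        raise OSError(f"could not read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"{path}: image has zero size")

    if arr.ndim == 3:  # color: drop alpha, collapse to luminance
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValidationError(f"{path}: unsupported channel count {arr.shape[2]}")
        arr = arr.astype(np.float64) @ _LUMA
        if arr.max() <= 255.0:
            return _round_half_up(arr).astype(np.uint8)
        return normalize_quantize(arr)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D image, got shape {arr.shape}")

    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer) and 0 <= arr.min() and arr.max() <= 255:
        return arr.astype(np.uint8)
    return normalize_quantize(arr)


def write_image(path: str | Path, img: GrayImage) -> None:
    """Write a grayscale image as 8-bit PNG or TIFF (by file extension)."""
    iio.imwrite(Path(path), as_gray_image(img))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label image (classes 0..K-1) as an 8-bit PNG/TIFF."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("label values must fit in 8 bits")
    iio.imwrite(Path(path), arr.astype(np.uint8))


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram of a grayscale image.

    ``counts[g]`` is the number of pixels of gray level ``g``;
    ``total`` is the pixel count, equal to ``counts.sum()``.
    """

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,) or counts.min() < 0:
            raise ValidationError("histogram needs 256 nonnegative counts")
        if self.total <= 0 or int(counts.sum()) != self.total:
            raise ValidationError("histogram counts must sum to a positive total")
        object.__setattr__(self, "counts", counts)


def histogram(img: GrayImage) -> Histogram:
    """Count pixels per gray level; conserves the total pixel count."""
    img = as_gray_image(img)
    counts = np.bincount(img.ravel(), minlength=256).astype(np.int64)
    return Histogram(counts=counts, total=int(img.size))
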