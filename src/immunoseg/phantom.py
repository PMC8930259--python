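"""Synthetic brain-like phantoms with pixel-level ground truth.

Clinical MRI cannot ship with a software package, so every algorithm and
metric here is exercised on phantoms: a concentric-ellipse geometry
(background, an outer ring, nested inner tissue, optionally a small bright
lesion disc) whose classes carry distinct mean intensities, plus additive
zero-mean Gaussian noise clipped to [0, 255] and rounded.

Gaussian noise is a deliberate simplification of MRI's Rician magnitude
noise; at moderate signal-to-noise the two are close, and Gaussian keeps the
parameter-recovery analysis transparent. The geometry is schematic —
ellipses, not anatomy — which is sufficient to exercise thresholding and
intensity clustering but says nothing about spatial regularity of real
lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .image_io import GrayImage

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_bilevel"]

#: (row, col, radius, class id) of the lesion disc.
Lesion = tuple[int, int, int, int]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a phantom.

    ``class_means`` lists one mean intensity per tissue class, strictly
    increasing, class 0 being the (darkest) background. ``noise_sigma`` is
    the Gaussian noise scale in gray levels. ``lesion`` optionally places a
    disc of the given class at (row, col) with the given radius; by default
    the brightest class is the innermost nested ellipse instead.
    """

    height: int = 64
    width: int = 64
    class_means: tuple[int, ...] = (30, 90, 150, 220)
    noise_sigma: float = 8.0
    lesion: Lesion | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("phantom must be at least 1x1")
        means = tuple(int(m) for m in self.class_means)
        if len(means) < 2:
            raise ValidationError("need at least 2 tissue classes")
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValidationError("class means must be strictly increasing")
        if means[0] < 0 or means[-1] > 255:
            raise ValidationError("class means must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.lesion is not None:
            row, col, radius, cls = self.lesion
            if radius < 1:
                raise ValidationError("lesion radius must be >= 1")
            if not (0 <= cls < len(means)):
                raise ValidationError(f"lesion class {cls} not among the {len(means)} classes")
            if (
                row - radius < 0
                or col - radius < 0
                or row + radius >= self.height
                or col + radius >= self.width
            ):
                raise ValidationError("lesion disc extends outside the image")
        object.__setattr__(self, "class_means", means)

    @property
    def n_classes(self) -> int:
        return len(self.class_means)


@dataclass(frozen=True)
class Phantom:
    """A generated image with its ground-truth label map and recipe."""

    image: GrayImage
    truth: np.ndarray
    spec: PhantomSpec


def _ellipse_mask(h: int, w: int, ry: float, rx: float) -> np.ndarray:
    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    return (rows / ry) ** 2 + (cols / rx) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Realize a phantom from its spec; deterministic under ``spec.seed``.

    Classes 1..K-1 (minus the lesion class if a lesion is placed) are nested
    concentric ellipses of shrinking radius painted over the class-0
    background, the ellipses slightly wider than tall; the lesion disc, if
    any, is painted last. Intensities are class mean + N(0, noise_sigma),
    clipped to [0, 255] and rounded half up.
    """
    h, w = spec.height, spec.width
    k = spec.n_classes
    truth = np.zeros((h, w), dtype=np.int64)
    nested = [c for c in range(1, k) if spec.lesion is None or c != spec.lesion[3]]
    n = len(nested)
    for i, cls in enumerate(nested):
        frac = (n - i) / (n + 1)
        ry = max(frac * 0.48 * h, 0.51)
        rx = max(frac * 0.48 * w * 1.08, 0.51)
        truth[_ellipse_mask(h, w, ry, rx)] = cls
    if spec.lesion is not None:
        row, col, radius, cls = spec.lesion
        rows = np.arange(h)[:, None] - row
        cols = np.arange(w)[None, :] - col
        truth[rows**2 + cols**2 <= radius**2] = cls
    for cls in range(k):
        if not np.any(truth == cls):
            raise ValidationError(
                f"class {cls} is empty for a {h}x{w} phantom; enlarge the image "
                "or move the lesion"
            )
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.class_means, dtype=np.float64)
    noisy = means[truth] + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.floor(np.clip(noisy, 0.0, 255.0) + 0.5).astype(np.uint8)
    return Phantom(image=image, truth=truth, spec=spec)


def generate_bilevel(
    height: int,
    width: int,
    low: int,
    high: int,
    fraction: float,
    seed: int | None = None,
) -> Phantom:
    """Noiseless two-level phantom: a random pixel subset of the given
    fraction is set to ``high`` (class 1), the rest to ``low`` (class 0).

    ``round(fraction * height * width)`` pixels are high, so at fraction 0.5
    on an even-sized image the split is exactly half — the fixture on which
    Otsu's variance is hand-checkable.
    """
    if not (0 <= low < high <= 255):
        raise ValidationError("need 0 <= low < high <= 255")
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must lie strictly between 0 and 1")
    n = height * width
    n_high = int(np.floor(fraction * n + 0.5))
    if n_high == 0 or n_high == n:
        raise ValidationError("fraction leaves one class empty at this image size")
    rng = np.random.default_rng(seed)
    flat = np.zeros(n, dtype=np.int64)
    flat[rng.permutation(n)[:n_high]] = 1
    truth = flat.reshape(height, width)
    image = np.where(truth == 1, high, low).astype(np.uint8)
    spec = PhantomSpec(
        height=height,
        width=width,
        class_means=(low, high),
        noise_sigma=0.0,
        seed=seed,
    )
    return Phantom(image=image, truth=truth, spec=spec)
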