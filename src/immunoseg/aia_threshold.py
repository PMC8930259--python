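"""Otsu thresholding by clonal selection.

The antigen is the between-class variance of a binary split of the intensity
histogram at threshold ``t``: with class 0 the pixels of intensity ``<= t``
(background) and class 1 those ``> t`` (target; lesions are hyperintense on
FLAIR/DWI, hence the direction),

    sigma_b^2(t) = V0 * (w0 - V)^2 + V1 * (w1 - V)^2,

where ``V0, V1`` are the class proportions, ``w0, w1`` the class mean gray
levels (0 for an empty class), and ``V = V0*w0 + V1*w1`` the total mean. The
antibody is the 8-bit code of ``t``; the immune loop maximizes the raw
variance (the multiplicative concentration correction is scale-covariant, so
no rescaling to [0, 1] is needed). An exhaustive scan over all 256 thresholds
serves as the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .image_io import GrayImage, Histogram, as_gray_image, histogram
from .immune_core import (
    Antibody,
    ConvergenceTrace,
    ImmuneParams,
    decode_gray,
    run_immune,
    stall_stop,
)

__all__ = [
    "ThresholdResult",
    "class_stats",
    "between_class_variance",
    "variance_table",
    "exhaustive_otsu",
    "aia_threshold",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a thresholding run: the gray-level threshold, the
    between-class variance attained there, the binary mask (0 = background
    ``<= t``, 1 = target ``> t``), and the optimizer's convergence trace."""

    threshold: int
    variance: float
    mask: np.ndarray
    trace: ConvergenceTrace


def class_stats(hist: Histogram, t: int) -> tuple[float, float, float, float, float]:
    """Class proportions and mean gray levels of the split at ``t``.

    Returns ``(V0, w0, V1, w1, V)``: proportion and mean of the ``<= t``
    class, proportion and mean of the ``> t`` class, and the total mean
    ``V = V0*w0 + V1*w1`` (the image's global mean whenever both classes are
    nonempty). An empty class has mean 0 by convention.
    """
    if not (0 <= t <= 255):
        raise ValidationError(f"threshold must lie in [0, 255], got {t}")
    counts = hist.counts
    g = np.arange(256, dtype=np.float64)
    n0 = int(counts[: t + 1].sum())
    n1 = hist.total - n0
    v0 = n0 / hist.total
    v1 = n1 / hist.total
    w0 = float((counts[: t + 1] * g[: t + 1]).sum() / n0) if n0 > 0 else 0.0
    w1 = float((counts[t + 1 :] * g[t + 1 :]).sum() / n1) if n1 > 0 else 0.0
    v = v0 * w0 + v1 * w1
    return v0, w0, v1, w1, v


def between_class_variance(hist: Histogram, t: int) -> float:
    """Otsu's between-class variance at threshold ``t``; zero when either
    class is empty. Algebraically equal to ``V0*V1*(w0 - w1)^2``."""
    v0, w0, v1, w1, v = class_stats(hist, t)
    return v0 * (w0 - v) ** 2 + v1 * (w1 - v) ** 2


def variance_table(hist: Histogram) -> np.ndarray:
    """Between-class variance at every threshold 0..255, vectorized.

    Used both by the exhaustive oracle and as the immune loop's O(1)
    objective lookup; identical arithmetic to :func:`between_class_variance`
    up to floating-point reassociation.
    """
    counts = hist.counts.astype(np.float64)
    g = np.arange(256, dtype=np.float64)
    cum_n = np.cumsum(counts)
    cum_s = np.cumsum(counts * g)
    n0 = cum_n  # pixels <= t
    n1 = hist.total - n0
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = np.where(n0 > 0, cum_s / n0, 0.0)
        w1 = np.where(n1 > 0, (cum_s[-1] - cum_s) / n1, 0.0)
    v0 = n0 / hist.total
    v1 = n1 / hist.total
    v = v0 * w0 + v1 * w1
    return v0 * (w0 - v) ** 2 + v1 * (w1 - v) ** 2


def exhaustive_otsu(hist: Histogram) -> tuple[int, float]:
    """Scan all 256 thresholds; return the smallest ``t`` attaining the
    maximum between-class variance, with that variance."""
    table = variance_table(hist)
    t = int(np.argmax(table))  # argmax returns the first (smallest) maximizer
    return t, float(table[t])


def aia_threshold(img: GrayImage, params: ImmuneParams | None = None) -> ThresholdResult:
    """Threshold *img* with the clonal-selection optimizer.

    The antibody is the 8-bit code of the threshold; antigen affinity is the
    between-class variance; the run stops when the memory-cell affinity has
    stalled for ``params.stall_gens`` generations or at ``params.maxgen``.
    The reported variance is exactly the objective at the returned threshold,
    and the mask applies the ``> t`` rule.
    """
    img = as_gray_image(img)
    if params is None:
        params = ImmuneParams()
    hist = histogram(img)
    table = variance_table(hist)

    def affinity(ab: Antibody) -> float:
        return float(table[decode_gray(ab)])

    best, trace = run_immune(
        affinity, L=8, params=params, stop=stall_stop(params.stall_gens)
    )
    t = decode_gray(best)
    mask = (img > t).astype(np.uint8)
    return ThresholdResult(threshold=t, variance=float(table[t]), mask=mask, trace=trace)
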