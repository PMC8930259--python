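"""Immune clustering: clonal selection hybridized with K-means.

An antibody encodes K cluster centers as K concatenated 8-bit gray values.
The antigen objective is the within-cluster sum of squared intensity
differences

    J = sum_j sum_{x in cluster j} (x - D_j)^2,

with each pixel assigned to its nearest center (ties to the lowest center
index); antigen affinity is ``1 / (1 + J)``, so smaller J means stronger
binding. Antibody-antibody affinity uses the squared Euclidean distance
between decoded center sets, ``1 / (1 + sum_k (c_k - c'_k)^2)``.

The hybrid step: each generation the memory-cell (elite) antibody is decoded,
polished by Lloyd iterations (K-means), re-encoded and re-injected if its J
improved — the immune loop supplies global search over initial centers, Lloyd
the strong local descent. The run stops at ``maxgen`` or once the improvement
over the initial elite objective, ``|J1 - J*|``, has reached its threshold
and the elite has stopped changing.

Because the feature is scalar intensity, J and the Lloyd updates are computed
on the 256-bin histogram; this is exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import ValidationError
from .image_io import GrayImage, as_gray_image, histogram
from .immune_core import (
    Antibody,
    ConvergenceTrace,
    ImmuneParams,
    decode_values,
    encode_values,
    run_immune,
)

__all__ = [
    "CenterSet",
    "SegmentationResult",
    "assign_pixels",
    "within_cluster_ss",
    "antigen_affinity_ica",
    "ab_affinity_euclid",
    "kmeans_refine",
    "ica_segment",
    "order_labels_by_center",
]

#: Cluster centers: 1-D integer array of K gray levels in [0, 255]; order is
#: significant — the cluster label is the center's index.
CenterSet = np.ndarray

_K_MIN, _K_MAX = 2, 16


def _check_centers(centers: Sequence[int] | np.ndarray) -> CenterSet:
    arr = np.asarray(centers)
    if arr.ndim != 1 or not (_K_MIN <= arr.size <= _K_MAX):
        raise ValidationError(
            f"need between {_K_MIN} and {_K_MAX} centers, got shape {arr.shape}"
        )
    if np.any(arr != np.floor(arr)) or arr.min() < 0 or arr.max() > 255:
        raise ValidationError("centers must be integers in [0, 255]")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class SegmentationResult:
    """Outcome of a clustering run.

    ``labels`` assigns every pixel a cluster index 0..K-1 (label = index of
    the center as encoded); ``centers`` are the decoded gray-level centers;
    ``J`` the within-cluster sum of squares recomputed from labels and
    centers; ``J1`` the initial elite objective the stopping rule measures
    improvement against; ``trace`` the optimizer's convergence record.
    """

    labels: np.ndarray
    centers: CenterSet
    J: float
    J1: float
    trace: ConvergenceTrace


def _labels_of_gray(centers: CenterSet) -> np.ndarray:
    """Nearest-center label for each of the 256 gray levels (ties -> lowest
    center index, since argmin returns the first minimizer)."""
    g = np.arange(256, dtype=np.int64)
    d2 = (g[:, None] - centers[None, :]) ** 2
    return np.argmin(d2, axis=1)


def assign_pixels(img: GrayImage, centers: CenterSet) -> np.ndarray:
    """Label each pixel with the index of its nearest center (squared
    intensity difference; ties go to the lowest center index)."""
    img = as_gray_image(img)
    centers = _check_centers(centers)
    return _labels_of_gray(centers)[img]


def _wcss_from_hist(counts: np.ndarray, centers: CenterSet) -> float:
    g = np.arange(256, dtype=np.int64)
    d2 = (g[:, None] - centers[None, :]) ** 2
    return float((counts * d2.min(axis=1)).sum())


def within_cluster_ss(img: GrayImage, centers: CenterSet) -> float:
    """Within-cluster sum of squares J under :func:`assign_pixels`."""
    img = as_gray_image(img)
    centers = _check_centers(centers)
    return _wcss_from_hist(histogram(img).counts, centers)


def antigen_affinity_ica(J: float) -> float:
    """Antigen affinity ``1 / (1 + J)``: strictly decreasing in J, equal to 1
    exactly when the clustering fits perfectly (J = 0)."""
    if J < 0:
        raise ValidationError("within-cluster sum of squares cannot be negative")
    return 1.0 / (1.0 + J)


def ab_affinity_euclid(a: Antibody, b: Antibody) -> float:
    """Antibody-antibody affinity ``1 / (1 + s)`` with s the squared
    Euclidean distance between the decoded center sets, position-wise."""
    ca, cb = decode_values(a), decode_values(b)
    if ca.size != cb.size:
        raise ValidationError("antibodies must decode to equally many centers")
    s = float(((ca - cb) ** 2).sum())
    return 1.0 / (1.0 + s)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def kmeans_refine(
    img: GrayImage, centers: CenterSet, max_iter: int = 100
) -> CenterSet:
    """Lloyd iterations on the intensity histogram.

    Alternates nearest-center assignment and center update (rounded half-up
    mean intensity of the assigned pixels; an empty cluster keeps its
    previous center) until the gray-level assignment map no longer changes or
    ``max_iter`` is reached. J never increases across an iteration beyond the
    K/4 slack that integer rounding of the means can introduce.
    """
    img = as_gray_image(img)
    centers = _check_centers(centers).copy()
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    counts = histogram(img).counts
    g = np.arange(256, dtype=np.int64)
    labels = _labels_of_gray(centers)
    for _ in range(max_iter):
        new_centers = centers.copy()
        for j in range(centers.size):
            sel = labels == j
            n_j = counts[sel].sum()
            if n_j > 0:
                new_centers[j] = _round_half_up(
                    np.array((counts[sel] * g[sel]).sum() / n_j)
                )
        new_labels = _labels_of_gray(new_centers)
        centers = new_centers
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return centers


def _improvement_stop(
    j_tol_rel: float, stall_gens: int
) -> Callable[[ConvergenceTrace], bool]:
    """Stop once |J1 - J*| has met its threshold (relative to J1) and the
    elite objective has been flat for ``stall_gens`` generations."""

    def stop(trace: ConvergenceTrace) -> bool:
        if len(trace) <= stall_gens or trace.initial_elite_objective is None:
            return False
        j1 = trace.initial_elite_objective
        j_star = trace.best_objective[-1]
        if abs(j1 - j_star) < j_tol_rel * j1:
            return False
        return trace.best_objective[-1] == trace.best_objective[-1 - stall_gens]

    return stop


def ica_segment(
    img: GrayImage, K: int = 4, params: ImmuneParams | None = None
) -> SegmentationResult:
    """Cluster *img* into K intensity classes with the immune/K-means hybrid.

    The antibody is the 8K-bit encoding of K centers; antigen affinity is
    ``1/(1+J)``; pairwise affinity is Euclidean on decoded centers; the elite
    is Lloyd-refined every generation. Returns labels from the final centers,
    with J recomputed from them for internal consistency.
    """
    img = as_gray_image(img)
    if not (_K_MIN <= K <= _K_MAX):
        raise ValidationError(f"K must lie in [{_K_MIN}, {_K_MAX}], got {K}")
    if params is None:
        params = ImmuneParams(popsize=30, maxgen=300)
    counts = histogram(img).counts
    g = np.arange(256, dtype=np.int64)
    # J for every gray level against every possible center value, precomputed
    d2_all = (g[:, None] - g[None, :]) ** 2  # (gray, center)

    def j_of(ab: Antibody) -> float:
        centers = decode_values(ab)
        return float((counts * d2_all[:, centers].min(axis=1)).sum())

    def affinity(ab: Antibody) -> float:
        return antigen_affinity_ica(j_of(ab))

    def pair_matrix(pop: np.ndarray) -> np.ndarray:
        centers = np.packbits(pop, axis=1).astype(np.int64)  # (N, K)
        s = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return 1.0 / (1.0 + s)

    def refine(ab: Antibody) -> Antibody:
        centers = decode_values(ab)
        return encode_values(list(kmeans_refine(img, centers)))

    best, trace = run_immune(
        affinity,
        L=8 * K,
        params=params,
        stop=_improvement_stop(params.j_tol_rel, params.stall_gens),
        objective=j_of,
        pair_affinity_matrix=pair_matrix,
        refine=refine,
    )
    centers = decode_values(best)
    labels = assign_pixels(img, centers)
    j_final = within_cluster_ss(img, centers)
    j1 = trace.initial_elite_objective
    assert j1 is not None
    return SegmentationResult(
        labels=labels, centers=centers, J=j_final, J1=float(j1), trace=trace
    )


def order_labels_by_center(result: SegmentationResult) -> tuple[np.ndarray, CenterSet]:
    """Relabel clusters so class indices follow ascending center intensity —
    the deterministic convention used to match clusters to phantom truth
    classes (whose means are strictly increasing)."""
    order = np.argsort(result.centers, kind="stable")
    remap = np.empty(result.centers.size, dtype=np.int64)
    remap[order] = np.arange(result.centers.size)
    return remap[result.labels], result.centers[order]
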