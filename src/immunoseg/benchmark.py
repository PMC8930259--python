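"""AIA-vs-ICA benchmark harness on phantoms.

Mirrors the study design of comparing a deterministic Otsu baseline
("plain-otsu"), the clonal-selection thresholder ("aia") and the immune
clusterer ("ica") as the number of segmentation classes K sweeps: for each
(K, replicate, algorithm) a fresh phantom is generated, segmented and scored,
and the per-class metrics land in one long-format table. Every row carries
the seed and parameters that reproduce it.

The two-class thresholders are scored against the K-class truth via the
greedy maximum-overlap label matching, so their volume fractions degrade
honestly as K grows — a binary split cannot cover four tissue classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aia_threshold import aia_threshold, exhaustive_otsu
from .exceptions import ValidationError
from .ica_segment import ica_segment, order_labels_by_center
from .image_io import histogram
from .immune_core import ImmuneParams
from .metrics import evaluate
from .phantom import PhantomSpec, generate_phantom

__all__ = ["BenchmarkConfig", "benchmark", "summarize"]

_ALGORITHMS = ("plain-otsu", "aia", "ica")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Sweep definition: class counts K, replicate seeds, algorithm arms, and
    the phantom geometry shared by all cells."""

    ks: tuple[int, ...] = (2, 3, 4, 5)
    replicates: int = 5
    seed: int = 0
    algorithms: tuple[str, ...] = _ALGORITHMS
    size: int = 64
    noise_sigma: float = 8.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("need at least one replicate")
        if any(k < 2 for k in self.ks) or not self.ks:
            raise ValidationError("every K must be >= 2")
        bad = set(self.algorithms) - set(_ALGORITHMS)
        if bad or not self.algorithms:
            raise ValidationError(f"unknown algorithms {sorted(bad)}")


def _class_means(k: int) -> tuple[int, ...]:
    return tuple(int(np.floor(m + 0.5)) for m in np.linspace(30, 220, k))


def _segment(algorithm, phantom, k, seed):
    """Run one arm; returns (labels, objective, generations)."""
    if algorithm == "plain-otsu":
        t, var = exhaustive_otsu(histogram(phantom.image))
        return (phantom.image > t).astype(np.int64), var, 0
    if algorithm == "aia":
        res = aia_threshold(phantom.image, ImmuneParams(seed=seed))
        return res.mask.astype(np.int64), res.variance, len(res.trace)
    res = ica_segment(
        phantom.image, K=k, params=ImmuneParams(popsize=30, maxgen=300, seed=seed)
    )
    labels, _ = order_labels_by_center(res)
    return labels, res.J, len(res.trace)


def benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Run the sweep; one row per (algorithm, K, replicate, class).

    Columns: algorithm, K, replicate, seed, class, TP, FP, FN, TN, PR, TPVF,
    FNVF, FPVF, objective (variance or J), generations, error. A failing cell
    is recorded in its ``error`` column and the sweep continues.
    """
    seed_rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for k in config.ks:
        for rep in range(config.replicates):
            cell_seed = int(seed_rng.integers(0, 2**31 - 1))
            phantom = generate_phantom(
                PhantomSpec(
                    height=config.size,
                    width=config.size,
                    class_means=_class_means(k),
                    noise_sigma=config.noise_sigma,
                    seed=cell_seed,
                )
            )
            for algorithm in config.algorithms:
                base = {
                    "algorithm": algorithm,
                    "K": k,
                    "replicate": rep,
                    "seed": cell_seed,
                }
                try:
                    labels, objective, gens = _segment(
                        algorithm, phantom, k, cell_seed
                    )
                    report = evaluate(labels, phantom.truth, match=True)
                    for rec in report.per_class.to_dict("records"):
                        rows.append(
                            base
                            | rec
                            | {
                                "objective": objective,
                                "generations": gens,
                                "error": "",
                            }
                        )
                except Exception as exc:  # record the failure, keep sweeping
                    rows.append(
                        base
                        | {"class": -1, "objective": np.nan, "generations": 0,
                           "error": f"{type(exc).__name__}: {exc}"}
                    )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of each metric per algorithm x K, macro
    averaged over classes within a replicate first."""
    ok = results[results["error"] == ""]
    macro = (
        ok.groupby(["algorithm", "K", "replicate"])[["PR", "TPVF", "FNVF", "FPVF"]]
        .mean()
        .reset_index()
    )
    return (
        macro.groupby(["algorithm", "K"])[["PR", "TPVF", "FNVF", "FPVF"]]
        .agg(["mean", "std"])
        .reset_index()
    )
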