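"""Shared clonal-selection engine.

Both optimizers in this package — the Otsu thresholder and the immune/K-means
hybrid clusterer — run the same artificial-immune generation loop and differ
only in their objective (the *antigen affinity*), their antibody-antibody
similarity, and their stopping rule. The immune metaphor maps as follows:

* **antigen** — the optimization problem (a segmentation objective over an
  image);
* **antibody** — a candidate solution, a fixed-length bitstring encoding one
  or more 8-bit gray values;
* **antigen affinity** — objective quality of a solution;
* **antibody-antibody affinity** — similarity of two solutions, used to
  measure crowding;
* **concentration** ``D_i`` — fraction of the population whose affinity with
  antibody *i* exceeds the affinity constant ``lambda_``;
* **adjusted fitness** — ``affinity * exp(k * D_i)`` with ``k < 0``, which
  penalizes crowded antibodies to preserve diversity;
* **memory cell** — elitist store of the best antibody ever evaluated.

Each generation: evaluate affinities, update the memory cell, (optionally)
locally refine the elite, compute concentrations and adjusted fitness, clone
the top-ranked antibodies, cross them with a freshly drawn random antibody
group, mutate a single bit, re-evaluate, and form the next population from
the mutated group with the memory cell re-injected.

All randomness flows through a single ``numpy.random.Generator`` seeded from
``ImmuneParams.seed``, so every run is bit-exact reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ComputationError, ValidationError

__all__ = [
    "Antibody",
    "ImmuneParams",
    "ConvergenceTrace",
    "encode_gray",
    "decode_gray",
    "encode_values",
    "decode_values",
    "hamming",
    "ab_affinity_hamming",
    "concentration",
    "adjusted_fitness",
    "clone_select",
    "crossover",
    "mutate",
    "run_immune",
    "stall_stop",
]

#: An antibody: 1-D uint8 array of {0,1}, length a positive multiple of 8,
#: most-significant bit first within each 8-bit block.
Antibody = np.ndarray


@dataclass(frozen=True)
class ImmuneParams:
    """Constants of the clonal-selection loop.

    Parameters
    ----------
    popsize : population size N (>= 2).
    maxgen : generation cap.
    qc : crossover probability per clone, in [0, 1].
    qm : mutation probability per antibody, in [0, 1].
    lambda_ : affinity constant for the concentration count, in [0.9, 1].
    k : concentration penalty exponent, strictly negative.
    mc : candidate-clone constant; rank r receives ``max(1, round(mc / r))``
        clones (half-up rounding).
    stall_gens : consecutive no-improvement generations after which the
        thresholder stops (and the clusterer's convergence check arms).
    j_tol_rel : clusterer stopping threshold on the improvement |J1 - J*|,
        relative to the initial elite objective J1.
    seed : RNG seed; ``None`` draws entropy from the OS.
    """

    popsize: int = 20
    maxgen: int = 200
    qc: float = 0.6
    qm: float = 0.06
    lambda_: float = 0.95
    k: float = -0.8
    mc: int = 10
    stall_gens: int = 20
    j_tol_rel: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.popsize < 2:
            raise ValidationError("popsize must be >= 2")
        if self.maxgen < 1:
            raise ValidationError("maxgen must be >= 1")
        if not (0.0 <= self.qc <= 1.0 and 0.0 <= self.qm <= 1.0):
            raise ValidationError("qc and qm must lie in [0, 1]")
        if not (0.9 <= self.lambda_ <= 1.0):
            raise ValidationError("lambda_ must lie in [0.9, 1]")
        if self.k >= 0:
            raise ValidationError("k must be negative")
        if not (1 <= self.mc <= self.popsize):
            raise ValidationError("mc must satisfy 1 <= mc <= popsize")
        if self.stall_gens < 1:
            raise ValidationError("stall_gens must be >= 1")
        if self.j_tol_rel < 0:
            raise ValidationError("j_tol_rel must be >= 0")

    def with_seed(self, seed: int | None) -> "ImmuneParams":
        return replace(self, seed=seed)


@dataclass
class ConvergenceTrace:
    """Per-generation record of the run: generation index, memory-cell
    (best-ever) antigen affinity, the corresponding objective value, and the
    population mean concentration."""

    generation: list[int] = field(default_factory=list)
    best_affinity: list[float] = field(default_factory=list)
    best_objective: list[float] = field(default_factory=list)
    mean_concentration: list[float] = field(default_factory=list)
    #: Objective of the best antibody of the *initial* population, recorded
    #: before any local refinement (the clusterer's J1).
    initial_elite_objective: float | None = None

    def append(self, gen: int, aff: float, obj: float, conc: float) -> None:
        self.generation.append(gen)
        self.best_affinity.append(aff)
        self.best_objective.append(obj)
        self.mean_concentration.append(conc)

    def __len__(self) -> int:
        return len(self.generation)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "best_affinity": self.best_affinity,
                "best_objective": self.best_objective,
                "mean_concentration": self.mean_concentration,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------- encoding

def encode_gray(value: int) -> Antibody:
    """Encode one gray value as 8 bits, most-significant bit first."""
    if not (0 <= int(value) <= 255) or value != int(value):
        raise ValidationError(f"gray value must be an integer in [0, 255], got {value}")
    return np.unpackbits(np.array([int(value)], dtype=np.uint8))


def decode_gray(bits: Antibody) -> int:
    """Invert :func:`encode_gray` on one 8-bit block."""
    bits = _check_bits(bits)
    if bits.size != 8:
        raise ValidationError("decode_gray expects exactly 8 bits")
    return int(np.packbits(bits)[0])


def encode_values(values: Sequence[int]) -> Antibody:
    """Concatenate 8-bit encodings of several gray values."""
    if len(values) == 0:
        raise ValidationError("need at least one value to encode")
    return np.concatenate([encode_gray(v) for v in values])


def decode_values(bits: Antibody) -> np.ndarray:
    """Decode a multiple-of-8 bitstring into its gray values, in order."""
    bits = _check_bits(bits)
    return np.packbits(bits).astype(np.int64)


def _check_bits(bits: np.ndarray) -> Antibody:
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1 or arr.size == 0 or arr.size % 8 != 0:
        raise ValidationError("antibody length must be a positive multiple of 8")
    if np.any(arr > 1):
        raise ValidationError("antibody bits must be 0 or 1")
    return arr


# ---------------------------------------------------------------- affinities

def hamming(a: Antibody, b: Antibody) -> int:
    """Number of positions at which two equal-length antibodies differ."""
    a, b = _check_bits(a), _check_bits(b)
    if a.size != b.size:
        raise ValidationError("antibodies must have equal length")
    return int(np.count_nonzero(a != b))


def ab_affinity_hamming(a: Antibody, b: Antibody) -> float:
    """Antibody-antibody binding strength ``1 / (1 + Hamming distance)``."""
    return 1.0 / (1.0 + hamming(a, b))


def concentration(
    pop: Sequence[Antibody],
    i: int,
    lambda_: float,
    pair_affinity: Callable[[Antibody, Antibody], float] = ab_affinity_hamming,
) -> float:
    """Fraction of the population whose affinity with antibody *i* exceeds
    ``lambda_``; antibody *i* itself always counts, so the value lies in
    ``[1/N, 1]``."""
    n = len(pop)
    if n == 0:
        raise ValidationError("population is empty")
    if not (0 <= i < n):
        raise ValidationError(f"index {i} out of range for population of {n}")
    count = sum(1 for j in range(n) if pair_affinity(pop[i], pop[j]) > lambda_)
    return count / n


def adjusted_fitness(affinity: float, d_i: float, k: float) -> float:
    """Diversity-corrected fitness ``affinity * exp(k * D_i)``, ``k < 0``.

    Strictly decreasing in the concentration ``D_i`` for fixed affinity, so
    crowded antibodies are demoted without reordering antibodies that share
    the same concentration.
    """
    if affinity < 0:
        raise ValidationError("affinity must be nonnegative")
    if k >= 0:
        raise ValidationError("k must be negative")
    return affinity * math.exp(k * d_i)


# ---------------------------------------------------------------- operators

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def clone_select(
    pop: Sequence[Antibody], fitnesses: Sequence[float], mc: int
) -> list[Antibody]:
    """Rank-proportional cloning of the fittest antibodies.

    The population is sorted by fitness descending (ties broken by original
    index, stable); the top ``m = ceil(N/2)`` are copied, rank ``r`` (1-based)
    receiving ``max(1, round(mc / r))`` clones with half-up rounding. The
    highest-fitness antibody always heads the clone group.
    """
    n = len(pop)
    if n == 0:
        raise ValidationError("population is empty")
    if mc > n:
        raise ValidationError(f"mc={mc} exceeds population size {n}")
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    if fitnesses.shape != (n,):
        raise ValidationError("one fitness per antibody required")
    order = np.argsort(-fitnesses, kind="stable")
    m = math.ceil(n / 2)
    clones: list[Antibody] = []
    for rank, idx in enumerate(order[:m], start=1):
        n_copies = max(1, _round_half_up(mc / rank))
        clones.extend(np.array(pop[idx], dtype=np.uint8, copy=True) for _ in range(n_copies))
    return clones


def crossover(
    clones: Sequence[Antibody], qc: float, rng: np.random.Generator
) -> list[Antibody]:
    """Single-point crossover of each clone with a fresh random antibody.

    A random antibody group of equal size is drawn; each clone, with
    probability ``qc``, takes the suffix from a uniformly chosen cut point
    (cut 0 = full replacement) of its partner; otherwise it passes unchanged.
    """
    if len(clones) == 0:
        raise ValidationError("clone group is empty")
    length = clones[0].size
    partners = rng.integers(0, 2, size=(len(clones), length), dtype=np.uint8)
    out: list[Antibody] = []
    for clone, partner in zip(clones, partners):
        child = np.array(clone, dtype=np.uint8, copy=True)
        if rng.random() < qc:
            cut = int(rng.integers(0, length))
            child[cut:] = partner[cut:]
        out.append(child)
    return out


def mutate(
    group: Sequence[Antibody], qm: float, rng: np.random.Generator
) -> list[Antibody]:
    """With probability ``qm`` per antibody, flip exactly one uniformly
    chosen bit; the output is always within Hamming distance 1 of the input."""
    if len(group) == 0:
        raise ValidationError("antibody group is empty")
    out: list[Antibody] = []
    for ab in group:
        child = np.array(ab, dtype=np.uint8, copy=True)
        if rng.random() < qm:
            pos = int(rng.integers(0, child.size))
            child[pos] ^= 1
        out.append(child)
    return out


# ---------------------------------------------------------------- main loop

def stall_stop(stall_gens: int) -> Callable[[ConvergenceTrace], bool]:
    """Stopping rule: the memory-cell affinity has not changed over the last
    ``stall_gens`` generations."""

    def stop(trace: ConvergenceTrace) -> bool:
        if len(trace) <= stall_gens:
            return False
        return trace.best_affinity[-1] == trace.best_affinity[-1 - stall_gens]

    return stop


def _pairwise_hamming_affinity(pop: np.ndarray) -> np.ndarray:
    diff = (pop[:, None, :] != pop[None, :, :]).sum(axis=2)
    return 1.0 / (1.0 + diff)


def run_immune(
    antigen_affinity: Callable[[Antibody], float],
    L: int,
    params: ImmuneParams,
    stop: Callable[[ConvergenceTrace], bool] | None = None,
    *,
    objective: Callable[[Antibody], float] | None = None,
    pair_affinity_matrix: Callable[[np.ndarray], np.ndarray] | None = None,
    refine: Callable[[Antibody], Antibody] | None = None,
) -> tuple[Antibody, ConvergenceTrace]:
    """Run the clonal-selection generation loop.

    Parameters
    ----------
    antigen_affinity : objective map Antibody -> float (maximized).
    L : antibody bit length, a positive multiple of 8.
    params : loop constants (see :class:`ImmuneParams`).
    stop : optional stopping rule evaluated on the trace each generation;
        defaults to the stall rule with ``params.stall_gens``.
    objective : value recorded in the trace alongside affinity (the
        clusterer's J); defaults to the affinity itself.
    pair_affinity_matrix : maps the (N, L) population array to an (N, N)
        antibody-antibody affinity matrix; defaults to Hamming-based
        ``1/(1+d)``.
    refine : optional local-search hook applied to the memory cell each
        generation; the refined antibody replaces it only if its affinity
        improves (the hybrid clusterer's Lloyd step).

    Returns
    -------
    (best antibody ever evaluated, convergence trace). The trace's best
    affinity is monotone non-decreasing by construction of the memory cell.
    """
    if L < 8 or L % 8 != 0:
        raise ValidationError("L must be a positive multiple of 8")
    if objective is None:
        objective = antigen_affinity
    if pair_affinity_matrix is None:
        pair_affinity_matrix = _pairwise_hamming_affinity
    if stop is None:
        stop = stall_stop(params.stall_gens)

    rng = np.random.default_rng(params.seed)
    pop = rng.integers(0, 2, size=(params.popsize, L), dtype=np.uint8)

    trace = ConvergenceTrace()
    best_bits: Antibody | None = None
    best_aff = -math.inf
    best_obj = math.nan

    def evaluate(ab: Antibody) -> float:
        aff = float(antigen_affinity(ab))
        if not math.isfinite(aff):
            raise ComputationError(
                f"antigen affinity is not finite for antibody {np.packbits(ab)}"
            )
        return aff

    for gen in range(params.maxgen):
        affs = np.array([evaluate(ab) for ab in pop])
        i_best = int(np.argmax(affs))
        if affs[i_best] > best_aff:
            best_aff = affs[i_best]
            best_bits = pop[i_best].copy()
            best_obj = float(objective(best_bits))
        if gen == 0:
            trace.initial_elite_objective = best_obj
        if refine is not None and best_bits is not None:
            refined = np.asarray(refine(best_bits), dtype=np.uint8)
            aff_r = evaluate(refined)
            if aff_r > best_aff:
                best_aff = aff_r
                best_bits = refined.copy()
                best_obj = float(objective(best_bits))

        pair = pair_affinity_matrix(pop)
        conc = (pair > params.lambda_).sum(axis=1) / params.popsize
        fit = affs * np.exp(params.k * conc)

        trace.append(gen, best_aff, best_obj, float(conc.mean()))
        if stop(trace):
            break

        clones = clone_select(list(pop), fit, params.mc)
        crossed = crossover(clones, params.qc, rng)
        mutated = mutate(crossed, params.qm, rng)

        # re-evaluate the varied group and let its champion update the memory
        m_affs = np.array([evaluate(ab) for ab in mutated])
        j_best = int(np.argmax(m_affs))
        if m_affs[j_best] > best_aff:
            best_aff = float(m_affs[j_best])
            best_bits = mutated[j_best].copy()
            best_obj = float(objective(best_bits))

        # next generation: elitist re-injection of the memory cell, then the
        # mutated group with duplicates suppressed (crowding is penalized by
        # the concentration term; letting copies also fill the population
        # would collapse diversity and invite premature convergence), the
        # last fifth of the population renewed with fresh random antibodies
        # (the classic clonal-selection newcomer influx), and any shortfall
        # padded randomly as well
        n_new = params.popsize // 5
        nxt = [best_bits.copy()]
        seen = {best_bits.tobytes()}
        for ab in mutated:
            if len(nxt) == params.popsize - n_new:
                break
            key = ab.tobytes()
            if key not in seen:
                seen.add(key)
                nxt.append(ab)
        short = params.popsize - len(nxt)
        if short > 0:
            nxt.extend(rng.integers(0, 2, size=(short, L), dtype=np.uint8))
        pop = np.array(nxt, dtype=np.uint8)

    assert best_bits is not None
    return best_bits, trace
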