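"""The clonal-selection engine: encoding, affinities, operators, main loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoseg import (
    ComputationError,
    ImmuneParams,
    ValidationError,
    ab_affinity_hamming,
    adjusted_fitness,
    clone_select,
    concentration,
    crossover,
    decode_gray,
    decode_values,
    encode_gray,
    encode_values,
    hamming,
    mutate,
    run_immune,
)
from immunoseg.immune_core import stall_stop


class TestEncoding:
    @pytest.mark.parametrize(
        "value, bits",
        [(0, "00000000"), (255, "11111111"), (128, "10000000"), (200, "11001000")],
    )
    def test_msb_first(self, value, bits):
        assert "".join(map(str, encode_gray(value))) == bits

    @given(st.integers(0, 255))
    @settings(derandomize=True)
    def test_decode_inverts_encode(self, v):
        assert decode_gray(encode_gray(v)) == v

    def test_multi_value_roundtrip(self):
        vals = [3, 128, 255, 0]
        assert decode_values(encode_values(vals)).tolist() == vals

    @pytest.mark.parametrize("bad", [-1, 256, 3.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            encode_gray(bad)


class TestAffinities:
    def test_hamming_known_values(self):
        zeros, ones = encode_gray(0), encode_gray(255)
        assert hamming(zeros, ones) == 8
        assert hamming(ones, ones) == 0
        assert hamming(encode_gray(128), encode_gray(1)) == 2

    def test_hamming_length_mismatch(self):
        with pytest.raises(ValidationError):
            hamming(encode_gray(0), encode_values([0, 0]))

    def test_pair_affinity_values_and_symmetry(self, rng):
        assert ab_affinity_hamming(encode_gray(7), encode_gray(7)) == 1.0
        assert ab_affinity_hamming(encode_gray(0), encode_gray(255)) == pytest.approx(1 / 9)
        for _ in range(20):
            a = rng.integers(0, 2, 16, dtype=np.uint8)
            b = rng.integers(0, 2, 16, dtype=np.uint8)
            assert ab_affinity_hamming(a, b) == ab_affinity_hamming(b, a)

    def test_concentration_identical_population(self):
        pop = [encode_gray(42) for _ in range(6)]
        assert all(concentration(pop, i, 0.95) == 1.0 for i in range(6))

    def test_concentration_isolated_antibody(self):
        # lambda 0.95 admits only exact matches under Hamming affinity
        pop = [encode_gray(0), encode_gray(255), encode_gray(129)]
        assert concentration(pop, 0, 0.95) == pytest.approx(1 / 3)

    def test_concentration_matches_double_loop(self, rng):
        pop = [rng.integers(0, 2, 8, dtype=np.uint8) for _ in range(10)]
        lam = 0.9
        for i in range(10):
            brute = (
                sum(1 for j in range(10) if ab_affinity_hamming(pop[i], pop[j]) > lam)
                / 10
            )
            assert concentration(pop, i, lam) == pytest.approx(brute)

    def test_concentration_bounds(self, rng):
        pop = [rng.integers(0, 2, 8, dtype=np.uint8) for _ in range(7)]
        for i in range(7):
            assert 1 / 7 <= concentration(pop, i, 0.95) <= 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValidationError):
            concentration([], 0, 0.95)


class TestAdjustedFitness:
    @pytest.mark.parametrize(
        "aff, d, k, expected",
        [
            (0.7, 0.0, -0.8, 0.7),
            (0.5, 1.0, -0.8, 0.5 * math.exp(-0.8)),  # ~0.22466
            (0.0, 0.3, -0.8, 0.0),
        ],
    )
    def test_known_values(self, aff, d, k, expected):
        assert adjusted_fitness(aff, d, k) == pytest.approx(expected)

    def test_decreasing_in_concentration(self):
        assert adjusted_fitness(0.5, 0.9, -0.8) < adjusted_fitness(0.5, 0.1, -0.8)

    def test_preserves_ranking_at_equal_concentration(self, rng):
        affs = sorted(rng.random(5))
        adj = [adjusted_fitness(a, 0.4, -0.8) for a in affs]
        assert adj == sorted(adj)

    def test_nonnegative_k_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_fitness(0.5, 0.5, 0.1)


class TestCloneSelect:
    def test_rank_proportional_counts(self):
        # fitnesses descending 0.9,0.5,0.1,0.05: m = ceil(4/2) = 2 ranks kept;
        # rank 1 gets round(3/1)=3 clones, rank 2 round(3/2)=1.5 -> 2 (half-up)
        pop = [encode_gray(v) for v in (10, 20, 30, 40)]
        clones = clone_select(pop, [0.9, 0.5, 0.1, 0.05], mc=3)
        decoded = [decode_gray(c) for c in clones]
        assert decoded == [10] * 3 + [20] * 2

    def test_default_popsize_clone_group_size(self):
        # popsize 20, mc 10: ranks 1..10 get 10,5,3,3,2,2,1,1,1,1 clones
        pop = [encode_gray(v) for v in range(20)]
        fits = list(np.linspace(1.0, 0.05, 20))
        clones = clone_select(pop, fits, mc=10)
        assert len(clones) == 29
        assert [decode_gray(c) for c in clones[:10]] == [0] * 10

    def test_best_heads_group(self):
        pop = [encode_gray(v) for v in (1, 2, 3, 4)]
        clones = clone_select(pop, [0.0, 0.0, 1.0, 0.0], mc=3)
        assert decode_gray(clones[0]) == 3
        counts = {v: sum(decode_gray(c) == v for c in clones) for v in (1, 2, 3, 4)}
        assert counts[3] == max(counts.values())

    def test_ties_keep_original_order(self):
        pop = [encode_gray(v) for v in (5, 6, 7, 8)]
        clones = clone_select(pop, [0.5] * 4, mc=4)
        # stable sort: rank order is original order 5,6 (m=2 ranks)
        assert decode_gray(clones[0]) == 5

    def test_mc_exceeding_popsize_rejected(self):
        pop = [encode_gray(0), encode_gray(1)]
        with pytest.raises(ValidationError):
            clone_select(pop, [0.1, 0.2], mc=3)


class TestCrossoverMutate:
    def test_qc_zero_is_identity(self, rng):
        clones = [rng.integers(0, 2, 16, dtype=np.uint8) for _ in range(5)]
        out = crossover(clones, 0.0, np.random.default_rng(3))
        assert all(np.array_equal(a, b) for a, b in zip(clones, out))

    def test_qm_zero_is_identity(self, rng):
        group = [rng.integers(0, 2, 16, dtype=np.uint8) for _ in range(5)]
        out = mutate(group, 0.0, np.random.default_rng(3))
        assert all(np.array_equal(a, b) for a, b in zip(group, out))

    def test_qm_one_flips_exactly_one_bit(self, rng):
        group = [rng.integers(0, 2, 16, dtype=np.uint8) for _ in range(20)]
        out = mutate(group, 1.0, np.random.default_rng(3))
        assert all(hamming(a, b) == 1 for a, b in zip(group, out))

    def test_mutation_within_hamming_one_always(self, rng):
        group = [rng.integers(0, 2, 8, dtype=np.uint8) for _ in range(50)]
        out = mutate(group, 0.5, np.random.default_rng(4))
        assert all(hamming(a, b) <= 1 for a, b in zip(group, out))

    @pytest.mark.parametrize("op, prob", [(crossover, 1.0), (mutate, 0.3)])
    def test_seeded_operators_reproducible(self, op, prob, rng):
        group = [rng.integers(0, 2, 16, dtype=np.uint8) for _ in range(8)]
        out1 = op(group, prob, np.random.default_rng(9))
        out2 = op(group, prob, np.random.default_rng(9))
        assert all(np.array_equal(a, b) for a, b in zip(out1, out2))


class TestRunImmune:
    def test_finds_known_optimum_across_seeds(self):
        # objective rewards exactly the code 200; compare to exhaustive search
        target = max(range(256), key=lambda v: 1.0 if v == 200 else 0.0)
        hits = 0
        for seed in range(20):
            best, _ = run_immune(
                lambda ab: 1.0 if decode_gray(ab) == 200 else 0.0,
                L=8,
                params=ImmuneParams(seed=seed),
            )
            hits += decode_gray(best) == target
        assert hits >= 16  # large majority of seeded runs

    def test_constant_objective_stops_by_stall(self):
        _, trace = run_immune(
            lambda ab: 1.0, L=8, params=ImmuneParams(maxgen=200, stall_gens=20, seed=0)
        )
        assert len(trace) == 21  # stalls immediately after the window fills

    def test_memory_affinity_monotone(self):
        _, trace = run_immune(
            lambda ab: float(decode_gray(ab)), L=8, params=ImmuneParams(seed=3)
        )
        assert np.all(np.diff(trace.best_affinity) >= 0)

    def test_same_seed_identical_trace(self):
        runs = [
            run_immune(
                lambda ab: float(decode_gray(ab)), L=8, params=ImmuneParams(seed=12)
            )
            for _ in range(2)
        ]
        (b1, t1), (b2, t2) = runs
        assert np.array_equal(b1, b2)
        assert t1.best_affinity == t2.best_affinity
        assert t1.mean_concentration == t2.mean_concentration

    def test_non_finite_affinity_raises(self):
        with pytest.raises(ComputationError):
            run_immune(lambda ab: float("nan"), L=8, params=ImmuneParams(seed=0))

    def test_stall_stop_windows(self):
        stop = stall_stop(3)
        from immunoseg import ConvergenceTrace

        trace = ConvergenceTrace()
        for g, a in enumerate([1, 2, 2, 2]):
            trace.append(g, a, a, 0.5)
        assert not stop(trace)  # best changed within the window
        trace.append(4, 2, 2, 0.5)
        assert stop(trace)

    def test_trace_csv_roundtrip(self, tmp_path):
        _, trace = run_immune(
            lambda ab: float(decode_gray(ab)), L=8, params=ImmuneParams(seed=1)
        )
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "generation", "best_affinity", "best_objective", "mean_concentration",
        ]
        assert len(df) == len(trace)


class TestImmuneParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"popsize": 1},
            {"maxgen": 0},
            {"qc": 1.5},
            {"lambda_": 0.5},
            {"k": 0.1},
            {"mc": 25},
            {"stall_gens": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ImmuneParams(**kwargs)
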