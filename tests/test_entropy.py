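"""Entropy ratio: observed, null expectation, bootstrap, comparisons."""

import math
from collections import Counter
from itertools import combinations, product

import numpy as np
import pytest

import facscomplexity as fc
from facscomplexity.entropy import CombinationDistribution, _pattern_counts, randomize_rows
from facscomplexity.errors import DegenerateInputError, ValidationError

from conftest import make_matrix

AU4 = ["AU1", "AU2", "AU3", "AU4"]


class TestObservedEntropy:
    def test_single_configuration_has_zero_entropy(self):
        m = make_matrix([(1, 0, 1, 0)] * 100, "affiliative", AU4)
        assert fc.observed_entropy(m) == 0.0

    def test_hand_computed_three_configurations(self):
        # counts {A:2, B:1, C:1} -> -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        m = make_matrix(
            [(1, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0)],
            "affiliative",
            AU4,
        )
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert fc.observed_entropy(m) == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_uniform_configurations_reach_log_n(self):
        pats = [tuple(int(b) for b in f"{i:04b}") for i in range(1, 9)]
        m = make_matrix(pats * 5, "affiliative", AU4)
        assert fc.observed_entropy(m) == pytest.approx(math.log(8))

    def test_invariant_to_row_and_column_order(self, tiny_matrix):
        h = fc.observed_entropy(tiny_matrix)
        shuffled = tiny_matrix.df.sample(frac=1, random_state=0)
        cols = list(shuffled.columns)
        cols[4:] = cols[4:][::-1]
        m2 = fc.AUMatrix(shuffled[cols])
        assert fc.observed_entropy(m2) == pytest.approx(h)

    def test_neutral_rows_dropped_by_default(self):
        m = make_matrix([(1, 0, 0, 0), (0, 0, 0, 0)], "affiliative", AU4)
        assert fc.observed_entropy(m) == 0.0
        assert fc.observed_entropy(m, drop_neutral=False) == pytest.approx(math.log(2))

    def test_empty_subset_errors(self):
        m = make_matrix([(0, 0, 0, 0)], "affiliative", AU4)
        with pytest.raises(ValidationError):
            fc.observed_entropy(m)


class TestExpectedEntropy:
    def test_single_column_randomization_is_identity(self):
        m = make_matrix([(1,), (1,), (1,)], "affiliative", ["AU1"])
        assert fc.expected_entropy(m, n_rand=5, seed=0) == fc.observed_entropy(m)

    def test_fully_active_rows_are_permutation_invariant(self):
        m = make_matrix([(1, 1, 1, 1)] * 10, "affiliative", AU4)
        assert fc.expected_entropy(m, n_rand=5, seed=0) == 0.0

    def test_singleton_rows_approach_log2_with_two_columns(self):
        m = make_matrix([(1, 0)] * 200, "affiliative", ["AU1", "AU2"])
        # each randomized row is uniform over the two singleton configurations
        exp = fc.expected_entropy(m, n_rand=400, seed=1)
        assert exp == pytest.approx(math.log(2), abs=0.02)

    def test_row_sums_conserved_in_every_replicate(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, size=(40, 6)).astype(np.uint8)
        for _ in range(20):
            r = randomize_rows(vals, rng)
            assert (r.sum(axis=1) == vals.sum(axis=1)).all()
            assert r.sum() == vals.sum()

    def test_matches_exact_enumeration_on_small_matrix(self):
        """Monte-Carlo null mean equals the exact enumeration average."""
        pats = [(1, 0, 0, 0), (1, 1, 0, 0), (0, 1, 1, 1), (1, 0, 0, 0), (0, 0, 1, 0)]
        vals = np.array(pats, dtype=np.uint8)

        # oracle: average plug-in entropy over all per-row column choices
        choices = [
            list(combinations(range(4), int(k))) for k in vals.sum(axis=1)
        ]
        total, n_assign = 0.0, 0
        for assignment in product(*choices):
            counts = np.array(list(Counter(assignment).values()), dtype=float)
            p = counts / counts.sum()
            total += float(-(p * np.log(p)).sum())
            n_assign += 1
        exact = total / n_assign

        rng = np.random.default_rng(4)
        reps = np.array(
            [
                CombinationDistribution(_pattern_counts(randomize_rows(vals, rng))).entropy()
                for _ in range(20_000)
            ]
        )
        se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - exact) <= 3 * se

        m = make_matrix(pats, "affiliative", AU4)
        assert fc.expected_entropy(m, n_rand=5000, seed=5) == pytest.approx(
            exact, abs=4 * se * 2
        )


class TestEntropyRatio:
    def test_stereotyped_repertoire_has_ratio_zero(self):
        m = make_matrix([(1, 1, 0, 0)] * 50, "affiliative", AU4)
        res = fc.entropy_ratio(m, n_rand=20, seed=0)
        assert res.ratio == 0.0

    def test_random_use_has_ratio_near_one(self):
        rng = np.random.default_rng(6)
        pats = rng.integers(0, 2, size=(2000, 6))
        m = make_matrix([tuple(p) for p in pats], "affiliative", [f"AU{i}" for i in range(6)])
        res = fc.entropy_ratio(m, n_rand=30, seed=7)
        assert res.ratio == pytest.approx(1.0, abs=0.05)

    def test_degenerate_expected_entropy_errors(self):
        m = make_matrix([(1, 1, 1, 1)] * 5, "affiliative", AU4)
        with pytest.raises(DegenerateInputError):
            fc.entropy_ratio(m, n_rand=5, seed=0)

    def test_ratio_invariant_to_log_base(self):
        rng = np.random.default_rng(8)
        pats = rng.integers(0, 2, size=(200, 5))
        m = make_matrix([tuple(p) for p in pats], "affiliative", [f"AU{i}" for i in range(5)])
        nats = fc.entropy_ratio(m, n_rand=20, seed=9)
        obs2 = fc.observed_entropy(m, base=2)
        exp2 = fc.expected_entropy(m, n_rand=20, seed=9, base=2)
        assert obs2 / exp2 == pytest.approx(nats.ratio)

    def test_ratio_increases_with_repertoire_diversity(self):
        """More diverse, more evenly planted configurations -> higher ratio."""
        ratios = []
        for overlap in (0.0, 0.5, 1.0):
            cfg = fc.GeneratorConfig(
                activation_profiles=fc.overlap_profiles(overlap),
                context_row_counts=(800, 800, 800),
                seed=10,
            )
            m, _ = fc.simulate_matrix(cfg)
            sub = m.subset(contexts="affiliative")
            ratios.append(fc.entropy_ratio(sub, n_rand=20, seed=11).ratio)
        assert ratios[0] < ratios[1] < ratios[2]


class TestBootstrap:
    def test_stereotyped_bootstrap_is_all_zero(self):
        m = make_matrix([(1, 1, 0, 0)] * 30, "affiliative", AU4)
        res = fc.bootstrap_entropy_ratio(m, n_boot=10, n_rand=10, seed=0)
        s = res.bootstrap_summary
        assert s.min == s.max == s.mean == 0.0

    def test_summary_consistent_with_list(self, tiny_matrix):
        res = fc.bootstrap_entropy_ratio(tiny_matrix, n_boot=15, n_rand=10, seed=1)
        b = np.array(res.bootstrap)
        s = res.bootstrap_summary
        assert s.min <= s.mean <= s.max
        assert s.mean == pytest.approx(b.mean())
        assert len(b) == 15

    def test_deterministic_under_seed(self, tiny_matrix):
        a = fc.bootstrap_entropy_ratio(tiny_matrix, n_boot=5, n_rand=5, seed=2)
        b = fc.bootstrap_entropy_ratio(tiny_matrix, n_boot=5, n_rand=5, seed=2)
        assert a.bootstrap == b.bootstrap


class TestCompareDistributions:
    def _result(self, values):
        return fc.EntropyRatioResult(1, 1, 1, 1, bootstrap=list(values))

    def test_disjoint_ranges_are_meaningful(self):
        v = fc.compare_ratio_distributions(
            self._result([0.50, 0.53]), self._result([0.37, 0.39])
        )
        assert v.meaningful and v.direction == "first_higher"

    def test_touching_ranges_overlap(self):
        v = fc.compare_ratio_distributions(
            self._result([0.51, 0.51]), self._result([0.51, 0.52])
        )
        assert not v.meaningful

    def test_self_comparison_overlaps(self):
        r = self._result([0.4, 0.5])
        assert not fc.compare_ratio_distributions(r, r).meaningful

    def test_missing_bootstrap_errors(self):
        with pytest.raises(ValidationError):
            fc.compare_ratio_distributions(
                fc.EntropyRatioResult(1, 1, 1, 1), self._result([0.1])
            )
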