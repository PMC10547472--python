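"""Combination enumeration, specificity, summaries and the bipartite network."""

import numpy as np
import pandas as pd
import pytest

import facscomplexity as fc
from facscomplexity.errors import ValidationError

from conftest import make_matrix

AU3 = ["AUa", "AUb", "AUc"]


def brute_force_counts(matrix, max_size):
    """Oracle: double loop over rows and candidate combinations."""
    from itertools import combinations

    cols = matrix.au_columns
    out = {}
    for _, row in matrix.df.iterrows():
        active = [c for c in cols if row[c] == 1]
        for size in range(1, max_size + 1):
            for combo in combinations(sorted(active), size):
                key = (combo, row["context"])
                out[key] = out.get(key, 0) + 1
    return out


class TestEnumerateCombinations:
    def test_single_row_emits_all_nonempty_subsets(self):
        m = make_matrix([(1, 1, 0)], "aggressive", AU3)
        tab = fc.enumerate_combinations(m)
        got = {tuple(r.combination): r.count for r in tab.itertuples()}
        assert got == {("AUa",): 1, ("AUb",): 1, ("AUa", "AUb"): 1}

    def test_row_contributes_two_to_k_minus_one_combinations(self):
        m = make_matrix([(1, 1, 1)], "aggressive", AU3)
        tab = fc.enumerate_combinations(m)
        assert len(tab) == 2**3 - 1
        assert (tab["count"] == 1).all()

    def test_superset_rows_count_toward_subsets(self):
        m = make_matrix([(1, 0, 0), (1, 0, 0), (1, 1, 0)], "aggressive", AU3)
        tab = fc.enumerate_combinations(m).set_index("combination")
        assert tab.loc[[("AUa",)], "count"].iloc[0] == 3
        assert tab.loc[[("AUa", "AUb")], "count"].iloc[0] == 1

    def test_max_size_caps_emitted_combinations(self):
        m = make_matrix([(1, 1, 1)], "aggressive", AU3)
        tab = fc.enumerate_combinations(m, max_size=2)
        assert tab["size"].max() == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = 6
        pats = [tuple(rng.integers(0, 2, size=n_cols)) for _ in range(50)]
        ctxs = list(rng.choice(fc.CLEAR_CONTEXTS, size=50))
        m = make_matrix(pats, ctxs, [f"AU{i}" for i in range(n_cols)])
        tab = fc.enumerate_combinations(m, max_size=n_cols)
        got = {(tuple(r.combination), r.context): r.count for r in tab.itertuples()}
        assert got == brute_force_counts(m, n_cols)


class TestSpecificityTable:
    def _matrix(self, agg=3, aff=1, extra_balanced=True):
        pats = [(1, 0, 0)] * agg + [(1, 0, 0)] * aff
        ctxs = ["aggressive"] * agg + ["affiliative"] * aff
        # pad contexts so all three are present and balanced
        pats += [(0, 1, 0)] * 4 + [(0, 0, 1)] * 4
        ctxs += ["submissive"] * 4 + ["affiliative"] * 3 + ["aggressive"]
        return make_matrix(pats, ctxs, AU3)

    def test_exclusive_combination_has_specificity_one(self):
        m = make_matrix(
            [(1, 0, 0)] * 4 + [(0, 1, 0)] * 4 + [(0, 0, 1)] * 4,
            ["aggressive"] * 4 + ["affiliative"] * 4 + ["submissive"] * 4,
            AU3,
        )
        tab = fc.specificity_table(m, seed=0)
        row = tab.table[
            (tab.table["combination"] == ("AUa",))
            & (tab.table["context"] == "aggressive")
        ]
        assert row["specificity"].iloc[0] == 1.0

    def test_balanced_conditional_probability_is_exact(self):
        # 4 rows per context; AUa in 3 aggressive rows and 1 affiliative row
        pats = [(1, 0, 0)] * 3 + [(0, 1, 0)]
        ctxs = ["aggressive"] * 4
        pats += [(1, 0, 0)] + [(0, 1, 0)] * 3
        ctxs += ["affiliative"] * 4
        pats += [(0, 0, 1)] * 4
        ctxs += ["submissive"] * 4
        m = make_matrix(pats, ctxs, AU3)
        tab = fc.specificity_table(m, seed=0)
        t = tab.table.set_index(["combination", "context"])["specificity"]
        assert t[("AUa",), "aggressive"] == 0.75
        assert t[("AUa",), "affiliative"] == 0.25

    def test_specificity_sums_to_one_per_combination(self):
        m, _ = fc.simulate_matrix(
            fc.GeneratorConfig(context_row_counts=(300, 150, 60), seed=1)
        )
        tab = fc.specificity_table(m, seed=2)
        sums = tab.table.groupby("combination")["specificity"].sum()
        assert np.allclose(sums, 1.0)

    def test_absent_context_errors(self):
        m = make_matrix([(1, 0, 0)], "aggressive", AU3)
        with pytest.raises(ValidationError, match="affiliative"):
            fc.specificity_table(m)

    def test_rare_flag_uses_original_frequencies(self):
        # AUc occurs once among 200 aggressive rows -> frequency 0.5% < 1%
        pats = [(1, 0, 0)] * 199 + [(0, 0, 1)]
        ctxs = ["aggressive"] * 200
        pats += [(1, 0, 0)] * 10 + [(0, 1, 0)] * 10
        ctxs += ["affiliative"] * 10 + ["submissive"] * 10
        m = make_matrix(pats, ctxs, AU3)
        tab = fc.specificity_table(m, seed=3)
        t = tab.table
        def rare(combo, ctx):
            row = t[(t["combination"] == combo) & (t["context"] == ctx)]
            return bool(row["rare"].iloc[0])
        assert rare(("AUc",), "aggressive")
        assert not rare(("AUa",), "aggressive")

    def test_raising_threshold_never_increases_n(self):
        m, _ = fc.simulate_matrix(
            fc.GeneratorConfig(context_row_counts=(300, 150, 60), seed=4)
        )
        ns = []
        for thr in (0.01, 0.05, 0.20):
            tab = fc.specificity_table(m, threshold=thr, seed=5)
            ns.append(len(tab.for_context("affiliative")))
        assert ns[0] >= ns[1] >= ns[2]

    def test_deterministic_under_seed(self):
        m, _ = fc.simulate_matrix(
            fc.GeneratorConfig(context_row_counts=(120, 60, 30), seed=6)
        )
        a = fc.specificity_table(m, seed=7).table
        b = fc.specificity_table(m, seed=7).table
        pd.testing.assert_frame_equal(a, b)


class TestSummarize:
    def _table(self, specs, rare=None):
        n = len(specs)
        rare = rare or [False] * n
        df = pd.DataFrame(
            {
                "combination": [(f"AU{i}",) for i in range(n)],
                "size": 1,
                "context": "affiliative",
                "count_in_context": 1,
                "total_count": 1,
                "specificity": specs,
                "observed_frequency": 0.5,
                "rare": rare,
            }
        )
        return fc.SpecificityTable(df, fc.CLEAR_CONTEXTS, 0.01)

    def test_exclusive_combinations_all_high(self):
        s = fc.summarize_specificity(self._table([1.0, 1.0, 1.0]), "affiliative")
        assert s.mean == 1.0 and s.proportion_high == 1.0

    def test_bin_edges(self):
        s = fc.summarize_specificity(self._table([0.9, 0.5, 0.1]), "affiliative")
        assert (s.proportion_high, s.proportion_moderate, s.proportion_low) == (
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
        )
        assert s.proportion_high + s.proportion_moderate + s.proportion_low == 1.0

    def test_rare_combinations_excluded(self):
        s = fc.summarize_specificity(
            self._table([0.9, 0.5, 0.1], rare=[False, False, True]), "affiliative"
        )
        assert s.n == 2

    def test_empty_after_filter_errors(self):
        with pytest.raises(ValidationError):
            fc.summarize_specificity(self._table([0.9], rare=[True]), "affiliative")


class TestBipartiteNetwork:
    def test_degrees_and_mean_degree(self):
        # AUa used everywhere, AUb only affiliative, AUc rare everywhere
        rows = []
        for ctx in fc.CLEAR_CONTEXTS:
            rows.append(("AUa", ctx, 1 / 3, 0.5, False))
        rows.append(("AUb", "affiliative", 1.0, 0.5, False))
        for ctx in ("aggressive", "submissive"):
            rows.append(("AUb", ctx, 0.0, 0.0, True))
        for ctx in fc.CLEAR_CONTEXTS:
            rows.append(("AUc", ctx, 1 / 3, 0.001, True))
        df = pd.DataFrame(
            rows,
            columns=["au", "context", "specificity", "observed_frequency", "rare"],
        )
        df["combination"] = df["au"].map(lambda a: (a,))
        df["size"] = 1
        df["count_in_context"] = 1
        df["total_count"] = 3
        tab = fc.SpecificityTable(df, fc.CLEAR_CONTEXTS, 0.01)
        net = fc.bipartite_network(tab)
        assert net.degrees["AUa"] == 3
        assert net.degrees["AUb"] == 1
        assert net.degrees["AUc"] == 0  # isolated but present
        assert net.mean_degree == pytest.approx(4 / 3)
        assert net.graph["AUb"]["affiliative"]["weight"] == 1.0

    def test_node_link_export_round_trips(self):
        m, _ = fc.simulate_matrix(
            fc.GeneratorConfig(context_row_counts=(100, 100, 100), seed=8)
        )
        net = fc.bipartite_network(fc.specificity_table(m, seed=9))
        d = net.to_json_dict()
        assert d["schema_version"] == 1
        assert {n["id"] for n in d["nodes"]} >= set(fc.CLEAR_CONTEXTS)
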