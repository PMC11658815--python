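import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lpdsub.data_io import CountMatrix
from lpdsub.de import (
    bh_adjust,
    core_overlap,
    filter_de,
    hypergeom_enrichment,
    nb_wald_de,
    pairwise_de,
    read_gmt,
    run_support_filter,
    size_factors_median_ratios,
)
from lpdsub.experiments import _flat_counts
from oracles import bh_bruteforce, hypergeom_tail


def counts_from(vals, n_genes=None):
    vals = np.asarray(vals)
    return CountMatrix(
        vals, [f"g{i}" for i in range(vals.shape[0])],
        [f"s{i}" for i in range(vals.shape[1])],
    )


class TestSizeFactors:
    def test_doubled_sample_splits_geometrically(self, rng):
        base = rng.integers(10, 500, size=(50, 1))
        cm = counts_from(np.hstack([base, 2 * base]))
        sf = size_factors_median_ratios(cm)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_samples_give_unit_factors(self, rng):
        base = rng.integers(1, 300, size=(40, 1))
        cm = counts_from(np.tile(base, (1, 5)))
        np.testing.assert_allclose(size_factors_median_ratios(cm), 1.0)

    def test_matches_bruteforce_recomputation(self, rng):
        vals = rng.integers(1, 1000, size=(60, 8))
        cm = counts_from(vals)
        sf = size_factors_median_ratios(cm)
        # brute force: per-gene geometric means, then per-sample median ratio
        expected = []
        geo = np.array([np.prod(row ** (1 / len(row))) for row in vals.astype(float)])
        for d in range(8):
            expected.append(np.median(vals[:, d] / geo))
        np.testing.assert_allclose(sf, expected, rtol=1e-8)

    def test_no_common_nonzero_gene_rejected(self):
        cm = counts_from(np.array([[0, 5], [5, 0]]))
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_ratios(cm)


class TestBH:
    def test_forced_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_bruteforce(pvals), atol=1e-12)

    def test_nan_passthrough_excluded_from_denominator(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_bruteforce([0.01, 0.02]))


class TestNBWald:
    def test_label_swap_negates_log2fc(self):
        counts, cond = _flat_counts(50, 10, 100.0, 0.1, seed=4, lfc_genes=10)
        res_ab = nb_wald_de(counts, cond)
        swapped = np.where(cond == "A", "Z", "A")  # reverses the level order
        res_ba = nb_wald_de(counts, swapped)
        np.testing.assert_allclose(res_ab["log2fc"], -res_ba["log2fc"], atol=1e-6)
        np.testing.assert_allclose(res_ab["p"], res_ba["p"], atol=1e-8)

    def test_planted_fold_change_estimated(self):
        # a small planted fraction keeps the median-of-ratios reference clean
        counts, cond = _flat_counts(300, 20, 100.0, 0.1, seed=5, lfc_genes=10)
        res = nb_wald_de(counts, cond)
        planted = res.iloc[:10]
        assert planted["log2fc"].mean() == pytest.approx(2.0, abs=0.15)
        assert (planted["padj"] < 0.01).mean() >= 0.9

    def test_null_roughly_calibrated_small(self):
        counts, cond = _flat_counts(400, 20, 100.0, 0.1, seed=6)
        res = nb_wald_de(counts, cond)
        rate = (res["p"] < 0.05).mean()
        assert 0.01 < rate < 0.10

    def test_all_zero_gene_gets_na(self):
        vals = np.vstack([np.zeros(8, dtype=int), np.full(8, 50)])
        counts = counts_from(vals)
        res = nb_wald_de(counts, np.repeat(["A", "B"], 4), np.ones(8))
        assert np.isnan(res.loc[0, "p"])
        assert not np.isnan(res.loc[1, "p"])

    def test_requires_two_groups_of_two(self):
        counts = counts_from(np.full((3, 3), 10))
        with pytest.raises(ValueError):
            nb_wald_de(counts, np.array(["A", "A", "B"]))


class TestFilters:
    def test_exact_threshold_excluded_by_strict_inequality(self):
        df = pd.DataFrame({
            "transcript": ["a", "b"],
            "log2fc": [1.5, 1.51],
            "padj": [0.001, 0.001],
        })
        out = filter_de(df)
        assert out["transcript"].tolist() == ["b"]

    def test_direction_and_manual_enumeration(self):
        df = pd.DataFrame({
            "transcript": list("abcdef"),
            "log2fc": [-2.0, 2.0, 1.0, -1.6, 3.0, -4.0],
            "padj": [0.005, 0.02, 0.001, 0.009, 0.0001, np.nan],
        })
        out = filter_de(df)
        assert set(out["transcript"]) == {"a", "d", "e"}

    def test_run_support_boundary(self):
        n_runs = 94
        sets = [{("keep", "up")} for _ in range(80)]
        sets += [set() for _ in range(14)]
        for s in sets[:75]:
            s.add(("drop", "up"))
        out = run_support_filter(sets, 0.8)
        assert out["transcript"].tolist() == ["keep"]
        assert out["run_support"].iloc[0] == pytest.approx(80 / 94)

    def test_opposite_directions_do_not_pool(self):
        sets = [{("g", "up")}] * 5 + [{("g", "down")}] * 5
        assert len(run_support_filter(sets, 0.8)) == 0

    def test_present_in_all_runs_kept(self):
        assert run_support_filter([{("g", "up")}] * 3, 1.0)["transcript"].tolist() == ["g"]

    def test_support_filter_shrinks_with_threshold(self, rng):
        sets = [
            {(f"g{i}", "up") for i in rng.choice(30, 15, replace=False)}
            for _ in range(10)
        ]
        sizes = [len(run_support_filter(sets, f)) for f in (0.5, 0.7, 0.9)]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestCoreOverlap:
    def test_worked_example(self):
        core, table = core_overlap({
            "w": {"A", "B", "C"}, "x": {"B", "C"},
            "y": {"B", "C", "D"}, "z": {"B", "C"},
        })
        assert core == {"B", "C"}
        assert len(table) == 4

    def test_disjoint_sets_empty(self):
        core, _ = core_overlap({"a": {"x"}, "b": {"y"}})
        assert core == set()

    def test_matches_bruteforce_enumeration(self, rng):
        sets = {
            f"d{i}": set(rng.choice(20, rng.integers(3, 12), replace=False).tolist())
            for i in range(4)
        }
        core, table = core_overlap(sets)
        brute = {x for x in range(20) if all(x in s for s in sets.values())}
        assert core == brute
        in_all = table[[c for c in table.columns if c != "item"]].all(axis=1)
        assert set(table.loc[in_all, "item"]) == brute


class TestHypergeom:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        res = hypergeom_enrichment(term, universe, {"t": term})
        assert res["p"].iloc[0] == pytest.approx(1 / 15504)

    def test_no_overlap_near_one(self):
        universe = {f"g{i}" for i in range(50)}
        res = hypergeom_enrichment(
            {f"g{i}" for i in range(5)}, universe, {"t": {f"g{i}" for i in range(45, 50)}})
        assert res["p"].iloc[0] > 0.4

    def test_matches_tail_summation_oracle(self, rng):
        universe = {f"g{i}" for i in range(30)}
        query = set(rng.choice(sorted(universe), 8, replace=False).tolist())
        annotation = {
            f"t{j}": set(rng.choice(sorted(universe), 10, replace=False).tolist())
            for j in range(5)
        }
        res = hypergeom_enrichment(query, universe, annotation).set_index("term")
        for term, genes in annotation.items():
            k = len(query & genes)
            expected = hypergeom_tail(k, 30, len(genes), 8)
            assert res.loc[term, "p"] == pytest.approx(expected, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"a"}, set(), {})


class TestGMT:
    def test_reads_both_formats(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("term1\tdesc\tg1\tg2\nterm2\tdesc\tg3\n")
        two_col = tmp_path / "map.tsv"
        two_col.write_text("g1\ttermA\ng2\ttermA\ng3\ttermB\n")
        assert read_gmt(gmt) == {"term1": {"g1", "g2"}, "term2": {"g3"}}
        assert read_gmt(two_col) == {"termA": {"g1", "g2"}, "termB": {"g3"}}


class TestPairwiseDE:
    def test_calls_are_symmetric_across_processes(self):
        counts, cond = _flat_counts(80, 10, 100.0, 0.1, seed=9, lfc_genes=15)
        labels = np.where(cond == "A", 0, 1)
        calls = pairwise_de(counts_from(counts.values), labels)
        ups_in_1 = {t for t, d in calls[1] if d == "up"}
        downs_in_0 = {t for t, d in calls[0] if d == "down"}
        assert ups_in_1 == downs_in_0
        assert len(ups_in_1) > 0
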