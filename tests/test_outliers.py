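import logging

import numpy as np
import pandas as pd
import pytest

from divergesim import outliers
from divergesim.fixtures import make_block_overlap_sets, make_spikein_pools


class TestQuantileOutliers:
    def test_two_thousand_distinct_values_give_one_hundred(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.permutation(2000).astype(float))
        assert len(outliers.quantile_outliers(vals)) == 100

    def test_one_to_twenty(self):
        vals = pd.Series(np.arange(1.0, 21.0), index=np.arange(1, 21))
        assert outliers.quantile_outliers(vals, q=0.95) == {20}

    def test_all_equal_values_give_empty_set(self):
        assert outliers.quantile_outliers(pd.Series([5.0] * 100)) == set()

    def test_missing_values_excluded(self):
        vals = pd.Series([np.nan] * 50 + list(range(100)))
        out = outliers.quantile_outliers(vals, q=0.9)
        assert len(out) == 10
        with pytest.raises(ValueError):
            outliers.quantile_outliers(pd.Series([np.nan, np.nan]))

    def test_set_never_exceeds_five_percent(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.integers(0, 10, 500).astype(float))  # heavy ties
        assert len(outliers.quantile_outliers(vals)) <= 25


class TestSpikeIn:
    def test_perfect_separation(self):
        # 20 iterations so the spike (one record per region) is exactly the
        # upper 5% of the pool, the production shape
        neutral, phenodiv = make_spikein_pools(
            n_regions=50, n_iterations=20, shift=50.0, seed=0
        )
        res = outliers.spike_in_permutation(neutral, phenodiv, n_perm=20, seed=1)
        s = res.summary.set_index("measures")
        for m in ("fst", "dxy", "delta_pi", "fst&dxy&delta_pi"):
            assert s.loc[m, "fpr"] == 0.0
            assert s.loc[m, "fnr"] == 0.0
        assert s.loc["fst&dxy&delta_pi", "outlier_n"] == 50.0

    def test_single_measure_fpr_equals_fnr(self):
        neutral, phenodiv = make_spikein_pools(
            n_regions=50, n_iterations=20, shift=1.0, seed=2
        )
        res = outliers.spike_in_permutation(neutral, phenodiv, n_perm=30, seed=3)
        s = res.summary.set_index("measures")
        for m in ("fst", "dxy", "delta_pi"):
            assert s.loc[m, "outlier_n"] == 50.0
            assert s.loc[m, "fpr"] == s.loc[m, "fnr"]

    def test_combined_fnr_at_least_single_fnr(self):
        neutral, phenodiv = make_spikein_pools(
            n_regions=50, n_iterations=20, shift=1.5, seed=4, measure_corr=0.3
        )
        res = outliers.spike_in_permutation(neutral, phenodiv, n_perm=30, seed=5)
        s = res.summary.set_index("measures")
        for combo in ("fst&dxy", "fst&delta_pi", "dxy&delta_pi"):
            parts = combo.split("&")
            assert s.loc[combo, "fnr"] >= max(s.loc[p, "fnr"] for p in parts) - 1e-12
            assert s.loc[combo, "outlier_n"] <= min(
                s.loc[p, "outlier_n"] for p in parts
            )

    def test_pool_validation(self):
        neutral, phenodiv = make_spikein_pools(n_regions=20, n_iterations=5)
        with pytest.raises(ValueError, match="cover every region"):
            outliers.spike_in_permutation(
                neutral, phenodiv[phenodiv.region_id > 3], n_perm=2
            )
        with pytest.raises(ValueError, match="lacks columns"):
            outliers.spike_in_permutation(
                neutral.drop(columns=["fst"]), phenodiv, n_perm=2
            )


class TestOverlap:
    def test_identical_and_disjoint_sets(self):
        sets = {
            "A": [{1, 2, 3}] * 4,
            "B": [{1, 2, 3}] * 4,
            "C": [{7, 8, 9}] * 4,
        }
        mat = outliers.overlap_matrix(sets)
        assert mat.loc["A", "B"] == pytest.approx(1.0)
        assert mat.loc["A", "C"] == 0.0
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat.values, mat.values.T)

    def test_independent_draws_overlap_near_five_percent(self):
        """Two independent 100-of-2000 region draws share ~5 regions
        (hypergeometric expectation), i.e. proportional overlap ~0.05."""
        rng = np.random.default_rng(6)
        sets = {
            t: [set(rng.choice(2000, 100, replace=False).tolist())
                for _ in range(200)]
            for t in ("A", "B")
        }
        mat = outliers.overlap_matrix(sets)
        assert mat.loc["A", "B"] == pytest.approx(0.05, abs=0.01)

    def test_jaccard_denominator(self):
        sets = {"A": [{1, 2, 3, 4}], "B": [{3, 4, 5, 6}]}
        mean_based = outliers.overlap_matrix(sets).loc["A", "B"]
        jac = outliers.overlap_matrix(sets, denominator="jaccard").loc["A", "B"]
        assert mean_based == pytest.approx(0.5)
        assert jac == pytest.approx(2 / 6)

    def test_empty_sets_give_missing_entry(self):
        sets = {"A": [set(), set()], "B": [set(), set()]}
        mat = outliers.overlap_matrix(sets)
        assert np.isnan(mat.loc["A", "B"])


class TestClusterOrder:
    def test_block_structure_keeps_blocks_contiguous(self):
        labels = ["a1", "b1", "a2", "b2", "a3", "b3"]
        n = len(labels)
        m = np.full((n, n), 0.1)
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if li[0] == lj[0]:
                    m[i, j] = 0.9
        np.fill_diagonal(m, 1.0)
        mat = pd.DataFrame(m, index=labels, columns=labels)
        order, _ = outliers.cluster_order(mat)
        groups = [lab[0] for lab in order]
        # each block's members are adjacent in the leaf ordering
        assert "".join(groups) in ("aaabbb", "bbbaaa")

    def test_tied_matrix_preserves_input_order(self):
        labels = list("wxyz")
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        mat = pd.DataFrame(m, index=labels, columns=labels)
        order, _ = outliers.cluster_order(mat)
        assert order == labels

    def test_row_permutation_gives_same_partition(self):
        rng = np.random.default_rng(3)
        base = rng.random((6, 6)) * 0.5
        base = (base + base.T) / 2
        base[:3, :3] += 0.4
        base[3:, 3:] += 0.4
        np.fill_diagonal(base, 1.0)
        labels = [f"t{i}" for i in range(6)]
        mat = pd.DataFrame(base, index=labels, columns=labels)
        order1, _ = outliers.cluster_order(mat)
        perm = rng.permutation(6)
        mat2 = mat.iloc[perm, perm]
        order2, _ = outliers.cluster_order(mat2)
        blocks1 = {frozenset(order1[:3]), frozenset(order1[3:])}
        blocks2 = {frozenset(order2[:3]), frozenset(order2[3:])}
        assert blocks1 == blocks2

    def test_missing_entries_imputed_with_warning(self, caplog):
        labels = list("pqr")
        m = np.array([[1.0, 0.5, np.nan], [0.5, 1.0, 0.2], [np.nan, 0.2, 1.0]])
        mat = pd.DataFrame(m, index=labels, columns=labels)
        with caplog.at_level(logging.WARNING, logger="divergesim"):
            order, _ = outliers.cluster_order(mat)
        assert "imputing" in caplog.text
        assert sorted(order) == labels


def test_quantile_cutoffs_by_regime(micro_table):
    cuts = outliers.quantile_cutoffs(micro_table)
    assert set(cuts.columns) >= {"treatment", "generation", "regime",
                                 "fst", "dxy", "delta_pi"}
    n_groups = micro_table.groupby(
        ["treatment", "generation", "regime"]
    ).ngroups
    assert len(cuts) == n_groups
    # cut-offs are above the pooled medians
    one = micro_table[(micro_table.treatment == cuts.treatment.iloc[0])
                      & (micro_table.generation == cuts.generation.iloc[0])
                      & (micro_table.regime == cuts.regime.iloc[0])]
    assert cuts.fst.iloc[0] >= one.fst.median()
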