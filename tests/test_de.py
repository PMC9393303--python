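"""Median-of-ratios normalization, two-group DE with fold-change/FDR gates,
Benjamini-Hochberg against a brute-force step-up, and one-way ANOVA with
Bonferroni pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ferroscore.de import (anova_bonferroni, bh_adjust, differential_expression,
                           normalize_counts, size_factors)
from ferroscore.io import ExpressionMatrix
from ferroscore.simulate import CountSimConfig, PlantedDE, simulate_counts


def _counts(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            layer="counts")


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        m = _counts([[10, 20], [20, 40], [30, 60]])
        f = size_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [2 ** -0.5, 2 ** 0.5], atol=1e-12)

    def test_identical_samples_unit_factors(self):
        m = _counts([[5, 5, 5], [9, 9, 9]])
        np.testing.assert_allclose(size_factors(m).to_numpy(), [1, 1, 1])

    def test_scaling_one_sample_scales_its_relative_factor(self, rng):
        # the gene geometric means absorb c^(1/n), so equivariance holds
        # for factor ratios: f_j / f_i picks up exactly c
        arr = rng.poisson(50.0, (100, 4)) + 1.0
        f1 = size_factors(_counts(arr))
        arr2 = arr.copy()
        arr2[:, 2] *= 3.0
        f2 = size_factors(_counts(arr2))
        ratio = (f2.iloc[2] / f2.iloc[0]) / (f1.iloc[2] / f1.iloc[0])
        assert ratio == pytest.approx(3.0, rel=1e-9)

    def test_rescaled_factors_have_unit_geomean(self, rng):
        arr = rng.poisson(30.0, (50, 5)) + 1.0
        f = size_factors(_counts(arr), rescale_geomean=True)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rows_rejected(self):
        m = _counts([[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(m)


def brute_force_bh(p):
    """Independent step-up implementation with explicit monotonicity pass."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            worst = max(worst, np.abs(bh_adjust(p) - brute_force_bh(p)).max())
        assert worst <= 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_rank_preserving_and_bounded(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1.0).all()
        order_p = np.argsort(np.asarray(p), kind="stable")
        assert (np.diff(adj[order_p]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialExpression:
    @staticmethod
    def _simulated(seed, n_de=100, log2fc=2.0):
        base = CountSimConfig(n_genes=2000, n_samples=40, seed=seed,
                              factors={"group": ("a",) * 20 + ("b",) * 20})
        de_genes = tuple(base.gene_ids[:n_de]) if n_de else ()
        planted = (PlantedDE(genes=de_genes, log2fc=log2fc, group="a"),) if n_de else ()
        cfg = CountSimConfig(n_genes=2000, n_samples=40, seed=seed,
                             factors={"group": ("a",) * 20 + ("b",) * 20},
                             de=planted)
        m, truth = simulate_counts(cfg)
        labels = pd.Series(cfg.factors["group"], index=m.sample_ids)
        return m, labels, set(de_genes)

    def test_planted_genes_recovered_with_fdr_control(self):
        sens, fdr = [], []
        for seed in range(20):
            m, labels, true_genes = self._simulated(seed)
            result = differential_expression(m, labels)
            sig = set(result.significant_genes)
            tp = len(sig & true_genes)
            sens.append(tp / len(true_genes))
            fdr.append((len(sig) - tp) / max(len(sig), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdr) <= 0.1

    def test_null_replicates_nearly_no_calls(self):
        n_reps_with_calls = 0
        for seed in range(20):
            m, labels, _ = self._simulated(100 + seed, n_de=0)
            result = differential_expression(m, labels)
            n_reps_with_calls += len(result.significant_genes) > 0
        assert n_reps_with_calls <= 1  # >=95% of null replicates clean

    def test_null_bh_fraction_controlled(self):
        fracs = []
        for seed in range(5):
            m, labels, _ = self._simulated(200 + seed, n_de=0)
            result = differential_expression(m, labels)
            fracs.append(float((result.table["padj"] < 0.05).mean()))
        assert max(fracs) <= 0.07

    def test_fold_change_gate_blocks_small_effects(self):
        # planted log2FC = 0.5: strongly significant p but below the gate
        m, labels, true_genes = self._simulated(7, n_de=50, log2fc=0.5)
        result = differential_expression(m, labels)
        sub = result.table.loc[sorted(true_genes)]
        assert not sub["significant"].any()
        assert (sub["padj"] < 0.05).any()  # detected, only gated by fold change

    def test_small_group_rejected(self):
        m = _counts(np.ones((5, 5)) * 10)
        labels = pd.Series(["a", "a", "b", "b", "b"], index=m.sample_ids)
        with pytest.raises(ValueError, match="3 samples"):
            differential_expression(m, labels)

    def test_adjusted_p_not_below_raw(self, rng):
        arr = rng.poisson(40.0, (300, 12)) + 1.0
        m = _counts(arr)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.sample_ids)
        t = differential_expression(m, labels).table
        assert (t["padj"] >= t["pval"] - 1e-15).all()


class TestAnovaBonferroni:
    def test_closed_form_f_statistic(self):
        values = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, p, pairs = anova_bonferroni(values, groups)
        assert f == pytest.approx(3.0)
        assert len(pairs) == 3

    def test_identical_groups_f_zero(self):
        f, p, _ = anova_bonferroni([1, 2, 3] * 3, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pairwise_bonferroni_multiplies_by_pair_count(self, rng):
        values = np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(3, 1, 10)]
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        _, _, pairs = anova_bonferroni(values, groups)
        for row in pairs.itertuples():
            assert row.p_bonferroni == pytest.approx(min(row.pval * 3, 1.0))

    def test_degenerate_all_identical_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_bonferroni([2, 2, 2, 2, 2, 2], ["a", "a", "b", "b", "c", "c"])


def test_normalized_counts_equalize_doubled_library(rng):
    arr = rng.poisson(50.0, (200, 2)) + 1.0
    arr[:, 1] = arr[:, 0] * 2
    m = _counts(arr)
    normed = normalize_counts(m)
    np.testing.assert_allclose(normed.values.iloc[:, 0].to_numpy(),
                               normed.values.iloc[:, 1].to_numpy(), rtol=1e-9)
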