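"""Enrichment engine: ssGSEA against a brute-force transcription of the
rank-weighted ECDF-difference formula, pre-ranked GSEA against hand-derived
running sums and a calibrated permutation null, and the hypergeometric
over-representation test against closed forms and simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ferroscore.enrichment import hypergeom_ora, preranked_gsea, ssgsea, SSGSEAScorer
from ferroscore.io import ExpressionMatrix, GeneSet, GeneSetCollection


def brute_force_es(column: pd.Series, members: frozenset, tau: float = 0.25) -> float:
    """Independent plain-loop transcription of the single-sample score."""
    genes = list(column.index)
    ranks = rankdata(column.to_numpy(), method="average")
    order = sorted(range(len(genes)), key=lambda i: (-ranks[i], i))
    in_set = [genes[i] in members for i in order]
    denom = sum(ranks[order[i]] ** tau for i in range(len(order)) if in_set[i])
    n_out = len(genes) - sum(in_set)
    p_in = p_out = total = 0.0
    for i, idx in enumerate(order):
        if in_set[i]:
            p_in += ranks[idx] ** tau / denom
        else:
            p_out += 1.0 / n_out
        total += p_in - p_out
    return total


def _random_instance(rng, n_genes, n_samples, set_size):
    genes = [f"g{i}" for i in range(n_genes)]
    vals = pd.DataFrame(rng.lognormal(0, 1, (n_genes, n_samples)),
                        index=genes, columns=[f"s{j}" for j in range(n_samples)])
    members = frozenset(rng.choice(genes, set_size, replace=False))
    return ExpressionMatrix(vals, layer="normalized"), members


class TestSsgsea:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            n_genes = int(rng.integers(10, 51))
            n_samples = int(rng.integers(2, 11))
            set_size = int(rng.integers(2, min(10, n_genes - 1) + 1))
            matrix, members = _random_instance(rng, n_genes, n_samples, set_size)
            es = ssgsea(matrix, [GeneSet("S", members)], normalize=False)
            for sample in matrix.sample_ids:
                expected = brute_force_es(matrix.values[sample], members)
                worst = max(worst, abs(es.scores.loc["S", sample] - expected))
        assert worst <= 1e-10

    def test_identical_samples_identical_scores(self, rng):
        col = rng.lognormal(0, 1, 20)
        vals = pd.DataFrame({"a": col, "b": col}, index=[f"g{i}" for i in range(20)])
        es = ssgsea(ExpressionMatrix(vals, layer="normalized"),
                    [GeneSet("S", frozenset(["g1", "g5", "g9"]))], normalize=False)
        assert es.scores["a"].iloc[0] == es.scores["b"].iloc[0]

    def test_monotone_transform_invariance(self, rng):
        matrix, members = _random_instance(rng, 30, 4, 5)
        squared = ExpressionMatrix(matrix.values ** 2, layer="normalized")
        s1 = ssgsea(matrix, [GeneSet("S", members)], normalize=False)
        s2 = ssgsea(squared, [GeneSet("S", members)], normalize=False)
        np.testing.assert_allclose(s1.scores.to_numpy(), s2.scores.to_numpy(),
                                   atol=1e-12)

    def test_range_normalization_preserves_ordering(self, rng):
        matrix, _ = _random_instance(rng, 40, 6, 5)
        sets = [GeneSet("A", frozenset([f"g{i}" for i in range(0, 8)])),
                GeneSet("B", frozenset([f"g{i}" for i in range(10, 15)]))]
        raw = ssgsea(matrix, sets, normalize=False).scores.to_numpy().ravel()
        normed = ssgsea(matrix, sets, normalize=True).scores.to_numpy().ravel()
        assert np.array_equal(np.argsort(raw), np.argsort(normed))

    def test_constant_sample_is_error(self):
        vals = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]},
                            index=["x", "y", "z"])
        with pytest.raises(ValueError, match="constant"):
            ssgsea(ExpressionMatrix(vals, layer="normalized"),
                   [GeneSet("S", frozenset(["x", "y"]))])

    def test_small_set_skipped_with_warning(self, small_matrix, caplog):
        sets = [GeneSet("TOOSMALL", frozenset(["g1", "nope"])),
                GeneSet("OK", frozenset(["g1", "g2", "g3"]))]
        with caplog.at_level("WARNING"):
            es = ssgsea(small_matrix, sets)
        assert es.set_names == ["OK"]

    def test_sklearn_transformer_matches_function(self, small_matrix):
        sets = GeneSetCollection([GeneSet("S", frozenset(["g1", "g2", "g4"]))])
        scorer = SSGSEAScorer(sets=sets, normalize=False)
        out = scorer.fit_transform(small_matrix.values.T)
        direct = ssgsea(small_matrix, sets, normalize=False)
        np.testing.assert_allclose(out.to_numpy(), direct.scores.T.to_numpy())
        assert scorer.get_params()["normalize"] is False


class TestPrerankedGsea:
    def test_hand_derived_top_set_es(self):
        ranking = pd.Series({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        res = preranked_gsea(ranking, [GeneSet("TOP", frozenset(["g1", "g2"]))],
                             n_perm=100, seed=0)
        # hits exhaust their weight before any miss: running sum peaks at 1
        assert res.loc["TOP", "es"] == pytest.approx(1.0)
        assert res.loc["TOP", "nes"] > 0

    def test_complement_set_negative_es(self):
        ranking = pd.Series({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        res = preranked_gsea(ranking, [GeneSet("BOT", frozenset(["g3", "g4", "g5"]))],
                             n_perm=100, seed=0)
        assert res.loc["BOT", "es"] < 0
        assert np.sign(res.loc["BOT", "nes"]) == np.sign(res.loc["BOT", "es"])

    def test_deterministic_under_seed(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ranking = pd.Series(rng.normal(0, 1, 60), index=genes)
        sets = [GeneSet("S", frozenset(genes[5:15]))]
        r1 = preranked_gsea(ranking, sets, n_perm=200, seed=42)
        r2 = preranked_gsea(ranking, sets, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_sets_calibrated_type_i_error(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(200)]
        ranking = pd.Series(rng.normal(0, 1, 200), index=genes)
        sets = [GeneSet(f"N{i}", frozenset(rng.choice(genes, 15, replace=False)))
                for i in range(500)]
        res = preranked_gsea(ranking, sets, n_perm=1000, seed=7)
        rate = float((res["pval"] < 0.05).mean())
        assert abs(rate - 0.05) <= 0.02

    def test_pvalues_in_unit_interval(self, rng):
        genes = [f"g{i}" for i in range(50)]
        ranking = pd.Series(rng.normal(0, 1, 50), index=genes)
        sets = [GeneSet(f"S{i}", frozenset(rng.choice(genes, 8, replace=False)))
                for i in range(10)]
        res = preranked_gsea(ranking, sets, n_perm=100, seed=1)
        assert ((res["pval"] > 0) & (res["pval"] <= 1)).all()

    def test_unmapped_set_skipped(self, rng):
        ranking = pd.Series({"a": 1.0, "b": 0.5, "c": -1.0})
        with pytest.raises(ValueError, match="no gene set"):
            preranked_gsea(ranking, [GeneSet("X", frozenset(["zz"]))], n_perm=100)


class TestHypergeomOra:
    def test_full_overlap_closed_form(self):
        universe = {f"u{i}" for i in range(20)}
        annotation = {f"u{i}" for i in range(5)}
        overlap, p = hypergeom_ora(annotation, frozenset(annotation), universe)
        assert overlap == 5
        assert p == pytest.approx(1.0 / 15504.0, abs=1e-12)

    def test_empty_selection_p_one(self):
        universe = {f"u{i}" for i in range(10)}
        overlap, p = hypergeom_ora(set(), frozenset({"u1", "u2"}), universe)
        assert (overlap, p) == (0, 1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_ora({"x"}, frozenset({"a"}), {"a", "b"})

    def test_tail_probability_matches_simulation(self):
        rng = np.random.default_rng(8)
        universe = [f"u{i}" for i in range(30)]
        annotation = frozenset(universe[:8])
        selected = set(universe[5:15])  # overlap 3
        overlap, p = hypergeom_ora(selected, annotation, set(universe))
        draws = 100_000
        hits = 0
        for _ in range(draws):
            pick = rng.choice(30, size=len(selected), replace=False)
            hits += sum(1 for i in pick if i < 8) >= overlap
        assert abs(hits / draws - p) < 0.01
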