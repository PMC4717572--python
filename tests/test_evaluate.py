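"""Ranking evaluation: mid-rank AUC vs a pair-counting oracle, bootstrap
confidence intervals, permutation bands, and p-value inflation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netwas.evaluate import (
    GoldStandard,
    bootstrap_ci,
    compare_methods,
    permutation_band,
    qq_inflation,
    ranking_from_pvalues,
    roc_auc,
)


def brute_force_auc(scores: dict[str, float], positives: set[str]) -> float:
    """Exhaustive pair counting: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for g, s in scores.items() if g in positives]
    neg = [s for g, s in scores.items() if g not in positives]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def gold(positives, universe):
    return GoldStandard("test", set(positives), set(universe))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.0})
        assert roc_auc(scores, gold({"a", "b"}, scores.index)) == 1.0

    def test_all_tied_is_half(self):
        scores = pd.Series(1.0, index=list("abcdef"))
        assert roc_auc(scores, gold({"a", "b"}, scores.index)) == 0.5

    def test_six_gene_toy_matches_pair_counting(self):
        scores = {"g0": 5.0, "g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0, "g5": 0.0}
        positives = {"g0", "g2", "g5"}
        expected = brute_force_auc(scores, positives)
        assert roc_auc(pd.Series(scores), gold(positives, scores)) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.integers(0, 4), min_size=2, max_size=12),
        labels=st.data(),
    )
    def test_matches_brute_force_with_ties(self, scores, labels):
        n = len(scores)
        lab = labels.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda v: any(v) and not all(v)
            )
        )
        genes = [f"g{i}" for i in range(n)]
        series = pd.Series(dict(zip(genes, map(float, scores))))
        positives = {g for g, is_pos in zip(genes, lab) if is_pos}
        assert roc_auc(series, gold(positives, genes)) == pytest.approx(
            brute_force_auc(dict(series), positives)
        )

    def test_reversal_identity_without_ties(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        scores = pd.Series(rng.permutation(30).astype(float), index=genes)
        g = gold(set(genes[:7]), genes)
        assert roc_auc(scores, g) == pytest.approx(1.0 - roc_auc(-scores, g))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        scores = pd.Series(rng.standard_normal(40), index=genes)
        g = gold(set(genes[:10]), genes)
        assert roc_auc(np.exp(scores), g) == pytest.approx(roc_auc(scores, g))

    def test_empty_class_is_error(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="positives"):
            roc_auc(scores, gold(set(), {"a", "b"}))
        with pytest.raises(ValueError, match="negatives"):
            roc_auc(scores, gold({"a", "b"}, {"a", "b"}))


class TestBootstrap:
    def test_perfect_ranking_degenerate_interval(self):
        genes = [f"g{i}" for i in range(40)]
        scores = pd.Series(np.arange(40, dtype=float), index=genes)
        res = bootstrap_ci(scores, gold(set(genes[-10:]), genes), n_boot=200, seed=4)
        assert res.auc == res.ci_low == res.ci_high == 1.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        scores = pd.Series(rng.standard_normal(60), index=genes)
        g = gold(set(genes[:12]), genes)
        a = bootstrap_ci(scores, g, n_boot=200, seed=7)
        b = bootstrap_ci(scores, g, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_width_shrinks_with_more_genes(self):
        def width(n_genes, seed):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(n_genes)]
            is_pos = np.zeros(n_genes, dtype=bool)
            is_pos[: n_genes // 10] = True
            scores = pd.Series(
                np.where(is_pos, 1.0, 0.0) + rng.standard_normal(n_genes), index=genes
            )
            res = bootstrap_ci(
                scores, gold({g for g, p in zip(genes, is_pos) if p}, genes),
                n_boot=400, seed=1,
            )
            return res.ci_high - res.ci_low

        assert width(2000, seed=3) < width(200, seed=3)

    def test_n_boot_floor(self):
        scores = pd.Series({"a": 1.0, "b": 0.0})
        with pytest.raises(ValueError):
            bootstrap_ci(scores, gold({"a"}, {"a", "b"}), n_boot=10)


class TestPermutationBand:
    def make_random_rankings(self, n_perm=100, n_genes=500, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        return genes, [
            pd.Series(rng.permutation(n_genes).astype(float), index=genes)
            for _ in range(n_perm)
        ]

    def test_random_rankings_center_near_half(self):
        genes, rankings = self.make_random_rankings()
        g = gold(set(genes[:50]), genes)
        mean, lo, hi = permutation_band(rankings, g, seed=2)
        assert 0.45 < mean < 0.55
        assert lo <= mean <= hi

    def test_identical_rankings_collapse_band(self):
        genes, rankings = self.make_random_rankings(n_perm=1)
        g = gold(set(genes[:50]), genes)
        mean, lo, hi = permutation_band([rankings[0]] * 40, g, seed=2)
        assert lo == hi == mean

    def test_order_invariance(self):
        genes, rankings = self.make_random_rankings(n_perm=40)
        g = gold(set(genes[:50]), genes)
        a = permutation_band(rankings, g, seed=5)
        b = permutation_band(list(reversed(rankings)), g, seed=5)
        assert a == b

    def test_minimum_count(self):
        genes, rankings = self.make_random_rankings(n_perm=10)
        with pytest.raises(ValueError, match=">= 30"):
            permutation_band(rankings, gold(set(genes[:50]), genes))


class TestQqInflation:
    def test_perfectly_calibrated_lambda_one(self):
        n = 999
        ps = np.arange(1, n + 1) / (n + 1.0)
        qq = qq_inflation(ps)
        assert qq.lambda_inflation == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(qq.expected, qq.observed, atol=1e-12)

    def test_signal_bearing_set_inflates(self):
        # one gene in ten carries signal: lambda must exceed 1.05
        rng = np.random.default_rng(6)
        ps = rng.uniform(0, 1, 500)
        ps[:50] = rng.uniform(0, 1e-3, 50)
        assert qq_inflation(ps).lambda_inflation > 1.05

    def test_domain_checks(self):
        with pytest.raises(ValueError, match=">= 20"):
            qq_inflation(np.full(5, 0.5))
        with pytest.raises(ValueError, match="\\(0, 1\\]"):
            qq_inflation(np.concatenate([np.full(30, 0.5), [0.0]]))


class TestCompareMethods:
    def setup_case(self, seed=0, n_genes=200):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        scores = pd.Series(rng.standard_normal(n_genes), index=genes)
        g = gold(set(genes[:20]), genes)
        rankings = [
            pd.Series(rng.permutation(n_genes).astype(float), index=genes)
            for _ in range(40)
        ]
        return genes, scores, g, rankings

    def test_identical_rankings_equal_auc(self):
        genes, scores, g, rankings = self.setup_case()
        cmp = compare_methods(scores, scores.copy(), rankings, g, n_boot=150, seed=1)
        assert cmp.gwas.auc == cmp.netwas.auc
        assert not cmp.netwas_above_gwas

    def test_reversed_netwas_flips_auc(self):
        genes, scores, g, rankings = self.setup_case(seed=3)
        scores = pd.Series(
            np.random.default_rng(5).permutation(len(genes)).astype(float), index=genes
        )
        cmp = compare_methods(scores, -scores, rankings, g, n_boot=150, seed=1)
        assert cmp.netwas.auc == pytest.approx(1.0 - cmp.gwas.auc)

    def test_universe_mismatch_is_error(self):
        genes, scores, g, rankings = self.setup_case()
        with pytest.raises(ValueError, match="universe"):
            compare_methods(scores, scores.iloc[:-1], rankings, g, n_boot=150)

    def test_pvalue_ranking_orientation(self):
        # smaller p must score higher
        ps = pd.Series({"a": 1e-6, "b": 0.5})
        ranking = ranking_from_pvalues(ps)
        assert ranking["a"] > ranking["b"]
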