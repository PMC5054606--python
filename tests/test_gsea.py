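"""Correlation ranking, weighted-KS enrichment score, permutation FWER."""

import numpy as np
import pandas as pd
import pytest

from lincscout.core import ExpressionTable, GeneSetCollection
from lincscout.gsea import (
    RankedGeneList,
    fwer_pvalues,
    gsea_es,
    rank_by_correlation,
)


def brute_es(genes, correlations, gene_set, p=1.0):
    """Independent running-sum implementation of the weighted KS score."""
    hits = [g in gene_set for g in genes]
    n_hits = sum(hits)
    n_miss = len(genes) - n_hits
    denom = sum(abs(r) ** p for g, r in zip(genes, correlations) if g in gene_set)
    running, best = 0.0, 0.0
    for g, r in zip(genes, correlations):
        if g in gene_set:
            running += abs(r) ** p / denom
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def make_ranked(n=100, seed=0):
    rng = np.random.default_rng(seed)
    r = np.sort(rng.uniform(-1, 1, n))[::-1]
    genes = [f"g{i:03d}" for i in range(n)]
    return RankedGeneList("L", genes, r)


class TestRanking:
    def _table(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(10)]
        frame = pd.DataFrame(
            rng.lognormal(1, 1, size=(50, 10)),
            index=[f"g{i:02d}" for i in range(50)],
            columns=samples,
        )
        return ExpressionTable(frame)

    def test_identical_profile_ranks_first(self):
        coding = self._table()
        linc = coding.frame.iloc[7].copy()
        linc.name = "L"
        ranked = rank_by_correlation(linc, coding)
        assert ranked.genes[0] == coding.ids[7]
        assert ranked.correlations[0] == pytest.approx(1.0)

    def test_anticorrelated_ranks_last(self):
        coding = self._table()
        x = np.log2(coding.frame.iloc[3] + 1)
        linc = pd.Series(2 ** (2 * x.max() - 2 * x) - 1, name="L")
        ranked = rank_by_correlation(linc, coding)
        assert ranked.genes[-1] == coding.ids[3]
        assert ranked.correlations[-1] == pytest.approx(-1.0)

    def test_order_matches_brute_force_sort(self):
        coding = self._table()
        rng = np.random.default_rng(1)
        linc = pd.Series(rng.lognormal(1, 1, 10), index=coding.samples, name="L")
        ranked = rank_by_correlation(linc, coding)
        x = np.log2(linc.to_numpy() + 1)
        brute = {}
        for g in coding.ids:
            y = np.log2(coding.frame.loc[g].to_numpy() + 1)
            brute[g] = np.corrcoef(x, y)[0, 1]
        expected = sorted(coding.ids, key=lambda g: (-brute[g], g))
        assert ranked.genes == expected
        assert np.allclose(ranked.correlations, [brute[g] for g in ranked.genes])

    def test_constant_linc_raises(self):
        coding = self._table()
        linc = pd.Series(np.ones(10), index=coding.samples, name="L")
        with pytest.raises(ValueError, match="constant"):
            rank_by_correlation(linc, coding)


class TestEnrichmentScore:
    def test_top_block_equal_weights(self):
        genes = [f"g{i}" for i in range(100)]
        ranked = RankedGeneList("L", genes, np.full(100, 0.5))
        top5 = set(genes[:5])
        es = gsea_es(ranked, top5)
        assert es == pytest.approx(brute_es(genes, ranked.correlations, top5))
        assert es == pytest.approx(1.0)  # all hits before any miss

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(2)
        ranked = make_ranked(80, seed=3)
        for _ in range(20):
            size = int(rng.integers(5, 30))
            gene_set = set(rng.choice(ranked.genes, size=size, replace=False))
            assert gsea_es(ranked, gene_set) == pytest.approx(
                brute_es(ranked.genes, ranked.correlations, gene_set)
            )

    def test_p_zero_reduces_to_unweighted_ks(self):
        ranked = make_ranked(60, seed=4)
        gene_set = set(ranked.genes[10:25])
        es = gsea_es(ranked, gene_set, p=0.0)
        hits = np.array([g in gene_set for g in ranked.genes])
        running = np.cumsum(
            np.where(hits, 1 / hits.sum(), -1 / (~hits).sum())
        )
        expected = running[np.argmax(np.abs(running))]
        assert es == pytest.approx(expected)

    def test_whole_list_set_is_error(self):
        ranked = make_ranked(20)
        with pytest.raises(ValueError):
            gsea_es(ranked, set(ranked.genes))

    def test_disjoint_set_is_error(self):
        ranked = make_ranked(20)
        with pytest.raises(ValueError):
            gsea_es(ranked, {"absent"})

    def test_es_bounded(self):
        rng = np.random.default_rng(5)
        ranked = make_ranked(50, seed=6)
        for _ in range(10):
            gene_set = set(rng.choice(ranked.genes, size=8, replace=False))
            assert -1.0 <= gsea_es(ranked, gene_set) <= 1.0


class TestFwer:
    def _sets(self, ranked, rng, n_sets=10):
        return GeneSetCollection(
            {
                f"GO:{i}": frozenset(rng.choice(ranked.genes, size=12, replace=False))
                for i in range(n_sets)
            }
        )

    def test_pvalues_are_multiples_of_one_over_nperm(self):
        rng = np.random.default_rng(7)
        ranked = make_ranked(60, seed=8)
        results = fwer_pvalues(ranked, self._sets(ranked, rng), n_perm=200, seed=1)
        for res in results:
            assert (res.fwer_p * 200) == pytest.approx(round(res.fwer_p * 200))
            assert (res.perm_p * 200) == pytest.approx(round(res.perm_p * 200))

    def test_max_statistic_dominance(self):
        rng = np.random.default_rng(9)
        ranked = make_ranked(60, seed=10)
        results = fwer_pvalues(ranked, self._sets(ranked, rng), n_perm=300, seed=2)
        for res in results:
            assert res.fwer_p >= res.perm_p

    def test_weak_term_gets_p_one(self):
        ranked = make_ranked(100, seed=11)
        rng = np.random.default_rng(12)
        sets = {
            "strong": frozenset(ranked.genes[:10]),
            "weak": frozenset(rng.choice(ranked.genes[40:], size=10, replace=False)),
        }
        results = {r.term: r for r in fwer_pvalues(ranked, sets, n_perm=200, seed=3)}
        assert results["weak"].fwer_p > results["strong"].fwer_p
        assert results["strong"].fwer_p <= 0.05

    def test_planted_top_genes_significant(self):
        ranked = make_ranked(200, seed=13)
        rng = np.random.default_rng(14)
        sets = {"planted": frozenset(ranked.genes[:15])}
        for i in range(20):
            sets[f"rand{i}"] = frozenset(
                rng.choice(ranked.genes, size=15, replace=False)
            )
        results = {r.term: r for r in fwer_pvalues(ranked, sets, n_perm=500, seed=4)}
        assert results["planted"].significant
        assert results["planted"].fwer_p <= 0.05

    def test_small_nperm_warns(self):
        ranked = make_ranked(30, seed=15)
        with pytest.warns(UserWarning, match="unstable"):
            fwer_pvalues(ranked, {"s": frozenset(ranked.genes[:6])}, n_perm=50, seed=5)
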