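"""The five-step candidate filter and the ORF finder."""

import numpy as np
import pandas as pd
import pytest

from lincscout.core import ExpressionTable, GenomeInterval, PipelineConfig, TranscriptModel
from lincscout.filters import find_longest_orf, longest_orf, run_filters

STOPS = {"TAA", "TAG", "TGA"}


def brute_longest_orf(seq):
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            codon = seq[j : j + 3]
            if "N" in seq[i : j + 3]:
                break
            if codon in STOPS:
                best = max(best, j + 3 - i)
                break
    return best


class TestLongestOrf:
    def test_single_complete_orf(self):
        assert find_longest_orf("ATGAAATAG") == 9

    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCC") == 0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            find_longest_orf("")

    def test_orf_may_not_span_n(self):
        assert find_longest_orf("ATGANATAG") == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=300))
            assert find_longest_orf(seq) == brute_longest_orf(seq)

    def test_position_reported(self):
        length, start = longest_orf("CCATGAAATAGCC")
        assert (length, start) == (9, 2)


def _tx(tx_id, chrom, strand, exons):
    return TranscriptModel(
        id=tx_id, chrom=chrom, strand=strand,
        exons=[GenomeInterval(chrom, s, e, strand) for s, e in exons],
    )


@pytest.fixture
def toy():
    """Five transcripts, one failing each step, E passing everything."""
    rng = np.random.default_rng(42)
    genome = {"chr1": "".join(rng.choice(list("ACG"), size=30000))}  # no T: no stops
    # plant a 450 nt ORF inside D's exon (ATG + 148 codons + TAA)
    g = list(genome["chr1"])
    orf = "ATG" + "GCA" * 148 + "TAA"
    g[20000 : 20000 + len(orf)] = orf
    genome["chr1"] = "".join(g)

    known = [_tx("K", "chr1", "+", [(1000, 2000)])]
    A = _tx("A", "chr1", "+", [(1500, 2500)])          # overlaps known exon
    B = _tx("B", "chr1", "+", [(5000, 5150)])          # 150 nt: too short
    C = _tx("C", "chr1", "+", [(8000, 8500)])          # single exon, no CAGE support
    D = _tx("D", "chr1", "+", [(19900, 20600)])        # carries the 450 nt ORF
    E = _tx("E", "chr1", "+", [(25000, 25300), (25600, 25900)])
    cage = [GenomeInterval("chr1", 19850, 19890)]      # upstream support for D
    expression = ExpressionTable(
        pd.DataFrame({"esc": [5.0, 5.0, 5.0, 5.0, 5.0]}, index=list("ABCDE"))
    )
    scores = {k: 0.2 for k in "ABCDE"}
    return genome, known, [A, B, C, D, E], cage, expression, scores


class TestRunFilters:
    def test_toy_elimination_reasons(self, toy):
        genome, known, assembled, cage, expression, scores = toy
        out, report = run_filters(assembled, known, cage, expression, scores, genome)
        assert [tx.id for tx in out] == ["E"]
        assert report.reasons == {
            "A": "known_overlap",
            "B": "size_cage",
            "C": "size_cage",
            "D": "orf",
        }
        assert report.n_input == 5 and report.n_output == 1

    def test_counts_reconcile(self, toy):
        genome, known, assembled, cage, expression, scores = toy
        _, report = run_filters(assembled, known, cage, expression, scores, genome)
        assert report.n_input == report.n_output + len(report.reasons)
        for step, (n_in, n_out) in report.step_counts.items():
            assert n_in - n_out == len(report.eliminated(step))

    def test_expression_and_score_thresholds(self, toy):
        genome, known, assembled, cage, expression, scores = toy
        low_expr = ExpressionTable(expression.frame.assign(esc=[5, 5, 5, 5, 0.5]))
        out, report = run_filters(assembled, known, cage, low_expr, scores, genome)
        assert out == [] and report.reasons["E"] == "expression"
        hi_score = dict(scores, E=0.45)
        out, report = run_filters(assembled, known, cage, expression, hi_score, genome)
        assert out == [] and report.reasons["E"] == "coding_potential"
        # score exactly at the cutoff is kept
        at_cutoff = dict(scores, E=0.44)
        out, _ = run_filters(assembled, known, cage, expression, at_cutoff, genome)
        assert [tx.id for tx in out] == ["E"]

    def test_empty_input(self, toy):
        genome, known, _, cage, expression, scores = toy
        out, report = run_filters([], known, cage, expression, scores, genome)
        assert out == [] and report.n_input == 0

    def test_missing_ids_raise(self, toy):
        genome, known, assembled, cage, expression, scores = toy
        with pytest.raises(KeyError, match="A"):
            run_filters(
                assembled, known, cage,
                ExpressionTable(expression.frame.drop("A")), scores, genome,
            )

    def test_idempotent_on_survivors(self, toy):
        genome, known, assembled, cage, expression, scores = toy
        out, _ = run_filters(assembled, known, cage, expression, scores, genome)
        again, report = run_filters(out, known, cage, expression, scores, genome)
        assert [t.id for t in again] == [t.id for t in out]
        assert report.reasons == {}

    def test_output_never_overlaps_known_exons(self, toy):
        genome, known, assembled, cage, expression, scores = toy
        out, _ = run_filters(assembled, known, cage, expression, scores, genome)
        for tx in out:
            for exon in tx.exons:
                for ktx in known:
                    for kexon in ktx.exons:
                        assert not exon.overlaps(kexon)


class TestOnSyntheticWorld:
    def test_truth_table(self, world, cfg):
        out, report = run_filters(
            world.assembled, world.known, world.cage_peaks, world.expression,
            world.coding_scores, world.genome, cfg,
        )
        out_ids = {tx.id for tx in out}
        novel_ids = {l.transcript.id for l in world.novel_lincs_true}
        # every sufficiently expressed novel lincRNA survives
        for tx_id in novel_ids:
            if world.expression.mean_fpkm(tx_id) >= cfg.min_fpkm_novel:
                assert tx_id in out_ids
        # every coding transcript is gone, at annotation overlap or coding potential
        for locus in world.true_loci:
            if locus.role == "coding":
                assert locus.transcript.id not in out_ids
                assert report.reasons[locus.transcript.id] in (
                    "known_overlap", "coding_potential",
                )
        assert out_ids <= novel_ids
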