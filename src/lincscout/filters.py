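"""The five-step lincRNA detection funnel.

From an assembled transcriptome to putative lincRNAs:

1. drop transcripts with exonic overlap against the known annotation;
2. keep spliced length >= 200 nt, and require single-exon survivors to
   have a CAGE peak within the 1 kb strand-aware upstream window of the TSS;
3. keep transcripts whose longest ORF is < 300 nt;
4. keep transcripts expressed at FPKM >= 1;
5. keep transcripts with coding-potential score <= 0.44.

Every elimination is recorded in a FilterReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import (
    ExpressionTable,
    GenomeInterval,
    IntervalIndex,
    PipelineConfig,
    TranscriptModel,
)

STEPS = (
    "known_overlap",
    "size_cage",
    "orf",
    "expression",
    "coding_potential",
)

_STOP = {"TAA", "TAG", "TGA"}


def longest_orf(tx_sequence: str) -> tuple[int, int | None]:
    """Longest complete ORF in the 3 forward frames: (length, start offset).

    The sequence is the mature transcript, 5'->3'; an ORF runs ATG..stop
    inclusive.  Codons containing N neither start, extend, nor stop an ORF
    (an ORF may not span an N run).  Returns (0, None) when no complete ORF
    exists.
    """
    seq = tx_sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    best, best_start = 0, None
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOP:
                length = pos + 3 - start
                if length > best:
                    best, best_start = length, start
                start = None
    return best, best_start


def find_longest_orf(tx_sequence: str) -> int:
    """Length of the longest complete ORF (0 if none); see :func:`longest_orf`."""
    return longest_orf(tx_sequence)[0]


@dataclass
class FilterReport:
    """Per-step survivor counts and per-transcript elimination reasons."""

    n_input: int = 0
    step_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        if not self.step_counts:
            return self.n_input
        return self.step_counts[STEPS[-1]][1]

    def eliminated(self, step: str) -> list[str]:
        return [tx for tx, s in self.reasons.items() if s == step]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"step": s, "n_in": io[0], "n_out": io[1], "n_removed": io[0] - io[1]}
                for s, io in self.step_counts.items()
            ]
        )


def _upstream_cage_window(tx: TranscriptModel, up: int) -> GenomeInterval:
    """Strand-aware [TSS-up, TSS] window, closed at the TSS base."""
    tss = tx.tss
    if tx.strand == "+":
        return GenomeInterval(tx.chrom, max(0, tss - up), tss + 1, tx.strand)
    return GenomeInterval(tx.chrom, tss, tss + up + 1, tx.strand)


def run_filters(
    assembled: Sequence[TranscriptModel],
    known: Sequence[TranscriptModel],
    cage_peaks: Sequence[GenomeInterval],
    expression: ExpressionTable,
    coding_scores: Mapping[str, float],
    genome: Mapping[str, str],
    cfg: PipelineConfig | None = None,
    overlap_same_strand_only: bool = False,
    overlap_span_level: bool = False,
) -> tuple[list[TranscriptModel], FilterReport]:
    """Apply the five filters in order; returns survivors and the report.

    ``overlap_same_strand_only`` restricts step 1 to same-strand overlap;
    ``overlap_span_level`` compares gene spans rather than exons.
    """
    cfg = cfg or PipelineConfig()
    report = FilterReport(n_input=len(assembled))

    missing_expr = [tx.id for tx in assembled if tx.id not in expression]
    missing_score = [tx.id for tx in assembled if tx.id not in coding_scores]
    if missing_expr or missing_score:
        raise KeyError(
            f"transcripts missing from expression table: {missing_expr}; "
            f"from coding-score table: {missing_score}"
        )

    if overlap_span_level:
        known_index = IntervalIndex(tx.span() for tx in known)
    else:
        known_index = IntervalIndex(e for tx in known for e in tx.exons)
    cage_index = IntervalIndex(cage_peaks)

    # step 1: annotation overlap
    survivors = []
    for tx in assembled:
        query = tx.span() if overlap_span_level else None
        hit = any(
            known_index.any_overlap(
                query or exon, same_strand=overlap_same_strand_only
            )
            for exon in ([query] if query else tx.exons)
        )
        if hit:
            report.reasons[tx.id] = "known_overlap"
        else:
            survivors.append(tx)
    report.step_counts["known_overlap"] = (len(assembled), len(survivors))

    # step 2: size selection + CAGE support for single-exon transcripts
    n_in = len(survivors)
    kept = []
    for tx in survivors:
        if tx.length < cfg.min_len:
            report.reasons[tx.id] = "size_cage"
            continue
        if tx.n_exons == 1 and not cage_index.any_overlap(
            _upstream_cage_window(tx, cfg.tss_up)
        ):
            report.reasons[tx.id] = "size_cage"
            continue
        kept.append(tx)
    survivors = kept
    report.step_counts["size_cage"] = (n_in, len(survivors))

    # step 3: ORF length
    n_in = len(survivors)
    kept = []
    for tx in survivors:
        if find_longest_orf(tx.spliced_sequence(genome)) < cfg.max_orf:
            kept.append(tx)
        else:
            report.reasons[tx.id] = "orf"
    survivors = kept
    report.step_counts["orf"] = (n_in, len(survivors))

    # step 4: expression abundance
    n_in = len(survivors)
    kept = []
    for tx in survivors:
        if expression.mean_fpkm(tx.id) >= cfg.min_fpkm_novel:
            kept.append(tx)
        else:
            report.reasons[tx.id] = "expression"
    survivors = kept
    report.step_counts["expression"] = (n_in, len(survivors))

    # step 5: coding potential
    n_in = len(survivors)
    kept = []
    for tx in survivors:
        if coding_scores[tx.id] <= cfg.coding_cutoff:
            kept.append(tx)
        else:
            report.reasons[tx.id] = "coding_potential"
    survivors = kept
    report.step_counts["coding_potential"] = (n_in, len(survivors))

    return survivors, report
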