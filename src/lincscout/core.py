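"""Core domain types and coordinate conventions.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
The only place 1-based arithmetic happens is the GTF reader/writer in
:mod:`lincscout.io`.  A transcription start site (TSS) is the first
transcribed base: ``first_exon.start`` on the plus strand and
``last_exon.end - 1`` (the last covered base) on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."


@dataclass(frozen=True)
class GenomeInterval:
    """A stranded genomic span; the unit of all region arithmetic."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """Exon-structured transcript with a strand-aware derived TSS."""

    id: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    gene_id: str | None = None
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in (PLUS, MINUS):
            raise ValueError(
                f"transcript {self.id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.id}: needs at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"transcript {self.id}: exon on wrong chromosome")

    @property
    def tss(self) -> int:
        if self.strand == PLUS:
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand, self.id)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature transcript sequence, 5'->3' (reverse-complemented on minus)."""
        seq = "".join(genome[self.chrom][e.start : e.end] for e in self.exons)
        if self.strand == MINUS:
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tss_proximal_region(
    chrom: str, tss: int, strand: str, up: int = 1000, down: int = 500
) -> GenomeInterval:
    """The TSS proximal region: ``up`` bp upstream through ``down`` bp downstream.

    On the plus strand this is ``[tss-up, tss+down)``; on the minus strand
    the mirror ``[tss-down, tss+up)``.
    """
    if strand == PLUS:
        return GenomeInterval(chrom, tss - up, tss + down, strand)
    if strand == MINUS:
        return GenomeInterval(chrom, tss - down, tss + up, strand)
    raise ValueError("TSS proximal region needs a stranded TSS")


class IntervalIndex:
    """Per-chromosome interval tree over GenomeIntervals for overlap queries."""

    def __init__(self, intervals: Iterable[GenomeInterval] = ()):  # noqa: D107
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomeInterval) -> None:
        # tag with a running index so duplicate intervals are kept
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, (self._n, iv)
        )
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(
        self, query: GenomeInterval, same_strand: bool = False
    ) -> list[GenomeInterval]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        if same_strand:
            hits = [h for h in hits if h[1].strand == query.strand]
        hits.sort()
        return [h[1] for h in hits]

    def any_overlap(self, query: GenomeInterval, same_strand: bool = False) -> bool:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return False
        if not same_strand:
            return bool(tree.overlaps(query.start, query.end))
        return any(
            h.data[1].strand == query.strand
            for h in tree.overlap(query.start, query.end)
        )


def query_overlaps(
    query: GenomeInterval,
    subjects: "IntervalIndex | Iterable[GenomeInterval]",
    same_strand: bool = False,
) -> list[GenomeInterval]:
    """All subjects sharing >= 1 bp with ``query`` (optionally strand-matched)."""
    if not isinstance(subjects, IntervalIndex):
        subjects = IntervalIndex(subjects)
    return subjects.overlapping(query, same_strand=same_strand)


class SignalTrack:
    """Per-base non-negative coverage, implicitly zero outside stored runs.

    Stored per chromosome as sorted, non-overlapping runs
    ``(starts, ends, values)``; a cached cumulative integral makes interval
    means O(log n).
    """

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start:
                raise ValueError(f"empty run {chrom}:{start}-{end}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"bad signal value {value!r} at {chrom}:{start}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls()
        for chrom, runs in by_chrom.items():
            runs.sort()
            starts = np.array([r[0] for r in runs], dtype=np.int64)
            ends = np.array([r[1] for r in runs], dtype=np.int64)
            values = np.array([r[2] for r in runs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            track._runs[chrom] = (starts, ends, values)
        return track

    @classmethod
    def from_dense(cls, arrays: Mapping[str, np.ndarray]) -> "SignalTrack":
        """Run-length encode dense per-base arrays (zeros dropped)."""
        track = cls()
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            values = arr[starts]
            keep = values != 0
            track._runs[chrom] = (
                starts[keep].astype(np.int64),
                ends[keep].astype(np.int64),
                values[keep],
            )
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def _cumint(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            starts, ends, values = self._runs[chrom]
            self._cum[chrom] = np.concatenate(
                ([0.0], np.cumsum((ends - starts) * values))
            )
        return self._cum[chrom]

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end)."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        cum = self._cumint(chrom)
        total = cum[hi] - cum[lo]
        # trim partial overlap at the two edges
        total -= max(0, start - starts[lo]) * values[lo]
        total -= max(0, ends[hi - 1] - end) * values[hi - 1]
        return float(total)

    def mean(self, chrom: str, start: int, end: int) -> float:
        return self.integral(chrom, start, end) / (end - start)

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end) as a dense array (0 outside runs)."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._runs or end <= start:
            return out
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            out[a:b] = values[i]
        return out


class ExpressionTable:
    """FPKM matrix: rows are transcript/gene ids, columns are samples."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ids in expression table: {dups}")
        if (frame.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        self.frame = frame.astype(float)

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def value(self, tx_id: str, sample: str) -> float:
        return float(self.frame.at[tx_id, sample])

    def mean_fpkm(self, tx_id: str) -> float:
        return float(self.frame.loc[tx_id].mean())

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self.frame.index


class GeneSetCollection:
    """Named gene sets (GMT), e.g. GO terms, with optional descriptions."""

    def __init__(self, sets: Mapping[str, frozenset[str]], descriptions: Mapping[str, str] | None = None):
        self.sets = {name: frozenset(genes) for name, genes in sets.items()}
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class PipelineConfig:
    """Every threshold and tunable the pipeline applies, in one place.

    Defaults follow the published analysis: transcripts >= 200 nt with
    longest ORF < 300 nt, FPKM >= 1 for novel transcripts, coding-potential
    cutoff 0.44, TSS proximal regions -1 kb..+0.5 kb, negatives sampled
    within +-10 kb, 1,500 bp scan windows stepped by 300 bp, RBF SVM with
    gamma = 1 and cost = 2, 10-fold CV, Obs/Exp word fold-change gates
    1.2 / 0.8, motif FDR 0.01, 1,000 GSEA permutations at FWER 0.05.
    """

    min_len: int = 200
    max_orf: int = 300
    min_fpkm_novel: float = 1.0
    min_fpkm_known: float = 0.5
    coding_cutoff: float = 0.44
    tss_up: int = 1000
    tss_down: int = 500
    neg_zone: int = 10000
    scan_window: int = 1500
    scan_step: int = 300
    profile_window: int = 300
    profile_step: int = 50
    meta_bins: int = 100
    cv_folds: int = 10
    svm_gamma: float = 1.0
    svm_cost: float = 2.0
    neg_per_pos: int = 1
    fc_hi: float = 1.2
    fc_lo: float = 0.8
    motif_fdr: float = 0.01
    motif_presence_p: float = 1e-4
    n_perm: int = 1000
    fwer_alpha: float = 0.05
    n_boot: int = 1000
    profile_flank: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_len", "max_orf", "min_fpkm_novel", "min_fpkm_known",
            "coding_cutoff", "tss_up", "tss_down", "neg_zone", "scan_window",
            "scan_step", "profile_window", "profile_step", "meta_bins",
            "cv_folds", "svm_gamma", "svm_cost", "neg_per_pos", "fc_hi",
            "fc_lo", "motif_fdr", "motif_presence_p", "n_perm", "fwer_alpha",
            "n_boot", "profile_flank",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineConfig.{name} must be positive")
        if self.tss_up + self.tss_down != self.scan_window:
            raise ValueError(
                "tss_up + tss_down must equal scan_window "
                f"({self.tss_up} + {self.tss_down} != {self.scan_window})"
            )

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
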