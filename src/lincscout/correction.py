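"""5'-end correction of putative lincRNAs from predicted TSS proximal regions.

Each predicted region is 1,500 bp; its anchor point — 1,000 bp into the
region on the transcript's strand (``start + 1000`` on plus,
``end - 1001`` on minus) — is the new-TSS candidate.  For a transcript
with original TSS t, candidate regions are those whose anchor lies in the
strand-aware window [t - 1000, t); the candidate with the anchor closest
to t wins (ties break upstream), and the transcript's first exon is
extended 5' to that anchor.  Transcripts without a candidate are left
unchanged.  Correction never moves a TSS downstream and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    GenomeInterval,
    PipelineConfig,
    SignalTrack,
    TranscriptModel,
)
from .signal import cage_distance, tss_meta_profile
from .tss_model import PredictedRegionSet


@dataclass
class CorrectionRecord:
    transcript_id: str
    strand: str
    original_tss: int
    corrected_tss: int
    shift: int                      # bp moved upstream (0 if uncorrected)
    region: GenomeInterval | None   # the selected TSS proximal region
    flagged: bool = False           # anchor conflicted with existing exons


def region_anchor(region: GenomeInterval, strand: str, up: int = 1000) -> int:
    """The new-TSS point of a predicted region on the given strand."""
    if strand == "+":
        return region.start + up
    return region.end - up - 1


def correct_five_prime(
    linc: TranscriptModel,
    regions: PredictedRegionSet,
    cfg: PipelineConfig | None = None,
) -> tuple[TranscriptModel, CorrectionRecord]:
    """Correct one transcript's 5' end against the predicted region set."""
    cfg = cfg or PipelineConfig()
    tss = linc.tss
    unchanged = CorrectionRecord(linc.id, linc.strand, tss, tss, 0, None)
    candidates: list[tuple[int, GenomeInterval]] = []
    for region in regions.regions:
        if region.chrom != linc.chrom:
            continue
        anchor = region_anchor(region, linc.strand, cfg.tss_up)
        if linc.strand == "+":
            in_window = tss - cfg.tss_up <= anchor <= tss
        else:
            in_window = tss <= anchor <= tss + cfg.tss_up
        if in_window:
            candidates.append((anchor, region))
    if not candidates:
        return linc, unchanged

    def upstreamness(anchor: int) -> int:
        return tss - anchor if linc.strand == "+" else anchor - tss

    # closest anchor to the original TSS; ties toward the more upstream one.
    # An anchor at exactly the TSS wins at distance 0 and is a no-op, which
    # makes correction idempotent.
    candidates.sort(key=lambda c: (abs(c[0] - tss), -upstreamness(c[0])))
    anchor, region = candidates[0]
    if anchor == tss:
        return linc, unchanged

    exons = list(linc.exons)
    if linc.strand == "+":
        preceding = [e for e in exons[1:]]
        if any(e.start <= anchor < e.end for e in preceding):
            unchanged.flagged = True
            return linc, unchanged
        exons[0] = GenomeInterval(
            linc.chrom, anchor, exons[0].end, linc.strand
        )
    else:
        preceding = [e for e in exons[:-1]]
        if any(e.start <= anchor < e.end for e in preceding):
            unchanged.flagged = True
            return linc, unchanged
        exons[-1] = GenomeInterval(
            linc.chrom, exons[-1].start, anchor + 1, linc.strand
        )
    corrected = TranscriptModel(
        id=linc.id, chrom=linc.chrom, strand=linc.strand, exons=exons,
        gene_id=linc.gene_id, biotype=linc.biotype,
    )
    record = CorrectionRecord(
        linc.id, linc.strand, tss, anchor, upstreamness(anchor), region
    )
    return corrected, record


def correct_all(
    lincs: Sequence[TranscriptModel],
    regions: PredictedRegionSet,
    cfg: PipelineConfig | None = None,
) -> tuple[list[TranscriptModel], list[CorrectionRecord]]:
    out, records = [], []
    for linc in lincs:
        tx, rec = correct_five_prime(linc, regions, cfg)
        out.append(tx)
        records.append(rec)
    return out, records


@dataclass
class CorrectionEvaluation:
    """Before/after comparison of corrected transcript sets."""

    profiles_before: dict
    profiles_after: dict
    distances_before: np.ndarray
    distances_after: np.ndarray
    median_abs_before: float
    median_abs_after: float
    fraction_improved: float
    n_corrected: int

    def summary(self) -> dict:
        return {
            "n_corrected": self.n_corrected,
            "median_abs_cage_distance_before": self.median_abs_before,
            "median_abs_cage_distance_after": self.median_abs_after,
            "fraction_improved": self.fraction_improved,
        }


def evaluate_correction(
    before: Sequence[TranscriptModel],
    after: Sequence[TranscriptModel],
    cage_track: SignalTrack,
    cage_peaks: Sequence[GenomeInterval],
    tracks: dict[str, SignalTrack] | None = None,
    cfg: PipelineConfig | None = None,
) -> CorrectionEvaluation:
    """Paired TSS meta-profiles and nearest-CAGE-peak distances, before vs
    after correction (transcripts matched by list order)."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    tss_before = [(tx.chrom, tx.tss, tx.strand) for tx in before]
    tss_after = [(tx.chrom, tx.tss, tx.strand) for tx in after]
    tracks = {"CAGE": cage_track, **(tracks or {})}
    profiles_before = {
        name: tss_meta_profile(
            tss_before, track, cfg.profile_flank, cfg.profile_step,
            cfg.n_boot, rng,
        )
        for name, track in tracks.items()
    }
    profiles_after = {
        name: tss_meta_profile(
            tss_after, track, cfg.profile_flank, cfg.profile_step,
            cfg.n_boot, rng,
        )
        for name, track in tracks.items()
    }
    d_before = cage_distance(tss_before, cage_peaks)
    d_after = cage_distance(tss_after, cage_peaks)
    corrected = np.array(
        [b.tss != a.tss for b, a in zip(before, after)], dtype=bool
    )
    improved = np.abs(d_after) < np.abs(d_before)
    frac = float(improved[corrected].mean()) if corrected.any() else 0.0
    return CorrectionEvaluation(
        profiles_before=profiles_before,
        profiles_after=profiles_after,
        distances_before=d_before,
        distances_after=d_after,
        median_abs_before=float(np.nanmedian(np.abs(d_before))),
        median_abs_after=float(np.nanmedian(np.abs(d_after))),
        fraction_improved=frac,
        n_corrected=int(corrected.sum()),
    )
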