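"""Signal aggregation over regions and TSS-anchored meta-profiles.

Covers per-region mean signal (the chromatin/CAGE features of the
classifier), TSS meta-profiles with bootstrap bands, length-normalized
meta-transcript coverage, and signed distances from TSSs to their nearest
CAGE peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GenomeInterval, SignalTrack, TranscriptModel
from .seqfeatures import bootstrap_band


@dataclass
class MetaProfile:
    """Mean signal per bin across anchored regions, with a 5-95% band."""

    anchor: str  # "tss" or "meta_transcript"
    centers: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"center": self.centers, "mean": self.mean, "lo": self.lo, "hi": self.hi}
        )


def aggregate_signal(region: GenomeInterval, track: SignalTrack) -> float:
    """Mean per-base signal over the region."""
    return track.mean(region.chrom, region.start, region.end)


def tss_meta_profile(
    tss_sites: Sequence[tuple[str, int, str]],
    track: SignalTrack,
    flank: int = 2000,
    bin_size: int = 50,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> MetaProfile:
    """Average signal around TSSs, strand-flipped so +x is downstream.

    Each row covers offsets [-flank, +flank) binned at ``bin_size``; the
    band is a seeded bootstrap (resampling regions) at the 5-95 percentiles.
    """
    if not tss_sites:
        raise ValueError("no TSS sites")
    if (2 * flank) % bin_size:
        raise ValueError("2*flank must be a multiple of bin_size")
    rng = rng or np.random.default_rng(0)
    n_bins = 2 * flank // bin_size
    rows = np.empty((len(tss_sites), n_bins))
    for i, (chrom, tss, strand) in enumerate(tss_sites):
        values = track.dense(chrom, tss - flank, tss + flank)
        if strand == "-":
            values = values[::-1]
        rows[i] = values.reshape(n_bins, bin_size).mean(axis=1)
    lo, hi = bootstrap_band(rows, n_boot, rng)
    centers = np.arange(-flank, flank, bin_size) + bin_size / 2
    return MetaProfile("tss", centers, rows.mean(axis=0), lo, hi, len(tss_sites))


def meta_transcript_coverage(
    transcripts: Sequence[TranscriptModel],
    track: SignalTrack,
    n_bins: int = 100,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> MetaProfile:
    """Exonic coverage resampled to ``n_bins`` per transcript and averaged.

    Bin 1 is the 5' end (minus-strand coverage is reversed).  Transcripts
    shorter than ``n_bins`` are linearly interpolated.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    rng = rng or np.random.default_rng(0)
    rows = np.empty((len(transcripts), n_bins))
    for i, tx in enumerate(transcripts):
        per_base = np.concatenate(
            [track.dense(tx.chrom, e.start, e.end) for e in tx.exons]
        )
        if tx.strand == "-":
            per_base = per_base[::-1]
        # resample to n_bins on a common 0..1 axis
        src = np.linspace(0.0, 1.0, per_base.size)
        dst = (np.arange(n_bins) + 0.5) / n_bins
        rows[i] = np.interp(dst, src, per_base)
    lo, hi = bootstrap_band(rows, n_boot, rng)
    centers = np.arange(1, n_bins + 1, dtype=float)
    return MetaProfile(
        "meta_transcript", centers, rows.mean(axis=0), lo, hi, len(transcripts)
    )


def peak_position(peak: GenomeInterval, mode: str = "midpoint") -> int:
    if mode == "midpoint":
        return (peak.start + peak.end) // 2
    if mode == "5p":
        return peak.start if peak.strand != "-" else peak.end - 1
    raise ValueError(f"unknown peak position mode {mode!r}")


def cage_distance(
    tss_sites: Sequence[tuple[str, int, str]],
    peaks: Sequence[GenomeInterval],
    mode: str = "midpoint",
) -> np.ndarray:
    """Signed strand-oriented distance from each TSS to its nearest peak.

    Negative means the peak is upstream of the TSS.  Nearest is by absolute
    distance; ties break toward upstream (the more negative distance).
    TSSs on chromosomes without peaks get NaN.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in peaks}:
        by_chrom[chrom] = np.array(
            sorted(peak_position(p, mode) for p in peaks if p.chrom == chrom)
        )
    out = np.full(len(tss_sites), np.nan)
    for i, (chrom, tss, strand) in enumerate(tss_sites):
        positions = by_chrom.get(chrom)
        if positions is None or positions.size == 0:
            continue
        signed = positions - tss
        if strand == "-":
            signed = -signed
        order = np.lexsort((signed, np.abs(signed)))  # abs first, upstream on ties
        out[i] = signed[order[0]]
    return out
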