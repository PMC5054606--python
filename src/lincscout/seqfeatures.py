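"""Sequence-derived features of TSS proximal regions.

k-mer frequency vectors (k = 2, 3, 4; 336 dimensions), CpG observed/expected
ratio, annotation coverage fractions, exact reverse-complement palindromes,
TSS-anchored sliding-window profiles with bootstrap bands, Obs/Exp word
fold-change comparison between region sets, and position-weight-matrix
scanning with exact score-distribution p-values computed by dynamic
programming over a 0-order background.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import GenomeInterval, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP_CODE_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G in code space


def kmer_names(k_set: Sequence[int] = (2, 3, 4)) -> list[str]:
    """All words over ACGT for each k, lexicographic within k."""
    names = []
    for k in k_set:
        names.extend("".join(p) for p in product(BASES, repeat=k))
    return names


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts of each of the 4**k words; windows containing N are skipped."""
    codes = encode_sequence(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c < 4
        ids = ids * 4 + np.where(c < 4, c, 0)
    return np.bincount(ids[valid], minlength=4**k)


def kmer_vector(seq: str, k_set: Sequence[int] = (2, 3, 4)) -> np.ndarray:
    """Concatenated k-mer frequency vector (336-dim for k in {2,3,4}).

    Each block is count / number-of-valid-windows; windows containing N are
    excluded from both numerator and denominator.
    """
    if len(seq) <= max(k_set):
        raise ValueError(f"sequence shorter than max k ({max(k_set)})")
    blocks = []
    for k in k_set:
        counts = kmer_counts(seq, k)
        total = counts.sum()
        blocks.append(counts / total if total > 0 else counts.astype(float))
    return np.concatenate(blocks)


def cpg_oe(seq: str) -> float:
    """CpG observed/expected ratio: (N_CG * L) / (N_C * N_G); 0 if no C or G."""
    if len(seq) < 2:
        raise ValueError("need at least 2 bases")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    return n_cg * len(seq) / (n_c * n_g)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def coverage_fraction(
    region: GenomeInterval, annotation: Iterable[GenomeInterval]
) -> float:
    """Fraction of the region covered by the (merged) annotation intervals."""
    spans = [
        (max(iv.start, region.start), min(iv.end, region.end))
        for iv in annotation
        if iv.chrom == region.chrom and iv.start < region.end and iv.end > region.start
    ]
    covered = sum(e - s for s, e in merge_intervals(spans))
    return covered / region.length


def find_palindromes(
    seq: str, min_len: int = 6, max_len: int = 24
) -> list[tuple[int, int]]:
    """Maximal exact reverse-complement palindromes as (offset, length).

    Even lengths only, no spacer; a palindrome is reported when its maximal
    extension has length within [min_len, max_len].
    """
    if min_len % 2 or min_len < 4:
        raise ValueError("min_len must be even and >= 4")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    out = []
    for center in range(1, n):
        left, right = center - 1, center
        while (
            left >= 0
            and right < n
            and seq[left] in comp
            and comp[seq[left]] == seq[right]
        ):
            left -= 1
            right += 1
        length = right - left - 1
        if min_len <= length <= max_len:
            out.append((left + 1, length))
    return out


def palindrome_coverage(seq: str, min_len: int = 6, max_len: int = 24) -> float:
    """Fraction of bases lying inside at least one detected palindrome."""
    hits = find_palindromes(seq, min_len, max_len)
    if not hits:
        return 0.0
    covered = sum(e - s for s, e in merge_intervals((o, o + l) for o, l in hits))
    return covered / len(seq)


@dataclass
class Profile:
    """A position-resolved mean profile with a 5-95% bootstrap band."""

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


def bootstrap_band(
    matrix: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """5-95% percentile band of the column means under row resampling."""
    n = matrix.shape[0]
    if n == 1:
        return matrix[0].copy(), matrix[0].copy()
    idx = rng.integers(0, n, size=(n_boot, n))
    means = matrix[idx].mean(axis=1)
    lo, hi = np.percentile(means, [5, 95], axis=0)
    return lo, hi


def sliding_profile(
    anchors: Sequence[tuple[str, int, str]],
    feature: Callable[[str, int, int], float],
    flank: int = 2000,
    window: int = 300,
    step: int = 50,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> Profile:
    """Sliding-window feature profile around TSS anchors.

    ``anchors`` are (chrom, tss, strand); minus-strand anchors are flipped so
    positive offsets point downstream.  ``feature(chrom, start, end)`` returns
    the per-window scalar.  Window centers run from -flank to +flank.
    """
    rng = rng or np.random.default_rng(0)
    centers = np.arange(-flank, flank + 1, step)
    rows = np.empty((len(anchors), centers.size))
    for i, (chrom, tss, strand) in enumerate(anchors):
        for j, c in enumerate(centers):
            offset = c if strand != "-" else -c
            start = tss + offset - window // 2
            rows[i, j] = feature(chrom, start, start + window)
    lo, hi = bootstrap_band(rows, n_boot, rng)
    return Profile(centers, rows.mean(axis=0), lo, hi, len(anchors))


def obs_exp_ratios(
    seqs: Sequence[str], k_set: Sequence[int] = (2, 3, 4)
) -> dict[str, float]:
    """Obs/Exp ratio per word from the set's pooled mononucleotide composition.

    Observed frequency pools word counts across sequences; the expectation is
    the product of pooled base frequencies.  Words with zero expected
    frequency get NaN.
    """
    base_counts = np.zeros(4, dtype=float)
    for seq in seqs:
        counts = kmer_counts(seq, 1)
        base_counts += counts
    base_freq = base_counts / base_counts.sum()
    out: dict[str, float] = {}
    for k in k_set:
        counts = np.zeros(4**k, dtype=float)
        for seq in seqs:
            counts += kmer_counts(seq, k)
        freq = counts / counts.sum()
        for idx, word in enumerate("".join(p) for p in product(BASES, repeat=k)):
            expected = float(np.prod([base_freq[_BASE_INDEX[b]] for b in word]))
            out[word] = freq[idx] / expected if expected > 0 else float("nan")
    return out


def obs_exp_words(
    set_a: Sequence[str],
    set_b: Sequence[str],
    k_set: Sequence[int] = (2, 3, 4),
    fc_hi: float = 1.2,
    fc_lo: float = 0.8,
):
    """Discriminative DNA words between two sequence sets.

    Computes each set's Obs/Exp ratio per word, takes the fold change
    ratio_a / ratio_b and retains words with fold change > fc_hi or < fc_lo.
    Words with undefined ratios (zero expectation or zero denominator) are
    excluded.  Returns a DataFrame sorted by |log2 fold change|.
    """
    import pandas as pd

    ratios_a = obs_exp_ratios(set_a, k_set)
    ratios_b = obs_exp_ratios(set_b, k_set)
    rows = []
    for word in ratios_a:
        ra, rb = ratios_a[word], ratios_b[word]
        if not np.isfinite(ra) or not np.isfinite(rb) or rb == 0:
            continue
        fc = ra / rb
        rows.append((word, ra, rb, fc, fc > fc_hi or fc < fc_lo))
    frame = pd.DataFrame(
        rows, columns=["word", "obs_exp_a", "obs_exp_b", "fold_change", "selected"]
    )
    order = np.abs(np.log2(frame["fold_change"].replace(0, np.nan)))
    return frame.loc[order.sort_values(ascending=False).index].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Position weight matrices


@dataclass
class Pwm:
    """A motif as per-position base probabilities (4 x width)."""

    id: str
    matrix: np.ndarray  # shape (4, width), columns sum to 1
    background: np.ndarray | None = None  # length 4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"PWM {self.id}: need shape (4, width>=4)")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id}: columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray, background=None) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        return cls(id, counts / counts.sum(axis=0, keepdims=True), background)

    @classmethod
    def from_consensus(cls, id: str, consensus: str, p_match: float = 0.85) -> "Pwm":
        width = len(consensus)
        mat = np.full((4, width), (1 - p_match) / 3)
        for j, base in enumerate(consensus):
            mat[_BASE_INDEX[base], j] = p_match
        return cls(id, mat)

    def log_odds(self, pseudocount: float = 0.01) -> np.ndarray:
        """log2((p + pc) / (bg + pc)) per cell, pseudocount 0.01."""
        p = self.matrix + pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        bg = self.background + pseudocount
        bg = bg / bg.sum()
        return np.log2(p / bg[:, None])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


class _ScoreDistribution:
    """Exact null distribution of PWM log-odds scores over a 0-order background.

    Scores are discretized to a fixed granularity and the pmf is built by
    dynamic programming (one convolution per motif column).  p(s) is the
    background probability of a window scoring >= s.
    """

    GRANULARITY = 1e-3

    def __init__(self, pwm: Pwm, pseudocount: float = 0.01):
        lo = pwm.log_odds(pseudocount)
        scaled = np.round(lo / self.GRANULARITY).astype(np.int64)
        offset = scaled.min(axis=0)
        scaled -= offset  # per-column non-negative
        self._base_offset = int(offset.sum())
        bg = pwm.background + pseudocount
        bg = bg / bg.sum()
        pmf = np.array([1.0])
        for j in range(pwm.width):
            width = scaled[:, j].max() + 1
            col = np.zeros(width)
            for b in range(4):
                col[scaled[b, j]] += bg[b]
            pmf = np.convolve(pmf, col)
        self._sf = np.concatenate((np.cumsum(pmf[::-1])[::-1], [0.0]))
        self._scaled = scaled

    def score_window(self, codes: np.ndarray) -> int | None:
        """Scaled integer score of one width-length window, None if it has N."""
        if np.any(codes >= 4):
            return None
        return int(self._scaled[codes, np.arange(codes.size)].sum())

    def pvalue_scaled(self, scaled_score: int) -> float:
        idx = min(max(scaled_score, 0), self._sf.size - 1)
        return float(self._sf[idx])

    def to_real(self, scaled_score: int) -> float:
        return (scaled_score + self._base_offset) * self.GRANULARITY


def _distribution(pwm: Pwm, pseudocount: float = 0.01) -> _ScoreDistribution:
    # cached on the instance; keyed by pseudocount
    cache = getattr(pwm, "_dist_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(pwm, "_dist_cache", cache)
    if pseudocount not in cache:
        cache[pseudocount] = _ScoreDistribution(pwm, pseudocount)
    return cache[pseudocount]


@dataclass
class PwmHit:
    position: int
    strand: str
    score: float
    pvalue: float
    present: bool


def scaled_scores(codes: np.ndarray, scaled: np.ndarray) -> np.ndarray:
    """Integer window scores at every position (N windows -> -1)."""
    w = scaled.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        c = codes[j : j + n]
        valid &= c < 4
        acc += scaled[np.where(c < 4, c, 0), j]
    acc[~valid] = -1
    return acc


def pwm_scan(
    seq: str, pwm: Pwm, p_threshold: float = 1e-4, pseudocount: float = 0.01
) -> PwmHit:
    """Best motif hit on either strand with its exact background p-value.

    Presence is declared when the best hit's p-value is <= ``p_threshold``.
    """
    dist = _distribution(pwm, pseudocount)
    best = (-1, "+", 0)
    fwd = scaled_scores(encode_sequence(seq), dist._scaled)
    rev = scaled_scores(encode_sequence(reverse_complement(seq)), dist._scaled)
    n = len(seq)
    w = pwm.width
    for strand, scores in (("+", fwd), ("-", rev)):
        if scores.size == 0:
            continue
        pos = int(scores.argmax())
        sc = int(scores[pos])
        if sc > best[0]:
            # map reverse-strand position back to forward coordinates
            fpos = pos if strand == "+" else n - w - pos
            best = (sc, strand, fpos)
    if best[0] < 0:
        return PwmHit(-1, "+", float("-inf"), 1.0, False)
    score, strand, pos = best
    p = dist.pvalue_scaled(score)
    return PwmHit(pos, strand, dist.to_real(score), p, p <= p_threshold)


def motif_presence(
    seqs: Sequence[str],
    pwms: Sequence[Pwm],
    p_threshold: float = 1e-4,
) -> np.ndarray:
    """Presence matrix (sequences x motifs) of best-hit p <= threshold."""
    out = np.zeros((len(seqs), len(pwms)), dtype=bool)
    for j, pwm in enumerate(pwms):
        for i, seq in enumerate(seqs):
            out[i, j] = pwm_scan(seq, pwm, p_threshold).present
    return out


# ---------------------------------------------------------------------------
# Motif file formats


def read_meme(path) -> list[Pwm]:
    """MEME minimal motif format."""
    pwms: list[Pwm] = []
    background = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array(
                [float(parts[parts.index(b) + 1]) for b in "ACGT"]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for r in range(width):
                rows.append([float(x) for x in lines[i + 1 + r].split()])
            pwms.append(Pwm(motif_id, np.array(rows).T, background))
            i += width + 1
            continue
        i += 1
    return pwms


def write_meme(pwms: Sequence[Pwm], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_jaspar(path) -> list[Pwm]:
    """JASPAR PFM text: '>ID name' header then four 'A [ counts ]' rows."""
    pwms = []
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        motif_id = lines[i][1:].split()[0]
        counts = np.zeros((4, 0))
        rows = {}
        for j in range(4):
            row = lines[i + 1 + j]
            base = row[0].upper()
            nums = row.split("[")[1].split("]")[0].split() if "[" in row else row.split()[1:]
            rows[base] = [float(x) for x in nums]
        counts = np.array([rows[b] for b in BASES])
        pwms.append(Pwm.from_counts(motif_id, counts))
        i += 5
    return pwms
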