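"""Synthetic genomes with planted promoter structure and ground truth.

The generator emulates the data regime the pipeline assumes: a genome
carrying coding and lincRNA loci whose true TSSs bear elevated CpG o/e,
planted promoter motifs, CAGE peaks within +-30 bp, and promoter-shaped
chromatin signal (symmetric exponential bumps plus Poisson noise);
assembled transcripts are 5'-truncated copies of the true loci (uniform
100-1,000 bp), and lincRNA FPKM is drawn with a lower median than coding
FPKM.  lincRNA loci are split into a "known" group (present in the
annotation with their true TSS, emulating a curated reference set used for
training) and a "novel" group (present only in the assembly, the targets
of discovery and 5'-end correction).

Everything is driven by one seeded generator; a fixed seed reproduces the
world byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionTable,
    GenomeInterval,
    GeneSetCollection,
    SignalTrack,
    TranscriptModel,
    tss_proximal_region,
)
from .filters import find_longest_orf, longest_orf
from .seqfeatures import BASES, Pwm, write_meme

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)

CHROMATIN_MARKS = ("H3K4me3", "H3K9ac", "H3K27ac", "PolII", "DHS")


def default_motif_library() -> list[Pwm]:
    """Six synthetic GC-rich promoter motifs (consensus-built PWMs).

    Stand-ins for the Sp/Klf/Egr-family promoter motifs; built from
    consensus strings, not derived from any curated PWM collection.
    """
    consensi = {
        "SP1_like": "GGGGCGGGGC",
        "SP2_like": "GGGCGGGAC",
        "KLF5_like": "AGGGTGGGGC",
        "GC_box_like": "GGGGCGGGG",
        "EGR1_like": "GCGTGGGCGG",
        "NRF_like": "GCGCCTGCGC",
    }
    return [Pwm.from_consensus(name, cons, 0.9) for name, cons in consensi.items()]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic world (all bp unless noted)."""

    n_coding: int = 30
    n_linc_known: int = 50
    n_linc_novel: int = 40
    n_chroms: int = 2
    gc_background: float = 0.42
    cpg_depletion: float = 0.75       # fraction of background CG dinucleotides broken
    promoter_cpg_rate: float = 0.04   # CG pairs planted per promoter bp
    motifs_per_promoter: int = 2
    flank: int = 10500                # clear zone either side of each locus
    gap_range: tuple[int, int] = (500, 2500)
    signal_peak_height: float = 12.0  # chromatin bump summit (tags/bp), coding loci
    linc_signal_scale: float = 0.6    # lincRNA promoter bumps are weaker
    signal_decay_bp: int = 300
    signal_noise_rate: float = 0.2    # Poisson background tags/bp
    cage_peak_height: float = 40.0
    cage_decay_bp: int = 25
    cage_noise_rate: float = 0.02
    cage_jitter: int = 30             # CAGE summit within +-30 bp of the true TSS
    cage_halfwidth: int = 15
    truncation_range: tuple[int, int] = (100, 1000)
    n_samples: int = 12
    fpkm_coding: tuple[float, float] = (2.5, 0.8)  # lognormal mu, sigma (ln FPKM)
    fpkm_linc: tuple[float, float] = (0.8, 0.8)
    sample_noise_sigma: float = 0.3
    repeat_fraction: float = 0.15
    repeat_len: tuple[int, int] = (150, 600)
    repeat_tss_exclusion: int = 1600
    cgi_half: int = 400               # promoter CGI spans TSS +- cgi_half
    seed: int = 0

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class TrueLocus:
    transcript: TranscriptModel
    role: str          # "coding" or "lincRNA"
    known: bool        # present in the reference annotation
    true_tss: int


@dataclass
class SyntheticWorld:
    """A generated genome plus every input the pipeline consumes, and truth."""

    config: GeneratorConfig
    genome: dict[str, str]
    true_loci: list[TrueLocus]
    known: list[TranscriptModel]
    assembled: list[TranscriptModel]
    cage_peaks: list[GenomeInterval]
    cage_track: SignalTrack
    chromatin: dict[str, SignalTrack]
    cgi: list[GenomeInterval]
    repeats: list[GenomeInterval]
    expression: ExpressionTable
    coding_scores: dict[str, float]
    truncations: dict[str, int]       # novel-transcript id -> 5' truncation bp
    pwms: list[Pwm]

    @property
    def novel_lincs_true(self) -> list[TrueLocus]:
        return [l for l in self.true_loci if l.role == "lincRNA" and not l.known]

    @property
    def known_lincs(self) -> list[TrueLocus]:
        return [l for l in self.true_loci if l.role == "lincRNA" and l.known]

    def true_tss_of(self, tx_id: str) -> int:
        for locus in self.true_loci:
            if locus.transcript.id == tx_id:
                return locus.true_tss
        raise KeyError(tx_id)


def _mutate_transcript_base(
    codes: Mapping[str, np.ndarray], tx: TranscriptModel, offset: int, base: str
) -> None:
    """Write ``base`` at transcript coordinate ``offset`` (5'->3')."""
    positions = np.concatenate([np.arange(e.start, e.end) for e in tx.exons])
    if tx.strand == "-":
        positions = positions[::-1]
    pos = positions[offset]
    code = BASES.index(base)
    if tx.strand == "-":
        code = int(_COMP_CODE[code])
    codes[tx.chrom][pos] = code


def _write_transcript_seq(codes, tx: TranscriptModel, offset: int, seq: str) -> None:
    for i, b in enumerate(seq):
        _mutate_transcript_base(codes, tx, offset + i, b)


def _deplete_transcript_atg(codes, tx: TranscriptModel, genome_str) -> None:
    """Remove start codons from the mature transcript (ATG -> ATC)."""
    seq = tx.spliced_sequence(genome_str)
    pos = seq.find("ATG")
    while pos != -1:
        _mutate_transcript_base(codes, tx, pos + 2, "C")
        seq = seq[: pos + 2] + "C" + seq[pos + 3 :]
        pos = seq.find("ATG", pos + 1)


def _exon_layout(
    rng: np.random.Generator, role: str, novel: bool
) -> list[tuple[int, int]]:
    """Exon (length, following-intron-length) templates, 5'->3'."""
    if role == "coding":
        n_exons = int(rng.integers(2, 4))
        lens = [int(rng.integers(400, 800)) for _ in range(n_exons)]
        introns = [int(rng.integers(300, 900)) for _ in range(n_exons - 1)] + [0]
        return list(zip(lens, introns))
    if novel and rng.random() < 0.5:
        return [(int(rng.integers(1400, 2600)), 0)]  # single exon
    first = int(rng.integers(1400, 1900))
    second = int(rng.integers(300, 700))
    return [(first, int(rng.integers(200, 800))), (second, 0)]


def simulate_world(cfg: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticWorld:
    """Generate a deterministic synthetic world under the given conditions."""
    cfg = cfg or GeneratorConfig()
    if seed is not None:
        cfg = cfg.with_(seed=seed)
    rng = np.random.default_rng(cfg.seed)

    # --- locus layout -----------------------------------------------------
    roles = (
        [("coding", True)] * cfg.n_coding
        + [("lincRNA", True)] * cfg.n_linc_known
        + [("lincRNA", False)] * cfg.n_linc_novel
    )
    order = rng.permutation(len(roles))
    chrom_of = {i: f"chr{(k % cfg.n_chroms) + 1}" for k, i in enumerate(order)}

    counters = {"coding": 0, "klinc": 0, "nlinc": 0}
    loci: list[TrueLocus] = []
    cursor: dict[str, int] = {f"chr{c+1}": 0 for c in range(cfg.n_chroms)}
    for i, (role, known) in enumerate(roles):
        chrom = chrom_of[i]
        strand = "+" if rng.random() < 0.5 else "-"
        layout = _exon_layout(rng, role, novel=not known)
        span = sum(l for l, _ in layout) + sum(g for _, g in layout)
        start = cursor[chrom] + cfg.flank + int(rng.integers(*cfg.gap_range))
        exons = []
        pos = start
        for length, intron in layout:
            exons.append(GenomeInterval(chrom, pos, pos + length, strand))
            pos += length + intron
        cursor[chrom] = pos + cfg.flank
        if role == "coding":
            counters["coding"] += 1
            tx_id = f"CODING_{counters['coding']:04d}"
        elif known:
            counters["klinc"] += 1
            tx_id = f"KLINC_{counters['klinc']:04d}"
        else:
            counters["nlinc"] += 1
            tx_id = f"NLINC_{counters['nlinc']:04d}"
        tx = TranscriptModel(
            id=tx_id, chrom=chrom, strand=strand, exons=exons,
            gene_id=tx_id, biotype="protein_coding" if role == "coding" else "lincRNA",
        )
        loci.append(TrueLocus(tx, role, known, tx.tss))

    chrom_lens = {c: cursor[c] + cfg.flank for c in cursor}

    # --- background sequence with CpG depletion ---------------------------
    p_base = np.array(
        [
            (1 - cfg.gc_background) / 2,
            cfg.gc_background / 2,
            cfg.gc_background / 2,
            (1 - cfg.gc_background) / 2,
        ]
    )
    codes: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lens.items():
        arr = rng.choice(4, size=length, p=p_base).astype(np.int8)
        cg = np.flatnonzero((arr[:-1] == 1) & (arr[1:] == 2))
        broken = cg[rng.random(cg.size) < cfg.cpg_depletion]
        arr[broken + 1] = rng.choice([0, 3], size=broken.size)
        codes[chrom] = arr

    def genome_str() -> dict[str, str]:
        return {
            c: _CODE_TO_BASE[arr.astype(np.intp)].tobytes().decode("ascii")
            for c, arr in codes.items()
        }

    # --- promoter sequence structure: CpG boost + planted motifs ----------
    pwms = default_motif_library()
    promoter_of = {
        l.transcript.id: tss_proximal_region(
            l.transcript.chrom, l.true_tss, l.transcript.strand
        )
        for l in loci
    }
    for locus in loci:
        win = promoter_of[locus.transcript.id]
        arr = codes[win.chrom]
        n_cg = int(cfg.promoter_cpg_rate * win.length)
        starts = rng.integers(win.start, win.end - 2, size=n_cg)
        arr[starts] = 1
        arr[starts + 1] = 2
        # plant motif instances in the core promoter
        chosen = rng.choice(len(pwms), size=cfg.motifs_per_promoter, replace=False)
        tss = locus.true_tss
        sign = 1 if locus.transcript.strand == "+" else -1
        for m in chosen:
            pwm = pwms[m]
            inst = np.array(
                [rng.choice(4, p=pwm.matrix[:, j]) for j in range(pwm.width)],
                dtype=np.int8,
            )
            if rng.random() < 0.5:
                inst = _COMP_CODE[inst.astype(np.intp)][::-1]
            offset = int(rng.integers(-600, 101))
            pos = tss + sign * offset
            pos = min(max(pos, 0), arr.size - pwm.width)
            arr[pos : pos + pwm.width] = inst

    # --- open reading frames ----------------------------------------------
    gstr = genome_str()
    stops = {"TAA", "TAG", "TGA"}
    for locus in loci:
        tx = locus.transcript
        if locus.role == "coding":
            codon_pool = [
                a + b + c
                for a in BASES for b in BASES for c in BASES
                if a + b + c not in stops and a + b + c != "ATG"
            ]
            body = "".join(rng.choice(codon_pool) for _ in range(130))
            _write_transcript_seq(codes, tx, 100, "ATG" + body + "TAA")
        else:
            _deplete_transcript_atg(codes, tx, gstr)
    gstr = genome_str()
    for locus in loci:  # safety: break any ORF reintroduced by planting
        if locus.role == "coding":
            continue
        tx = locus.transcript
        length, start = longest_orf(tx.spliced_sequence(gstr))
        while length >= 300 and start is not None:
            _mutate_transcript_base(codes, tx, start + 2, "C")
            gstr[tx.chrom] = _CODE_TO_BASE[
                codes[tx.chrom].astype(np.intp)
            ].tobytes().decode("ascii")
            length, start = longest_orf(tx.spliced_sequence(gstr))
    genome = genome_str()

    # --- CAGE peaks and signal tracks --------------------------------------
    cage_peaks: list[GenomeInterval] = []
    summit_of: dict[str, int] = {}
    for locus in loci:
        jitter = int(rng.integers(-cfg.cage_jitter, cfg.cage_jitter + 1))
        summit = locus.true_tss + jitter
        summit_of[locus.transcript.id] = summit
        cage_peaks.append(
            GenomeInterval(
                locus.transcript.chrom,
                summit - cfg.cage_halfwidth,
                summit + cfg.cage_halfwidth,
                locus.transcript.strand,
                f"cage_{locus.transcript.id}",
            )
        )

    def bump(dense: np.ndarray, center: int, height: float, decay: int) -> None:
        half = 5 * decay
        lo, hi = max(0, center - half), min(dense.size, center + half)
        x = np.arange(lo, hi) - center
        dense[lo:hi] += height * np.exp(-np.abs(x) / decay)

    mark_height = {
        "H3K4me3": 1.0, "H3K9ac": 0.8, "H3K27ac": 0.7, "PolII": 0.9, "DHS": 0.9,
    }
    chromatin: dict[str, SignalTrack] = {}
    for mark in CHROMATIN_MARKS:
        dense = {
            c: rng.poisson(cfg.signal_noise_rate, size=n).astype(np.float64)
            for c, n in chrom_lens.items()
        }
        for locus in loci:
            height = cfg.signal_peak_height * mark_height[mark]
            if locus.role == "lincRNA":
                height *= cfg.linc_signal_scale
            bump(dense[locus.transcript.chrom], locus.true_tss, height, cfg.signal_decay_bp)
        chromatin[mark] = SignalTrack.from_dense(dense)

    cage_dense = {
        c: rng.poisson(cfg.cage_noise_rate, size=n).astype(np.float64)
        for c, n in chrom_lens.items()
    }
    for locus in loci:
        height = cfg.cage_peak_height
        if locus.role == "lincRNA":
            height *= cfg.linc_signal_scale
        bump(
            cage_dense[locus.transcript.chrom],
            summit_of[locus.transcript.id],
            height,
            cfg.cage_decay_bp,
        )
    cage_track = SignalTrack.from_dense(cage_dense)

    # --- CGI and repeat annotations ----------------------------------------
    cgi = [
        GenomeInterval(
            l.transcript.chrom,
            max(0, l.true_tss - cfg.cgi_half),
            l.true_tss + cfg.cgi_half,
            ".",
            f"cgi_{l.transcript.id}",
        )
        for l in loci
    ]
    n_bg_cgi = len(loci) // 3
    tss_by_chrom: dict[str, list[int]] = {}
    for l in loci:
        tss_by_chrom.setdefault(l.transcript.chrom, []).append(l.true_tss)
    placed = 0
    attempts = 0
    while placed < n_bg_cgi and attempts < 50 * n_bg_cgi:
        attempts += 1
        chrom = rng.choice(list(chrom_lens))
        length = int(rng.integers(300, 800))
        start = int(rng.integers(0, chrom_lens[chrom] - length))
        if any(abs(start - t) < 3000 for t in tss_by_chrom[chrom]):
            continue
        cgi.append(GenomeInterval(chrom, start, start + length, ".", f"bg_cgi_{placed}"))
        placed += 1

    repeats: list[GenomeInterval] = []
    for chrom, length in chrom_lens.items():
        covered = 0
        target = cfg.repeat_fraction * length
        guard = 0
        while covered < target and guard < 100000:
            guard += 1
            rlen = int(rng.integers(*cfg.repeat_len))
            start = int(rng.integers(0, length - rlen))
            if any(
                start < t + cfg.repeat_tss_exclusion and start + rlen > t - cfg.repeat_tss_exclusion
                for t in tss_by_chrom[chrom]
            ):
                continue
            repeats.append(
                GenomeInterval(chrom, start, start + rlen, ".", f"rep_{len(repeats)}")
            )
            covered += rlen

    # --- assembled transcripts (5' truncated copies) ------------------------
    lo_tr, hi_tr = cfg.truncation_range
    assembled: list[TranscriptModel] = []
    truncations: dict[str, int] = {}
    for locus in loci:
        tx = locus.transcript
        delta = int(rng.integers(lo_tr, hi_tr + 1)) if hi_tr > 0 else 0
        first = tx.exons[0] if tx.strand == "+" else tx.exons[-1]
        delta = min(delta, first.length - 150)
        delta = max(delta, 0)
        exons = list(tx.exons)
        if tx.strand == "+":
            exons[0] = GenomeInterval(
                first.chrom, first.start + delta, first.end, tx.strand
            )
        else:
            exons[-1] = GenomeInterval(
                first.chrom, first.start, first.end - delta, tx.strand
            )
        assembled.append(
            TranscriptModel(
                id=tx.id, chrom=tx.chrom, strand=tx.strand, exons=exons,
                gene_id=tx.gene_id, biotype=tx.biotype,
            )
        )
        truncations[tx.id] = delta

    # --- expression and coding-potential scores -----------------------------
    samples = [f"esc_{j+1:02d}" for j in range(cfg.n_samples)]
    rows = {}
    for locus in loci:
        mu, sigma = cfg.fpkm_coding if locus.role == "coding" else cfg.fpkm_linc
        base = float(rng.lognormal(mu, sigma))
        rows[locus.transcript.id] = base * rng.lognormal(
            0.0, cfg.sample_noise_sigma, size=cfg.n_samples
        )
    expression = ExpressionTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    )
    coding_scores = {
        l.transcript.id: float(
            rng.uniform(0.55, 0.95) if l.role == "coding" else rng.uniform(0.01, 0.35)
        )
        for l in loci
    }

    known = [l.transcript for l in loci if l.known]
    return SyntheticWorld(
        config=cfg,
        genome=genome,
        true_loci=loci,
        known=known,
        assembled=assembled,
        cage_peaks=cage_peaks,
        cage_track=cage_track,
        chromatin=chromatin,
        cgi=cgi,
        repeats=repeats,
        expression=expression,
        coding_scores=coding_scores,
        truncations=truncations,
        pwms=pwms,
    )


# ---------------------------------------------------------------------------
# Co-expression worlds for guilt-by-association annotation


@dataclass
class CoexpressionWorld:
    coding: ExpressionTable
    linc: pd.Series
    gene_sets: GeneSetCollection
    planted_set: str | None


def simulate_coexpression(
    n_genes: int = 300,
    n_sets: int = 50,
    set_size: tuple[int, int] = (10, 30),
    n_samples: int = 20,
    planted: bool = False,
    effect: float = 1.5,
    seed: int = 0,
) -> CoexpressionWorld:
    """Expression matrix + GO-style gene sets, optionally with one planted
    lincRNA-pathway association (a shared latent factor in log-expression)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    log_expr = rng.normal(2.0, 1.0, size=(n_genes, 1)) + rng.normal(
        0.0, 1.0, size=(n_genes, n_samples)
    )
    linc_log = rng.normal(0.5, 1.0, size=n_samples)
    sets = {}
    for s in range(n_sets):
        size = int(rng.integers(*set_size))
        members = rng.choice(n_genes, size=size, replace=False)
        sets[f"GO:{s:04d}"] = frozenset(genes[i] for i in members)
    planted_set = None
    if planted:
        planted_set = "GO:0000"
        factor = rng.normal(0.0, 1.0, size=n_samples)
        for g in sets[planted_set]:
            log_expr[genes.index(g)] += effect * factor
        linc_log = linc_log + effect * factor
    samples = [f"s{j:02d}" for j in range(n_samples)]
    coding = ExpressionTable(
        pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    )
    linc = pd.Series(np.exp(linc_log), index=samples, name="LINC_QUERY")
    return CoexpressionWorld(coding, linc, GeneSetCollection(sets), planted_set)


# ---------------------------------------------------------------------------
# Export / import


def export_world(world: SyntheticWorld, outdir) -> dict[str, Path]:
    """Write the world to standard formats; re-reading reproduces the truth."""
    from . import io as lio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "known": outdir / "known.gtf",
        "truth": outdir / "truth.gtf",
        "assembled": outdir / "assembled.gtf",
        "cage_peaks": outdir / "cage_peaks.bed",
        "cgi": outdir / "cgi.bed",
        "repeats": outdir / "repeats.bed",
        "expression": outdir / "expression.tsv",
        "scores": outdir / "coding_scores.tsv",
        "truth_table": outdir / "truth.tsv",
        "motifs": outdir / "motifs.meme",
    }
    lio.write_fasta(world.genome, paths["genome"])
    lio.write_gtf(world.known, paths["known"])
    lio.write_gtf([l.transcript for l in world.true_loci], paths["truth"])
    lio.write_gtf(world.assembled, paths["assembled"])
    lio.write_bed(world.cage_peaks, paths["cage_peaks"])
    lio.write_bed(world.cgi, paths["cgi"])
    lio.write_bed(world.repeats, paths["repeats"])
    lio.write_expression(world.expression, paths["expression"])
    lio.write_scores(world.coding_scores, paths["scores"])
    write_meme(world.pwms, paths["motifs"])
    pd.DataFrame(
        [
            {
                "id": l.transcript.id,
                "role": l.role,
                "known": l.known,
                "true_tss": l.true_tss,
                "strand": l.transcript.strand,
                "truncation": world.truncations.get(l.transcript.id, 0),
            }
            for l in world.true_loci
        ]
    ).to_csv(paths["truth_table"], sep="\t", index=False)
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    lio.write_bedgraph(world.cage_track, tracks_dir / "CAGE.bedGraph")
    paths["cage_track"] = tracks_dir / "CAGE.bedGraph"
    for mark, track in world.chromatin.items():
        p = tracks_dir / f"{mark}.bedGraph"
        lio.write_bedgraph(track, p)
        paths[mark] = p
    return paths
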