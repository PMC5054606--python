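"""End-to-end orchestration: load a data directory, run every stage, log a manifest.

Stages run in order: candidate filtering -> training-set construction and
CV -> genome scan -> 5'-end correction -> (optional) guilt-by-association
annotation.  Every stage writes its intermediates in documented text
formats (GTF/BED/TSV/JSON) so any stage is independently inspectable, and
the run manifest (config snapshot, input checksums, per-stage counts,
seed, version) fully determines a rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, io as lio
from .core import (
    ExpressionTable,
    GenomeInterval,
    PipelineConfig,
    SignalTrack,
    TranscriptModel,
)
from .correction import correct_all, evaluate_correction
from .filters import run_filters
from .gsea import annotate_lincs
from .seqfeatures import Pwm, read_meme
from .simulate import CHROMATIN_MARKS
from .tss_model import (
    FeatureInputs,
    build_training_set,
    genome_scan,
    train_and_cv,
)


@dataclass
class WorldData:
    """In-memory view of an exported data directory."""

    genome: dict[str, str]
    known: list[TranscriptModel]
    assembled: list[TranscriptModel]
    cage_peaks: list[GenomeInterval]
    cage_track: SignalTrack
    chromatin: dict[str, SignalTrack]
    cgi: list[GenomeInterval]
    repeats: list[GenomeInterval]
    expression: ExpressionTable
    coding_scores: dict[str, float]
    pwms: list[Pwm]


def load_world(directory) -> WorldData:
    d = Path(directory)
    chromatin = {}
    for mark in CHROMATIN_MARKS:
        p = d / "tracks" / f"{mark}.bedGraph"
        if p.exists():
            chromatin[mark] = lio.read_bedgraph(p)
    return WorldData(
        genome=lio.read_fasta(d / "genome.fa"),
        known=lio.read_gtf(d / "known.gtf"),
        assembled=lio.read_gtf(d / "assembled.gtf"),
        cage_peaks=lio.read_bed(d / "cage_peaks.bed"),
        cage_track=lio.read_bedgraph(d / "tracks" / "CAGE.bedGraph"),
        chromatin=chromatin,
        cgi=lio.read_bed(d / "cgi.bed"),
        repeats=lio.read_bed(d / "repeats.bed"),
        expression=lio.read_expression(d / "expression.tsv"),
        coding_scores=lio.read_scores(d / "coding_scores.tsv"),
        pwms=read_meme(d / "motifs.meme"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def input_checksums(directory) -> dict[str, str]:
    d = Path(directory)
    return {
        str(p.relative_to(d)): _sha256(p)
        for p in sorted(d.rglob("*"))
        if p.is_file()
    }


def run_pipeline(
    world_dir,
    outdir,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    gmt: Mapping | None = None,
) -> dict:
    """Run every stage on an exported data directory; returns the manifest."""
    cfg = cfg or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world = load_world(world_dir)
    inputs = FeatureInputs(
        world.genome, world.chromatin, world.cage_track,
        world.cgi, world.repeats, world.pwms,
    )
    stages = []

    # stage 1: candidate filter
    putative, report = run_filters(
        world.assembled, world.known, world.cage_peaks, world.expression,
        world.coding_scores, world.genome, cfg,
    )
    lio.write_gtf(putative, out / "putative_lincRNAs.gtf")
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    stages.append(
        {"stage": "filter", "n_in": report.n_input, "n_out": len(putative)}
    )

    # stage 2: training set + cross-validated model
    known_lincs = [tx for tx in world.known if (tx.biotype or "") == "lincRNA"]
    ts = build_training_set(
        known_lincs, world.known, inputs, expression=world.expression,
        cfg=cfg, seed=seed,
    )
    cv, model = train_and_cv(ts.features, ts.labels, cfg=cfg, seed=seed)
    with open(out / "cv_report.json", "w") as fh:
        json.dump(
            {**cv.summary(), "n_pos": cv.n_pos, "n_neg": cv.n_neg},
            fh, indent=2, sort_keys=True,
        )
    cv.roc_curve.to_csv(out / "roc_curve.tsv", sep="\t", index=False)
    cv.prc_curve.to_csv(out / "prc_curve.tsv", sep="\t", index=False)
    stages.append({"stage": "train", "n_in": ts.n_pos + ts.n_neg, "n_out": 1})

    # stage 3: genome scan
    predicted = genome_scan(model, inputs, world.known, cfg)
    lio.write_bed(predicted.regions, out / "predicted_regions.bed", predicted.scores)
    lio.write_bed(predicted.merged(), out / "predicted_regions_merged.bed")
    stages.append({"stage": "scan", "n_in": len(predicted), "n_out": len(predicted)})

    # stage 4: 5' correction
    corrected, records = correct_all(putative, predicted, cfg)
    lio.write_gtf(corrected, out / "corrected_lincRNAs.gtf")
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "strand": r.strand,
                "original_tss": r.original_tss,
                "corrected_tss": r.corrected_tss,
                "shift": r.shift,
                "flagged": r.flagged,
            }
            for r in records
        ]
    ).to_csv(out / "correction_records.tsv", sep="\t", index=False)
    evaluation = evaluate_correction(
        putative, corrected, world.cage_track, world.cage_peaks,
        tracks=world.chromatin, cfg=cfg,
    )
    with open(out / "correction_summary.json", "w") as fh:
        json.dump(evaluation.summary(), fh, indent=2, sort_keys=True)
    for name, prof in evaluation.profiles_after.items():
        prof.to_frame().to_csv(
            out / f"profile_{name}_after.tsv", sep="\t", index=False
        )
        evaluation.profiles_before[name].to_frame().to_csv(
            out / f"profile_{name}_before.tsv", sep="\t", index=False
        )
    n_corrected = sum(r.shift > 0 for r in records)
    stages.append({"stage": "correct", "n_in": len(putative), "n_out": n_corrected})

    # stage 5 (optional): guilt-by-association annotation
    if gmt is not None:
        coding_ids = [
            tx.id
            for tx in world.known
            if (tx.biotype or "") == "protein_coding" and tx.id in world.expression
        ]
        coding_expr = ExpressionTable(world.expression.frame.loc[coding_ids])
        linc_expr = world.expression.frame.loc[
            [tx.id for tx in corrected if tx.id in world.expression]
        ]
        annotations = annotate_lincs(
            linc_expr, coding_expr, {"BP": gmt},
            min_fpkm=cfg.min_fpkm_known, n_perm=cfg.n_perm, seed=seed,
            alpha=cfg.fwer_alpha,
        )
        annotations.to_csv(out / "go_annotations.tsv", sep="\t", index=False)
        stages.append(
            {
                "stage": "annotate",
                "n_in": len(linc_expr),
                "n_out": int(annotations["significant"].sum()) if len(annotations) else 0,
            }
        )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "inputs": input_checksums(world_dir),
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
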