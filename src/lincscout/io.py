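"""Readers and writers for the standard formats the pipeline touches.

GTF (GFF2 attribute dialect), BED6, bedGraph, FASTA, GMT gene sets and
TSV expression / score tables.  GTF is the only 1-based inclusive format;
everything is converted to 0-based half-open on read and back on write.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ExpressionTable,
    GenomeInterval,
    GeneSetCollection,
    SignalTrack,
    TranscriptModel,
)


class ParseError(ValueError):
    """Malformed record, carrying the file line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF into TranscriptModels (exon features only).

    1-based inclusive GTF coordinates become 0-based half-open; exons are
    grouped by ``transcript_id`` and sorted.  Unsorted input is tolerated.
    """
    exons: dict[str, list[GenomeInterval]] = {}
    meta: dict[str, tuple[str, str, str | None, str | None]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end_i < start_i:
                raise ParseError(path, lineno, f"end < start ({end_i} < {start_i})")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {strand!r}")
            attrd = _parse_gtf_attributes(attrs)
            tx_id = attrd.get("transcript_id")
            if not tx_id:
                raise ParseError(path, lineno, "missing transcript_id attribute")
            if tx_id not in meta:
                meta[tx_id] = (
                    chrom,
                    strand,
                    attrd.get("gene_id"),
                    attrd.get("biotype") or attrd.get("transcript_biotype"),
                )
                order.append(tx_id)
            exons.setdefault(tx_id, []).append(
                GenomeInterval(chrom, start_i - 1, end_i, strand)
            )
    out = []
    for tx_id in order:
        chrom, strand, gene_id, biotype = meta[tx_id]
        out.append(
            TranscriptModel(
                id=tx_id, chrom=chrom, strand=strand, exons=exons[tx_id],
                gene_id=gene_id, biotype=biotype,
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            gene = tx.gene_id or tx.id
            attrs = f'gene_id "{gene}"; transcript_id "{tx.id}";'
            if tx.biotype:
                attrs += f' biotype "{tx.biotype}";'
            for i, exon in enumerate(tx.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            tx.chrom, "lincscout", "exon",
                            str(exon.start + 1), str(exon.end),
                            ".", tx.strand, ".",
                            attrs + f' exon_number "{i}";',
                        ]
                    )
                    + "\n"
                )


def read_bed(path) -> list[GenomeInterval]:
    """BED (3-6 columns), 0-based half-open, strand defaults to '.'."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomeInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return out


def write_bed(
    intervals: Iterable[GenomeInterval], path, scores: Sequence[float] | None = None
) -> None:
    intervals = list(intervals)
    if scores is None:
        scores = [0.0] * len(intervals)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path) -> SignalTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 fields, got {len(fields)}")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError:
                raise ParseError(path, lineno, "malformed bedGraph row") from None
    try:
        return SignalTrack.from_records(
            (c, s, e, v) for c, s, e, v in records if v != 0
        )
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.12g}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT row needs name, description, genes")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(path, lineno, f"gene set {name!r} is empty")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sorted(collection.items()):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_expression(path) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(frame)


def write_expression(table: ExpressionTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="id")


def read_scores(path) -> dict[str, float]:
    """Two-column TSV of id -> coding-potential score (header row required)."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected id and score columns")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(float)))


def write_scores(scores: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"id": list(scores), "coding_score": [scores[k] for k in scores]}
    ).to_csv(path, sep="\t", index=False)
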