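"""Readers and writers for the pipeline's on-disk dialects.

All formats are plain text: long-form expression TSV, an annotation TSV plus a
protein FASTA keyed by transcript id, a differential-calls TSV, and a wide
intensity TSV with one ``condition_replicate`` column per sample (the shape an
OpenSWATH peptide-level export reduces to).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptide_layer import IntensityMatrix
from .synthetic_data import GroundTruth, SyntheticDataset
from .transcript_layer import (
    CONDITIONS,
    Biotype,
    DifferentialCalls,
    ExpressionTable,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the file (and line where known)."""


# -- expression -------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    try:
        return ExpressionTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


# -- annotation -------------------------------------------------------------


def read_annotation(annotation_tsv: str | Path, protein_fasta: str | Path) -> list[TranscriptRecord]:
    """Annotation table (transcript_id, gene_id, biotype) plus protein FASTA."""
    ann = pd.read_csv(annotation_tsv, sep="\t")
    required = {"transcript_id", "gene_id", "biotype"}
    if not required <= set(ann.columns):
        raise ParseError(f"{annotation_tsv}: missing columns {sorted(required - set(ann.columns))}")
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    records = []
    for i, row in enumerate(ann.itertuples(index=False), start=2):
        try:
            biotype = Biotype(row.biotype)
            records.append(
                TranscriptRecord(
                    transcript_id=row.transcript_id,
                    gene_id=row.gene_id,
                    biotype=biotype,
                    protein_sequence=proteins.get(row.transcript_id),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{annotation_tsv}: line {i}: {exc}") from exc
    return records


def write_annotation(
    transcripts: Sequence[TranscriptRecord],
    annotation_tsv: str | Path,
    protein_fasta: str | Path,
) -> None:
    pd.DataFrame(
        [(t.transcript_id, t.gene_id, t.biotype.value) for t in transcripts],
        columns=["transcript_id", "gene_id", "biotype"],
    ).to_csv(annotation_tsv, sep="\t", index=False)
    seqs = [
        SeqRecord(Seq(t.protein_sequence), id=t.transcript_id, description="")
        for t in transcripts
        if t.protein_sequence is not None
    ]
    SeqIO.write(seqs, str(protein_fasta), "fasta")


# -- differential calls -----------------------------------------------------


def read_calls_tsv(path: str | Path) -> DifferentialCalls:
    """Calls TSV: entity_id, entity_type {gene, transcript}, call {DTU, DGE, IR, NON_IR}."""
    df = pd.read_csv(path, sep="\t")
    required = {"entity_id", "entity_type", "call"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    sets: dict[tuple[str, str], set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.entity_type), str(row.call).upper())
        if row.entity_type not in ("gene", "transcript"):
            raise ParseError(f"{path}: line {i}: bad entity_type {row.entity_type!r}")
        sets.setdefault(key, set()).add(str(row.entity_id))
    return DifferentialCalls(
        dtu_transcripts=frozenset(sets.get(("transcript", "DTU"), set())),
        dtu_genes=frozenset(sets.get(("gene", "DTU"), set())),
        dge_genes=frozenset(sets.get(("gene", "DGE"), set())),
        ir_genes=frozenset(sets.get(("gene", "IR"), set())),
        non_ir_genes=frozenset(sets.get(("gene", "NON_IR"), set())),
    )


def write_calls_tsv(calls: DifferentialCalls, path: str | Path) -> None:
    rows = (
        [(t, "transcript", "DTU") for t in sorted(calls.dtu_transcripts)]
        + [(g, "gene", "DTU") for g in sorted(calls.dtu_genes)]
        + [(g, "gene", "DGE") for g in sorted(calls.dge_genes)]
        + [(g, "gene", "IR") for g in sorted(calls.ir_genes)]
        + [(g, "gene", "NON_IR") for g in sorted(calls.non_ir_genes)]
    )
    pd.DataFrame(rows, columns=["entity_id", "entity_type", "call"]).to_csv(
        path, sep="\t", index=False
    )


# -- intensities ------------------------------------------------------------


def read_intensity_tsv(path: str | Path, normalized: bool = False) -> IntensityMatrix:
    """Wide intensity TSV: first column peptide_sequence, then one
    ``condition_replicate`` column per sample (e.g. ``control_1``)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "peptide_sequence":
        raise ParseError(f"{path}: first column must be 'peptide_sequence'")
    df = df.set_index("peptide_sequence")
    tuples = []
    for col in df.columns:
        cond, _, rep = str(col).rpartition("_")
        if cond not in CONDITIONS or not rep.isdigit():
            raise ParseError(f"{path}: bad sample column {col!r}")
        tuples.append((cond, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(tuples, names=["condition", "replicate"])
    try:
        return IntensityMatrix(df, normalized=normalized)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_intensity_tsv(m: IntensityMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.columns = [f"{cond}_{rep}" for cond, rep in df.columns]
    df.index.name = "peptide_sequence"
    df.to_csv(path, sep="\t", float_format="%.6g")


# -- ground truth & whole datasets ------------------------------------------


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth TSV (never read by the pipeline)."""
    rows = [("gene_label", g, "", lab) for g, lab in sorted(truth.gene_labels.items())]
    rows += [("dtu_transcript", t, "", "1") for t in sorted(truth.dtu_transcripts)]
    rows += [
        ("transcript_expected", tid, cond, f"{v:.6g}")
        for (tid, cond), v in sorted(truth.transcript_expected.items())
    ]
    rows += [
        ("peptide_expected", pep, cond, f"{v:.6g}")
        for (pep, cond), v in sorted(truth.peptide_expected.items())
    ]
    pd.DataFrame(rows, columns=["record", "id", "condition", "value"]).to_csv(
        path, sep="\t", index=False
    )


DATASET_FILES = {
    "expression": "expression.tsv",
    "annotation": "annotation.tsv",
    "proteins": "proteins.fasta",
    "calls": "calls.tsv",
    "intensities": "intensities.tsv",
    "truth": "ground_truth.tsv",
}


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input (+ ground truth) under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in DATASET_FILES.items()}
    write_expression_tsv(ds.expression, paths["expression"])
    write_annotation(ds.transcripts, paths["annotation"], paths["proteins"])
    write_calls_tsv(ds.calls, paths["calls"])
    write_intensity_tsv(ds.intensities, paths["intensities"])
    write_ground_truth(ds.truth, paths["truth"])
    return paths
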