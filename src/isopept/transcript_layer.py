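"""Transcriptome side of the integration.

Expression ingestion, per-gene relative isoform abundance, major-transcript and
switch-event determination, transcript/gene fold changes, and a heuristic
stand-in classifier for upstream differential calls (DTU / DGE / IR).

Expression values are FPKM-like: non-negative, with an expressed-gene floor of
1 FPKM applied before any analysis.  Two conditions only ("control" vs
"depleted", the spliceosome-perturbation design), each with >= 2 biological
replicates; all per-condition summaries are medians across replicates.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
DEPLETED = "depleted"
CONDITIONS = (CONTROL, DEPLETED)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default expressed-gene floor, FPKM-equivalent units
EXPRESSION_FLOOR = 1.0


class UnknownGeneError(KeyError):
    """Lookup of a gene_id absent from the expression table."""


class UndefinedMajorError(ValueError):
    """Major transcript requested for a gene with zero expression in a condition."""


class Biotype(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    RETAINED_INTRON = "retained_intron"
    NMD = "nmd"
    OTHER = "other"

    @property
    def is_translated(self) -> bool:
        # NMD-biotype transcripts carry an ORF and are kept in the peptide
        # search space; retained-intron isoforms are treated as untranslated.
        return self in (Biotype.PROTEIN_CODING, Biotype.NMD)


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated isoform: gene link, biotype and (if translated) protein."""

    transcript_id: str
    gene_id: str
    biotype: Biotype = Biotype.PROTEIN_CODING
    protein_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.protein_sequence is not None:
            bad = set(self.protein_sequence) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"{self.transcript_id}: non-standard residues {sorted(bad)}"
                )
        if self.biotype.is_translated and self.protein_sequence is None:
            raise ValueError(f"{self.transcript_id}: translated biotype without protein")
        if not self.biotype.is_translated and self.protein_sequence is not None:
            raise ValueError(f"{self.transcript_id}: untranslated biotype with protein")


@dataclass(frozen=True)
class DifferentialCalls:
    """Upstream differential calls (the stand-in for MMDIFF/DEXSeq output)."""

    dtu_transcripts: frozenset[str] = frozenset()
    dtu_genes: frozenset[str] = frozenset()
    dge_genes: frozenset[str] = frozenset()
    ir_genes: frozenset[str] = frozenset()
    non_ir_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ir_genes & self.non_ir_genes:
            raise ValueError("ir_genes and non_ir_genes overlap")


@dataclass
class GeneIsoformProfile:
    """Per-gene isoform usage: relative abundances and condition majors.

    ``major_transcript[cond]`` is None when the gene has zero summarised
    expression in that condition (the major is then undefined).
    """

    gene_id: str
    relative_abundance: dict[tuple[str, str], float]
    major_transcript: dict[str, str | None]
    is_switch: bool


class ExpressionTable:
    """Transcript x (condition, replicate) expression values, long form.

    Wraps a DataFrame with columns ``transcript_id, gene_id, condition,
    replicate, expression``.  Every transcript of the annotation is expected to
    have rows; absent transcripts are treated as zero by the caller.
    """

    COLUMNS = ("transcript_id", "gene_id", "condition", "replicate", "expression")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"expression table missing columns {sorted(missing)}")
        data = data.loc[:, list(self.COLUMNS)].copy()
        if (data["expression"] < 0).any():
            raise ValueError("negative expression values")
        conds = set(data["condition"].unique())
        if conds != set(CONDITIONS):
            raise ValueError(f"conditions must be exactly {CONDITIONS}, got {sorted(conds)}")
        for cond in CONDITIONS:
            n_rep = data.loc[data["condition"] == cond, "replicate"].nunique()
            if n_rep < 2:
                raise ValueError(f"condition {cond!r} has {n_rep} replicate(s); need >= 2")
        gene_map = data.groupby("transcript_id")["gene_id"].nunique()
        if (gene_map > 1).any():
            raise ValueError("a transcript maps to more than one gene")
        self.data = data

    # -- cached views -------------------------------------------------------

    @cached_property
    def condition_medians(self) -> pd.DataFrame:
        """Per-transcript median expression across replicates; columns = conditions."""
        med = (
            self.data.pivot_table(
                index="transcript_id", columns="condition", values="expression",
                aggfunc="median", fill_value=0.0,
            )
            .reindex(columns=list(CONDITIONS), fill_value=0.0)
        )
        med.columns.name = None
        return med

    @cached_property
    def gene_of(self) -> pd.Series:
        return self.data.drop_duplicates("transcript_id").set_index("transcript_id")["gene_id"]

    @cached_property
    def transcripts_of_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tid, gid in self.gene_of.items():
            out.setdefault(gid, []).append(tid)
        for tids in out.values():
            tids.sort()
        return out

    @cached_property
    def gene_condition_medians(self) -> pd.DataFrame:
        """Gene-level median across replicates of per-replicate transcript sums."""
        totals = (
            self.data.groupby(["gene_id", "condition", "replicate"])["expression"]
            .sum()
            .groupby(["gene_id", "condition"])
            .median()
            .unstack("condition", fill_value=0.0)
            .reindex(columns=list(CONDITIONS), fill_value=0.0)
        )
        totals.columns.name = None
        return totals

    @property
    def genes(self) -> list[str]:
        return sorted(self.transcripts_of_gene)

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.gene_of.index)

    def replicates(self, condition: str) -> list:
        return sorted(self.data.loc[self.data["condition"] == condition, "replicate"].unique())

    # -- filters ------------------------------------------------------------

    def filter_expressed(self, threshold: float = EXPRESSION_FLOOR) -> "ExpressionTable":
        """Keep genes whose summarised expression reaches ``threshold`` in
        at least one condition (the expressed-gene floor)."""
        totals = self.gene_condition_medians
        keep = totals.index[totals.max(axis=1) >= threshold]
        kept = self.data[self.data["gene_id"].isin(set(keep))]
        logger.info(
            "expressed-gene filter (>= %g): kept %d / %d genes",
            threshold, len(keep), totals.shape[0],
        )
        return ExpressionTable(kept)


# -- operations -------------------------------------------------------------


def _gene_medians(expr: ExpressionTable, gene_id: str) -> pd.DataFrame:
    if gene_id not in expr.transcripts_of_gene:
        raise UnknownGeneError(gene_id)
    tids = expr.transcripts_of_gene[gene_id]
    return expr.condition_medians.reindex(tids, fill_value=0.0)


def compute_relative_abundance(
    expr: ExpressionTable, gene_id: str
) -> dict[tuple[str, str], float]:
    """Per-condition relative isoform abundance of one gene.

    Fractions are per-transcript condition medians divided by the gene total;
    NaN (undefined) for a condition in which the gene total is zero.
    """
    med = _gene_medians(expr, gene_id)
    out: dict[tuple[str, str], float] = {}
    for cond in CONDITIONS:
        total = med[cond].sum()
        for tid in med.index:
            out[(tid, cond)] = med.at[tid, cond] / total if total > 0 else float("nan")
    return out


def find_major_transcript(expr: ExpressionTable, gene_id: str, condition: str) -> str:
    """Most highly expressed isoform of a gene in one condition (median across
    replicates); ties broken towards the lexicographically smaller id."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    med = _gene_medians(expr, gene_id)[condition]
    if med.sum() <= 0:
        raise UndefinedMajorError(f"{gene_id}: zero expression in {condition!r}")
    best = med.max()
    winners = sorted(med.index[med == best])
    if len(winners) > 1:
        logger.debug("major-transcript tie in %s/%s: %s", gene_id, condition, winners)
    return winners[0]


def build_gene_profiles(expr: ExpressionTable) -> dict[str, GeneIsoformProfile]:
    """Relative abundances, condition majors and switch flags for every gene."""
    profiles: dict[str, GeneIsoformProfile] = {}
    for gene_id in expr.genes:
        rel = compute_relative_abundance(expr, gene_id)
        majors: dict[str, str | None] = {}
        for cond in CONDITIONS:
            try:
                majors[cond] = find_major_transcript(expr, gene_id, cond)
            except UndefinedMajorError:
                majors[cond] = None
        defined = all(majors[c] is not None for c in CONDITIONS)
        is_switch = defined and majors[CONTROL] != majors[DEPLETED]
        profiles[gene_id] = GeneIsoformProfile(gene_id, rel, majors, is_switch)
    return profiles


def detect_switch_events(
    expr: ExpressionTable,
    calls: DifferentialCalls,
    profiles: Mapping[str, GeneIsoformProfile] | None = None,
) -> set[str]:
    """DTU genes whose major transcript differs between conditions.

    Genes with an undefined major in either condition are skipped (logged),
    not errors.
    """
    if profiles is None:
        profiles = build_gene_profiles(expr)
    out: set[str] = set()
    for gene_id, prof in profiles.items():
        if any(prof.major_transcript[c] is None for c in CONDITIONS):
            logger.debug("switch detection: %s skipped (undefined major)", gene_id)
            continue
        if prof.is_switch and gene_id in calls.dtu_genes:
            out.add(gene_id)
    return out


def transcript_fold_change(
    expr: ExpressionTable, transcript_id: str, pseudocount: float = 0.0
) -> float:
    """log2(median depleted / median control) for one transcript."""
    if transcript_id not in expr.condition_medians.index:
        raise KeyError(transcript_id)
    med = expr.condition_medians.loc[transcript_id]
    num = med[DEPLETED] + pseudocount
    den = med[CONTROL] + pseudocount
    if num == 0 and den == 0:
        return 0.0
    return float(np.log2(num / den))


def gene_fold_change(expr: ExpressionTable, gene_id: str, pseudocount: float = 0.0) -> float:
    """log2 fold change of summarised gene-level expression (sum of isoforms
    per replicate, median across replicates)."""
    if gene_id not in expr.gene_condition_medians.index:
        raise UnknownGeneError(gene_id)
    med = expr.gene_condition_medians.loc[gene_id]
    num = med[DEPLETED] + pseudocount
    den = med[CONTROL] + pseudocount
    if num == 0 and den == 0:
        return 0.0
    return float(np.log2(num / den))


def classify_differential_synthetic(
    expr: ExpressionTable,
    transcripts: Iterable[TranscriptRecord],
    dge_threshold: float = 1.0,
    dtu_threshold: float = 0.1,
    ir_threshold: float = 0.1,
    pseudocount: float = 0.5,
) -> DifferentialCalls:
    """Threshold-based stand-in for upstream differential testing.

    This is a deliberately simple heuristic classifier, not a reimplementation
    of the Bayesian/exon-level tools that produce such calls on real data:

    * DGE: gene-level |log2 FC| >= ``dge_threshold``;
    * DTU: some transcript's relative abundance changes by >= ``dtu_threshold``
      between conditions (those transcripts are the DTU transcripts);
    * IR: a retained-intron-biotype isoform's relative abundance increases by
      >= ``ir_threshold``.
    """
    biotype_of = {t.transcript_id: t.biotype for t in transcripts}
    dtu_transcripts: set[str] = set()
    dtu_genes: set[str] = set()
    dge_genes: set[str] = set()
    ir_genes: set[str] = set()
    non_ir: set[str] = set()
    for gene_id in expr.genes:
        rel = compute_relative_abundance(expr, gene_id)
        fc = gene_fold_change(expr, gene_id, pseudocount=pseudocount)
        if abs(fc) >= dge_threshold:
            dge_genes.add(gene_id)
        deltas = {}
        for tid in expr.transcripts_of_gene[gene_id]:
            a, b = rel[(tid, CONTROL)], rel[(tid, DEPLETED)]
            if np.isnan(a) or np.isnan(b):
                continue
            deltas[tid] = b - a
        changed = {tid for tid, d in deltas.items() if abs(d) >= dtu_threshold}
        if changed:
            dtu_genes.add(gene_id)
            dtu_transcripts |= changed
        retained_up = any(
            biotype_of.get(tid) == Biotype.RETAINED_INTRON and d >= ir_threshold
            for tid, d in deltas.items()
        )
        if retained_up:
            ir_genes.add(gene_id)
        else:
            non_ir.add(gene_id)
    return DifferentialCalls(
        dtu_transcripts=frozenset(dtu_transcripts),
        dtu_genes=frozenset(dtu_genes),
        dge_genes=frozenset(dge_genes),
        ir_genes=frozenset(ir_genes),
        non_ir_genes=frozenset(non_ir),
    )
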