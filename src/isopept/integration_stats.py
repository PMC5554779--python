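"""Concordance between RNA and protein fold changes.

Aggregates allocated peptide intensities per transcript, correlates RNA and
protein log2 fold changes (Spearman primary, Pearson for comparison), tallies
sign agreement, and runs the intron-retention and differential-gene-expression
analyses (rank-sum, Fisher-exact contingency, coding-fraction comparison).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .assignment import AssignmentResult
from .peptide_layer import (
    IntensityMatrix,
    PeptideRecord,
    PeptideStat,
    _log_ratio,
    peptide_fold_change,
)
from .transcript_layer import (
    CONTROL,
    DEPLETED,
    Biotype,
    DifferentialCalls,
    ExpressionTable,
    TranscriptRecord,
    gene_fold_change,
    transcript_fold_change,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntegrationRow:
    """One scatterplot point: RNA vs protein log2 FC for one target.

    ``agree`` is defined (non-None) only when both fold changes are nonzero;
    rows with a zero on either side are tallied as disagreement.
    """

    target_id: str
    rna_log2fc: float
    protein_log2fc: float
    n_peptides: int
    gene_id: str | None = None

    @property
    def agree(self) -> bool | None:
        if self.rna_log2fc == 0.0 or self.protein_log2fc == 0.0:
            return None
        return (self.rna_log2fc > 0) == (self.protein_log2fc > 0)


@dataclass(frozen=True)
class CorrelationSummary:
    n_transcripts: int
    n_peptides: int
    n_genes: int
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n_agree: int
    n_disagree: int

    @property
    def agreement_pct(self) -> float:
        total = self.n_agree + self.n_disagree
        return 100.0 * self.n_agree / total if total else float("nan")


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 of down-regulated proteins among IR vs non-IR genes."""

    a: int   # down-regulated among IR genes
    n1: int  # IR genes total
    b: int   # down-regulated among non-IR genes
    n2: int  # non-IR genes total
    odds_ratio: float
    p_value: float


# -- per-transcript protein fold changes ------------------------------------


def _matrix_pseudocount(m: IntensityMatrix, pseudocount: float | None) -> float:
    return m.half_min_positive if pseudocount is None else pseudocount


def transcript_protein_fc_sum(
    assignment: AssignmentResult,
    m: IntensityMatrix,
    transcript_id: str,
    pseudocount: float | None = None,
) -> float:
    """Sum allocated peptide intensities per replicate, then log2 of the
    ratio of condition medians of the sums (one FC per transcript)."""
    peps = assignment.peptides_of_transcript(transcript_id)
    if not peps:
        raise KeyError(f"no allocated peptides on {transcript_id}")
    sums = m.values.loc[peps].sum(axis=0)
    ctrl = float(sums.loc[CONTROL].median())
    depl = float(sums.loc[DEPLETED].median())
    return _log_ratio(depl, ctrl, _matrix_pseudocount(m, pseudocount))


def transcript_protein_fc_median(
    assignment: AssignmentResult,
    m: IntensityMatrix,
    transcript_id: str,
    pseudocount: float | None = None,
) -> float:
    """Median over the transcript's allocated peptides of per-peptide FCs."""
    peps = assignment.peptides_of_transcript(transcript_id)
    if not peps:
        raise KeyError(f"no allocated peptides on {transcript_id}")
    fcs = [peptide_fold_change(m, p, pseudocount=pseudocount) for p in peps]
    return float(np.median(fcs))


def build_integration_rows(
    assignment: AssignmentResult,
    expr: ExpressionTable,
    m: IntensityMatrix,
    calls: DifferentialCalls,
    method: str = "sum",
    rna_pseudocount: float = 0.0,
    intensity_pseudocount: float | None = None,
    restrict_to_dtu: bool = True,
) -> list[IntegrationRow]:
    """One row per allocated transcript with peptide evidence.

    ``method`` selects the protein-side aggregation: ``"sum"`` (sum peptides
    per replicate, then median ratio) or ``"median"`` (median of per-peptide
    fold changes).  Transcripts are restricted to the DTU call set by default.
    """
    fc_fn = {"sum": transcript_protein_fc_sum, "median": transcript_protein_fc_median}[method]
    rows: list[IntegrationRow] = []
    detected = set(m.values.index)
    for tid in sorted(assignment.transcripts()):
        if restrict_to_dtu and tid not in calls.dtu_transcripts:
            continue
        peps = [p for p in assignment.peptides_of_transcript(tid) if p in detected]
        if not peps:
            logger.debug("transcript %s: no detected peptides, excluded", tid)
            continue
        sub = AssignmentResult(assignment.strategy, {p: tid for p in peps})
        rows.append(
            IntegrationRow(
                target_id=tid,
                rna_log2fc=transcript_fold_change(expr, tid, pseudocount=rna_pseudocount),
                protein_log2fc=fc_fn(sub, m, tid, pseudocount=intensity_pseudocount),
                n_peptides=len(peps),
                gene_id=str(expr.gene_of.get(tid)),
            )
        )
    return rows


# -- correlation ------------------------------------------------------------


def correlate(rows: Sequence[IntegrationRow]) -> CorrelationSummary:
    """Spearman/Pearson correlation and sign-agreement tallies over rows.

    With fewer than 3 rows the correlations are undefined (NaN) but the
    counts are still reported.
    """
    rna = np.array([r.rna_log2fc for r in rows], dtype=float)
    prot = np.array([r.protein_log2fc for r in rows], dtype=float)
    n_agree = sum(1 for r in rows if r.agree is True)
    n_disagree = len(rows) - n_agree
    if len(rows) >= 3:
        rho, rho_p = stats.spearmanr(rna, prot)
        r, r_p = stats.pearsonr(rna, prot)
    else:
        rho = rho_p = r = r_p = float("nan")
    genes = {r.gene_id for r in rows if r.gene_id is not None}
    return CorrelationSummary(
        n_transcripts=len(rows),
        n_peptides=int(sum(r.n_peptides for r in rows)),
        n_genes=len(genes) if genes else len(rows),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        pearson_r=float(r),
        pearson_p=float(r_p),
        n_agree=n_agree,
        n_disagree=n_disagree,
    )


def agreement_pct(n_agree: int, n_disagree: int) -> float:
    """Percent sign agreement from Y/N tallies."""
    return 100.0 * n_agree / (n_agree + n_disagree)


# -- intron retention -------------------------------------------------------


def gene_protein_fold_changes(
    m: IntensityMatrix,
    peptides: Iterable[PeptideRecord],
    pseudocount: float | None = None,
) -> dict[str, float]:
    """Gene-level protein log2 FC: median over the gene's detected peptides'
    fold changes (multi-gene peptides must be removed beforehand)."""
    detected = set(m.values.index)
    by_gene: dict[str, list[float]] = {}
    for p in peptides:
        if p.sequence not in detected:
            continue
        fc = peptide_fold_change(m, p.sequence, pseudocount=pseudocount)
        by_gene.setdefault(p.gene_id, []).append(fc)
    return {g: float(np.median(v)) for g, v in sorted(by_gene.items())}


def contingency_from_counts(a: int, n1: int, b: int, n2: int) -> ContingencyResult:
    """Odds ratio (cross-product) and two-sided Fisher-exact p for a 2x2
    given as down-regulated/total counts in each group."""
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("inconsistent contingency counts")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    if (table > 0).all():
        odds = (a / (n1 - a)) / (b / (n2 - b))
    else:
        odds = float("nan")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(a, n1, b, n2, float(odds), float(p))


def ir_protein_ratio_test(
    gene_protein_fc: Mapping[str, float], calls: DifferentialCalls
) -> tuple[float, ContingencyResult]:
    """Do intron-retaining genes make less protein?

    Two-sided rank-sum (Mann-Whitney) p comparing gene-level protein log2 FCs
    of IR vs non-IR genes, plus the 2x2 of down-regulated (log2 FC < 0)
    proteins in each group.  Zero fold changes count as not down.
    """
    ir = [fc for g, fc in gene_protein_fc.items() if g in calls.ir_genes]
    non_ir = [fc for g, fc in gene_protein_fc.items() if g in calls.non_ir_genes]
    if not ir or not non_ir:
        raise ValueError("both IR and non-IR groups must be nonempty")
    _, wilcoxon_p = stats.mannwhitneyu(ir, non_ir, alternative="two-sided")
    cont = contingency_from_counts(
        a=sum(1 for fc in ir if fc < 0),
        n1=len(ir),
        b=sum(1 for fc in non_ir if fc < 0),
        n2=len(non_ir),
    )
    return float(wilcoxon_p), cont


@dataclass(frozen=True)
class CodingFractionResult:
    wilcoxon_p: float
    median_up: float       # coding fraction among protein-up genes
    median_down: float     # coding fraction among protein-down genes
    fractions: dict[str, float]


def coding_fraction_analysis(
    expr: ExpressionTable,
    transcripts: Iterable[TranscriptRecord],
    gene_protein_fc: Mapping[str, float],
    calls: DifferentialCalls,
) -> CodingFractionResult | None:
    """Among IR genes, is a low protein-coding transcript fraction linked to
    protein down-regulation?

    The coding fraction of a gene is the summed depleted-condition median
    expression of its protein-coding isoforms over the gene total.  Genes are
    split by the sign of their protein fold change; returns None (with a
    warning) when either group is empty.
    """
    coding = {t.transcript_id for t in transcripts if t.biotype is Biotype.PROTEIN_CODING}
    med = expr.condition_medians[DEPLETED]
    fractions: dict[str, float] = {}
    for gene_id in sorted(calls.ir_genes):
        if gene_id not in expr.transcripts_of_gene or gene_id not in gene_protein_fc:
            continue
        tids = expr.transcripts_of_gene[gene_id]
        total = float(med.reindex(tids, fill_value=0.0).sum())
        if total <= 0:
            continue
        in_coding = [t for t in tids if t in coding]
        fractions[gene_id] = float(med.reindex(in_coding, fill_value=0.0).sum()) / total
    up = [fractions[g] for g in fractions if gene_protein_fc[g] > 0]
    down = [fractions[g] for g in fractions if gene_protein_fc[g] < 0]
    if not up or not down:
        logger.warning("coding-fraction analysis: empty up/down group, skipped")
        return None
    _, p = stats.mannwhitneyu(up, down, alternative="two-sided")
    return CodingFractionResult(
        wilcoxon_p=float(p),
        median_up=float(np.median(up)),
        median_down=float(np.median(down)),
        fractions=fractions,
    )


# -- differential gene expression -------------------------------------------


@dataclass(frozen=True)
class DgeCorrelations:
    all_peptides: CorrelationSummary
    significant_peptides: CorrelationSummary
    non_dge_genes: CorrelationSummary
    gene_summarised: CorrelationSummary


def dge_correlation(
    expr: ExpressionTable,
    calls: DifferentialCalls,
    peptide_stats: Sequence[PeptideStat],
    m: IntensityMatrix,
    peptides: Iterable[PeptideRecord],
    rna_pseudocount: float = 0.5,
) -> DgeCorrelations:
    """Gene-level RNA FC vs peptide-level protein FC over DGE genes.

    Each detected peptide of a DGE gene contributes one point (gene RNA FC,
    peptide FC).  Reported four ways: all peptides; only peptides whose
    Holm-adjusted t-test is significant; peptides of non-DGE genes (contrast);
    and a gene-summarised variant using the median peptide FC per gene.
    """
    stat_of = {s.peptide: s for s in peptide_stats}
    detected = set(m.values.index)
    gene_rna: dict[str, float] = {}

    def rna_fc(gene_id: str) -> float:
        if gene_id not in gene_rna:
            gene_rna[gene_id] = gene_fold_change(expr, gene_id, pseudocount=rna_pseudocount)
        return gene_rna[gene_id]

    rows_all, rows_sig, rows_non = [], [], []
    per_gene: dict[str, list[float]] = {}
    known_genes = set(expr.gene_condition_medians.index)
    for p in sorted(peptides, key=lambda p: p.sequence):
        if p.sequence not in detected or p.gene_id not in known_genes:
            continue
        stat = stat_of.get(p.sequence)
        fc = stat.log2_fc if stat is not None else peptide_fold_change(m, p.sequence)
        row = IntegrationRow(p.sequence, rna_fc(p.gene_id), fc, 1, gene_id=p.gene_id)
        if p.gene_id in calls.dge_genes:
            rows_all.append(row)
            per_gene.setdefault(p.gene_id, []).append(fc)
            if stat is not None and stat.significant:
                rows_sig.append(row)
        else:
            rows_non.append(row)
    rows_gene = [
        IntegrationRow(g, rna_fc(g), float(np.median(v)), len(v), gene_id=g)
        for g, v in sorted(per_gene.items())
    ]
    return DgeCorrelations(
        all_peptides=correlate(rows_all),
        significant_peptides=correlate(rows_sig),
        non_dge_genes=correlate(rows_non),
        gene_summarised=correlate(rows_gene),
    )
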