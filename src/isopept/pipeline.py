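"""End-to-end integration pipeline.

Ties the stages together: map peptides to isoforms, assign them under the
requested strategies, aggregate to per-transcript protein fold changes,
correlate against RNA fold changes, and run the intron-retention and
differential-gene-expression analyses.  ``run_pipeline`` is the file-based
entry point used by the CLI; ``run_integration`` is the in-memory core.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as iso_io
from .assignment import (
    AssignmentResult,
    assign_expression_agnostic,
    assign_major_guided,
    assign_unique_only,
)
from .integration_stats import (
    CodingFractionResult,
    ContingencyResult,
    CorrelationSummary,
    DgeCorrelations,
    IntegrationRow,
    build_integration_rows,
    coding_fraction_analysis,
    correlate,
    dge_correlation,
    gene_protein_fold_changes,
    ir_protein_ratio_test,
)
from .peptide_layer import (
    IntensityMatrix,
    PeptideRecord,
    map_peptides,
    peptide_significance,
    quantile_normalize,
    remove_multi_gene,
)
from .synthetic_data import SyntheticDataset
from .transcript_layer import (
    DifferentialCalls,
    ExpressionTable,
    TranscriptRecord,
    build_gene_profiles,
    detect_switch_events,
)

logger = logging.getLogger(__name__)

#: the four strategy x peptide-set rows of the side-by-side summary
STRATEGY_ROWS = {
    "dtu_all_unique": "unique-mapping peptides, all DTU transcripts",
    "dtu_all_all": "all peptides, expression-agnostic",
    "dtu_major_unique": "unique-mapping peptides, major transcripts",
    "dtu_major_all": "all peptides, major transcripts",
}

_STRATEGY_SELECT = {
    "all": tuple(STRATEGY_ROWS),
    "unique": ("dtu_all_unique",),
    "agnostic": ("dtu_all_all",),
    "major_unique": ("dtu_major_unique",),
    "major": ("dtu_major_all",),
}


@dataclass
class PipelineConfig:
    annotation_tsv: str | Path
    protein_fasta: str | Path
    expression_tsv: str | Path
    calls_tsv: str | Path
    intensity_tsv: str | Path
    outdir: str | Path | None = None
    strategy: str = "all"
    expression_floor: float = 1.0
    alpha: float = 0.1
    rna_pseudocount: float = 0.0
    dge_rna_pseudocount: float = 0.5
    intensity_pseudocount: float | None = None   # None = half minimum nonzero
    min_len: int = 7
    max_len: int = 30
    max_missed_cleavages: int = 2
    already_normalized: bool = False
    fc_method: str = "sum"                       # or "median"

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGY_SELECT:
            raise ValueError(f"strategy must be one of {sorted(_STRATEGY_SELECT)}")
        if self.fc_method not in ("sum", "median"):
            raise ValueError("fc_method must be 'sum' or 'median'")
        for name in ("expression_floor", "alpha", "min_len", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    assignments: dict[str, AssignmentResult]
    rows: dict[str, list[IntegrationRow]]
    summaries: dict[str, CorrelationSummary]
    switch_genes: set[str]
    gene_protein_fc: dict[str, float]
    ir_wilcoxon_p: float | None
    ir_contingency: ContingencyResult | None
    coding_fraction: CodingFractionResult | None
    dge: DgeCorrelations | None
    #: per strategy row: peptide accounting over the intensity matrix
    accounting: dict[str, dict[str, int]] = field(default_factory=dict)


def _assign(
    key: str,
    peptides: Sequence[PeptideRecord],
    profiles,
    calls: DifferentialCalls,
) -> AssignmentResult:
    if key == "dtu_all_unique":
        return assign_unique_only(peptides, calls)
    if key == "dtu_all_all":
        return assign_expression_agnostic(peptides, calls)
    if key == "dtu_major_unique":
        return assign_major_guided(peptides, profiles, calls, unique_peptides_only=True)
    if key == "dtu_major_all":
        return assign_major_guided(peptides, profiles, calls)
    raise KeyError(key)


def run_integration(
    transcripts: Sequence[TranscriptRecord],
    expr: ExpressionTable,
    calls: DifferentialCalls,
    intensities: IntensityMatrix,
    *,
    strategy: str = "all",
    expression_floor: float = 1.0,
    alpha: float = 0.1,
    rna_pseudocount: float = 0.0,
    dge_rna_pseudocount: float = 0.5,
    intensity_pseudocount: float | None = None,
    min_len: int = 7,
    max_len: int = 30,
    max_missed_cleavages: int = 2,
    fc_method: str = "sum",
) -> PipelineResult:
    """Run the full integration on in-memory inputs."""
    if not calls.dtu_transcripts:
        logger.warning("empty DTU call set: strategy summaries will have zero counts")

    expr = expr.filter_expressed(expression_floor)
    kept_genes = set(expr.genes)
    transcripts = [t for t in transcripts if t.gene_id in kept_genes]

    mapped = map_peptides(
        transcripts, min_len=min_len, max_len=max_len,
        max_missed_cleavages=max_missed_cleavages,
    )
    kept, multi_gene = remove_multi_gene(mapped)
    detected_seqs = set(intensities.peptides)
    detected = [p for p in kept if p.sequence in detected_seqs]
    mapped_seqs = {p.sequence for p in mapped}
    n_unmapped = len(detected_seqs - mapped_seqs)
    multi_gene_detected = [p for p in multi_gene if p.sequence in detected_seqs]

    if not intensities.normalized:
        intensities = quantile_normalize(intensities)

    profiles = build_gene_profiles(expr)
    switch_genes = detect_switch_events(expr, calls, profiles)

    result = PipelineResult(
        assignments={}, rows={}, summaries={}, switch_genes=switch_genes,
        gene_protein_fc={}, ir_wilcoxon_p=None, ir_contingency=None,
        coding_fraction=None, dge=None,
    )
    for key in _STRATEGY_SELECT[strategy]:
        assignment = _assign(key, detected, profiles, calls)
        rows = build_integration_rows(
            assignment, expr, intensities, calls,
            method=fc_method,
            rna_pseudocount=rna_pseudocount,
            intensity_pseudocount=intensity_pseudocount,
        )
        result.assignments[key] = assignment
        result.rows[key] = rows
        result.summaries[key] = correlate(rows)
        result.accounting[key] = {
            "allocated": assignment.n_allocated,
            "discarded": len(assignment.discarded) + len(multi_gene_detected),
            "shared_between_majors": len(assignment.shared_between_majors),
            "unmapped": n_unmapped,
            "total_in_matrix": len(detected_seqs),
        }

    # gene-level analyses use every detected single-gene peptide
    result.gene_protein_fc = gene_protein_fold_changes(
        intensities, detected, pseudocount=intensity_pseudocount
    )
    have_ir = any(g in calls.ir_genes for g in result.gene_protein_fc)
    have_non_ir = any(g in calls.non_ir_genes for g in result.gene_protein_fc)
    if have_ir and have_non_ir:
        result.ir_wilcoxon_p, result.ir_contingency = ir_protein_ratio_test(
            result.gene_protein_fc, calls
        )
        result.coding_fraction = coding_fraction_analysis(
            expr, transcripts, result.gene_protein_fc, calls
        )
    else:
        logger.warning("IR analysis skipped: empty IR or non-IR group")

    if calls.dge_genes:
        stats = peptide_significance(
            intensities, [p.sequence for p in detected],
            alpha=alpha, pseudocount=intensity_pseudocount,
        )
        result.dge = dge_correlation(
            expr, calls, stats, intensities, detected,
            rna_pseudocount=dge_rna_pseudocount,
        )
    else:
        logger.warning("DGE analysis skipped: no DGE genes called")
    return result


def summary_frame(result: PipelineResult) -> pd.DataFrame:
    """Side-by-side strategy summary (one row per strategy x peptide set)."""
    rows = []
    for key, summ in result.summaries.items():
        rows.append(
            {
                "strategy_row": key,
                "description": STRATEGY_ROWS[key],
                "n_transcripts": summ.n_transcripts,
                "n_peptides": summ.n_peptides,
                "n_genes": summ.n_genes,
                "spearman_rho": round(summ.spearman_rho, 6),
                "spearman_p": summ.spearman_p,
                "pearson_r": round(summ.pearson_r, 6),
                "pearson_p": summ.pearson_p,
                "n_agree": summ.n_agree,
                "n_disagree": summ.n_disagree,
                "agreement_pct": round(summ.agreement_pct, 4),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary_frame(result).to_csv(out / "summary.tsv", sep="\t", index=False)
    for key, rows in result.rows.items():
        pd.DataFrame(
            [
                (r.target_id, r.gene_id, r.rna_log2fc, r.protein_log2fc, r.n_peptides)
                for r in rows
            ],
            columns=["transcript_id", "gene_id", "rna_log2fc", "protein_log2fc", "n_peptides"],
        ).to_csv(out / f"integration_{key}.tsv", sep="\t", index=False, float_format="%.6g")
        assignment = result.assignments[key]
        report = (
            [(p, "allocated", t) for p, t in sorted(assignment.allocations.items())]
            + [(p, "discarded", r.value) for p, r in sorted(assignment.discarded.items())]
            + [
                (p, "shared_between_majors", f"{a}|{b}")
                for p, (a, b) in sorted(assignment.shared_between_majors.items())
            ]
        )
        pd.DataFrame(report, columns=["peptide", "status", "detail"]).to_csv(
            out / f"assignment_{key}.tsv", sep="\t", index=False
        )
    extras = {
        "n_switch_genes": len(result.switch_genes),
        "ir_wilcoxon_p": result.ir_wilcoxon_p,
    }
    if result.ir_contingency is not None:
        c = result.ir_contingency
        extras.update(
            ir_down_ir_genes=f"{c.a}/{c.n1}",
            ir_down_non_ir=f"{c.b}/{c.n2}",
            ir_odds_ratio=c.odds_ratio,
            ir_fisher_p=c.p_value,
        )
    if result.coding_fraction is not None:
        extras.update(
            coding_fraction_p=result.coding_fraction.wilcoxon_p,
            coding_fraction_median_up=result.coding_fraction.median_up,
            coding_fraction_median_down=result.coding_fraction.median_down,
        )
    if result.dge is not None:
        extras.update(
            dge_rho_all=result.dge.all_peptides.spearman_rho,
            dge_rho_significant=result.dge.significant_peptides.spearman_rho,
            dge_rho_non_dge=result.dge.non_dge_genes.spearman_rho,
            dge_rho_gene_summarised=result.dge.gene_summarised.spearman_rho,
        )
    pd.Series(extras, name="value").rename_axis("statistic").to_csv(
        out / "analysis_stats.tsv", sep="\t"
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based pipeline entry point: read inputs, run, write reports."""
    transcripts = iso_io.read_annotation(cfg.annotation_tsv, cfg.protein_fasta)
    expr = iso_io.read_expression_tsv(cfg.expression_tsv)
    calls = iso_io.read_calls_tsv(cfg.calls_tsv)
    intensities = iso_io.read_intensity_tsv(
        cfg.intensity_tsv, normalized=cfg.already_normalized
    )
    expr_design = {
        cond: len(expr.replicates(cond)) for cond in ("control", "depleted")
    }
    mat_design = {
        cond: intensities.condition_columns(cond).shape[1]
        for cond in ("control", "depleted")
    }
    if expr_design != mat_design:
        raise ValueError(
            f"replicate design mismatch: expression {expr_design} vs intensities {mat_design}"
        )
    result = run_integration(
        transcripts, expr, calls, intensities,
        strategy=cfg.strategy,
        expression_floor=cfg.expression_floor,
        alpha=cfg.alpha,
        rna_pseudocount=cfg.rna_pseudocount,
        dge_rna_pseudocount=cfg.dge_rna_pseudocount,
        intensity_pseudocount=cfg.intensity_pseudocount,
        min_len=cfg.min_len,
        max_len=cfg.max_len,
        max_missed_cleavages=cfg.max_missed_cleavages,
        fc_method=cfg.fc_method,
    )
    if cfg.outdir is not None:
        write_outputs(result, cfg.outdir)
    return result


def run_on_dataset(ds: SyntheticDataset, **overrides) -> PipelineResult:
    """Convenience wrapper: run the integration directly on a simulated dataset."""
    return run_integration(ds.transcripts, ds.expression, ds.calls, ds.intensities, **overrides)
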