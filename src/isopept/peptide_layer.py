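"""Proteome side: in-silico digestion, peptide-to-transcript mapping,
intensity normalization, peptide fold changes and per-peptide significance.

Peptides are plain amino-acid strings (charge states and modifications are out
of scope); isoleucine and leucine are kept distinct because mapping is done at
the sequence level, not at MS-ambiguity level.
"""
from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .transcript_layer import AMINO_ACIDS, CONDITIONS, CONTROL, DEPLETED, TranscriptRecord

logger = logging.getLogger(__name__)


class Uniqueness(str, enum.Enum):
    UNIQUE_TRANSCRIPT = "unique_transcript"  # one isoform only
    GENE_SHARED = "gene_shared"              # several isoforms of one gene
    MULTI_GENE = "multi_gene"                # more than one gene: removed


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    mapped_transcripts: frozenset[str]
    mapped_genes: frozenset[str]

    @property
    def uniqueness(self) -> Uniqueness:
        if len(self.mapped_genes) > 1:
            return Uniqueness.MULTI_GENE
        if len(self.mapped_transcripts) == 1:
            return Uniqueness.UNIQUE_TRANSCRIPT
        return Uniqueness.GENE_SHARED

    @property
    def gene_id(self) -> str:
        """The single mapped gene (only valid after multi-gene removal)."""
        if len(self.mapped_genes) != 1:
            raise ValueError(f"{self.sequence}: maps to {len(self.mapped_genes)} genes")
        return next(iter(self.mapped_genes))


# -- digestion --------------------------------------------------------------


def digest(
    protein_sequence: str,
    min_len: int = 7,
    max_len: int | None = 30,
    max_missed_cleavages: int = 2,
) -> list[str]:
    """Tryptic digest: cleave C-terminal to K or R except before P.

    Returns all products with at most ``max_missed_cleavages`` internal missed
    sites whose length lies in ``[min_len, max_len]`` (``max_len=None``
    disables the upper bound), in N- to C-terminal order, fully cleaved
    fragments first.  The fully cleaved fragments, before length filtering,
    concatenate back to the input.
    """
    bad = set(protein_sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letters {sorted(bad)}")
    if not protein_sequence:
        return []
    fragments: list[str] = []
    start = 0
    for i, residue in enumerate(protein_sequence):
        at_end = i + 1 == len(protein_sequence)
        if residue in "KR" and (at_end or protein_sequence[i + 1] != "P"):
            fragments.append(protein_sequence[start : i + 1])
            start = i + 1
    if start < len(protein_sequence):
        fragments.append(protein_sequence[start:])

    out: list[str] = []
    for missed in range(min(max_missed_cleavages, len(fragments) - 1) + 1):
        for i in range(len(fragments) - missed):
            pep = "".join(fragments[i : i + missed + 1])
            if len(pep) >= min_len and (max_len is None or len(pep) <= max_len):
                out.append(pep)
    return out


def map_peptides(
    transcripts: Sequence[TranscriptRecord],
    min_len: int = 7,
    max_len: int | None = 30,
    max_missed_cleavages: int = 2,
) -> list[PeptideRecord]:
    """Digest every translated isoform and classify each peptide's uniqueness.

    All transcripts are digested with identical parameters; a peptide's mapped
    transcripts are exactly those whose digest contains it.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    hits: dict[str, set[str]] = {}
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    for t in transcripts:
        if t.protein_sequence is None:
            continue
        for pep in set(digest(t.protein_sequence, min_len, max_len, max_missed_cleavages)):
            hits.setdefault(pep, set()).add(t.transcript_id)
    return [
        PeptideRecord(
            sequence=pep,
            mapped_transcripts=frozenset(tids),
            mapped_genes=frozenset(gene_of[tid] for tid in tids),
        )
        for pep, tids in sorted(hits.items())
    ]


def remove_multi_gene(
    peptides: Iterable[PeptideRecord],
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Split peptides into (kept, removed) by the multi-gene rule."""
    kept, removed = [], []
    for p in peptides:
        (removed if p.uniqueness is Uniqueness.MULTI_GENE else kept).append(p)
    if removed:
        logger.info("removed %d multi-gene peptides (%d kept)", len(removed), len(kept))
    return kept, removed


# -- intensities ------------------------------------------------------------


class IntensityMatrix:
    """Peptide x (condition, replicate) intensity matrix.

    ``values`` has the peptide sequence as index and a (condition, replicate)
    MultiIndex on the columns; all intensities are >= 0, with no missing
    entries (censored peptides are absent rows, not NaNs).
    """

    def __init__(self, values: pd.DataFrame, normalized: bool = False):
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValueError("columns must be a (condition, replicate) MultiIndex")
        conds = set(values.columns.get_level_values(0))
        if not conds <= set(CONDITIONS):
            raise ValueError(f"unknown conditions {sorted(conds - set(CONDITIONS))}")
        if values.isna().any().any():
            raise ValueError("missing intensities")
        if (values < 0).any().any():
            raise ValueError("negative intensities")
        self.values = values.copy()
        self.values.columns = values.columns.remove_unused_levels() if isinstance(
            values.columns, pd.MultiIndex) else values.columns
        self.normalized = normalized

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)

    def condition_columns(self, condition: str) -> pd.DataFrame:
        return self.values.loc[:, self.values.columns.get_level_values(0) == condition]

    @cached_property
    def half_min_positive(self) -> float:
        """Half the smallest nonzero intensity — the default pseudocount."""
        arr = self.values.to_numpy()
        pos = arr[arr > 0]
        return float(pos.min() / 2) if pos.size else 0.0


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Force identical value distributions across columns by rank averaging.

    The value at rank r in every column is replaced by the mean of the rank-r
    values across columns; tied values receive the mean of the target values
    their ranks span.  Idempotent; a single-column matrix is returned
    unchanged with a warning.
    """
    df = m.values
    if df.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; returning input")
        return IntensityMatrix(df, normalized=True)
    arr = df.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average assigned targets within tie groups
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    return IntensityMatrix(res, normalized=True)


def _condition_medians(m: IntensityMatrix, peptide: str) -> tuple[float, float]:
    if peptide not in m.values.index:
        raise KeyError(peptide)
    row = m.values.loc[peptide]
    return (
        float(row.loc[CONTROL].median()),
        float(row.loc[DEPLETED].median()),
    )


def _log_ratio(num: float, den: float, pseudocount: float) -> float:
    # pseudocount enters (both sides) only when one median is zero, so
    # fold changes of fully observed peptides stay exact ratios
    if num == 0.0 and den == 0.0:
        return 0.0
    if num == 0.0 or den == 0.0:
        num += pseudocount
        den += pseudocount
    if num == 0.0 or den == 0.0:
        raise ValueError("zero median with zero pseudocount")
    return float(np.log2(num / den))


def peptide_fold_change(
    m: IntensityMatrix, peptide: str, pseudocount: float | None = None
) -> float:
    """log2(median depleted / median control) for one peptide.

    ``pseudocount=None`` uses half the smallest nonzero intensity; it is added
    to both medians, and only when one of them is zero.
    """
    if not m.normalized:
        logger.warning("peptide_fold_change on an unnormalized matrix")
    ctrl, depl = _condition_medians(m, peptide)
    pc = m.half_min_positive if pseudocount is None else pseudocount
    return _log_ratio(depl, ctrl, pc)


@dataclass(frozen=True)
class PeptideStat:
    peptide: str
    log2_fc: float
    raw_p: float
    adjusted_p: float
    significant: bool


def peptide_significance(
    m: IntensityMatrix,
    peptide_set: Sequence[str] | None = None,
    alpha: float = 0.1,
    pseudocount: float | None = None,
) -> list[PeptideStat]:
    """Per-peptide Welch t-tests on log2 intensities, Holm-adjusted.

    A peptide is significant when its Holm-adjusted p-value is below ``alpha``
    (default 0.1).  Constant, equal groups give p = 1; constant, different
    groups give p = 0.
    """
    peptides = list(peptide_set) if peptide_set is not None else m.peptides
    if not peptides:
        return []
    pc = m.half_min_positive if pseudocount is None else pseudocount
    ctrl = np.log2(m.condition_columns(CONTROL).loc[peptides].to_numpy() + pc)
    depl = np.log2(m.condition_columns(DEPLETED).loc[peptides].to_numpy() + pc)
    if ctrl.shape[1] < 2 or depl.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(depl, ctrl, axis=1, equal_var=False)
    means_equal = np.isclose(depl.mean(axis=1), ctrl.mean(axis=1))
    pvals = np.where(np.isnan(pvals), np.where(means_equal, 1.0, 0.0), pvals)
    _, adjusted, _, _ = multipletests(pvals, method="holm")
    fcs = [peptide_fold_change(m, p, pseudocount=pseudocount) for p in peptides]
    return [
        PeptideStat(p, fc, float(raw), float(adj), bool(adj < alpha))
        for p, fc, raw, adj in zip(peptides, fcs, pvals, adjusted)
    ]
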