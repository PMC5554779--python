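"""Coupled synthetic transcriptome/proteome datasets with ground truth.

Emulates the two-condition (control vs spliceosome-depleted), three-replicate
design the pipeline was built for: multi-isoform genes with differential
transcript usage (DTU, including major-transcript switches and shifts confined
to minor isoforms), differential gene expression (DGE), intron-retention (IR)
genes whose retained isoform is untranslated, peptide sharing across isoforms
(shared + isoform-specific protein blocks), and MS dynamic-range censoring
(~4.4 orders of magnitude below the most intense peptide).

Peptide expected intensity is proportional to the summed expression (raised to
``coupling_slope``) of the transcripts containing it; replicate noise is
multiplicative log-normal, inflated near the detection limit so low-abundance
signals are noisier, as in real RNA-seq/MS data.

The generator is hierarchical: one global seed spawns one substream per gene,
so a gene's transcript-level data does not depend on how many other genes are
simulated.  (The proteome cannot be fully per-gene: the censoring floor is a
property of the whole peptide population.)
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .peptide_layer import IntensityMatrix
from .transcript_layer import (
    CONDITIONS,
    CONTROL,
    DEPLETED,
    Biotype,
    DifferentialCalls,
    ExpressionTable,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)

#: residue alphabet for synthetic "tryptic words" (no K/R/P in the interior,
#: so cleavage sites sit exactly at word boundaries)
_WORD_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))

LABEL_SWITCH = "switch"
LABEL_DTU = "dtu"
LABEL_DGE = "dge"
LABEL_IR = "ir"
LABEL_NULL = "null"


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the depletion study design: two conditions, three
    biological replicates, FPKM-like log-normal gene totals and a 4.4-order
    MS dynamic range; effect sizes are documented in docs/methods.md.
    """

    n_genes: int = 300
    #: probability of a gene having 1, 2, 3 or 4 isoforms
    isoform_weights: tuple[float, ...] = (0.25, 0.35, 0.25, 0.15)
    fraction_dtu: float = 0.15
    fraction_switch: float = 0.05      # subset of the DTU fraction
    fraction_dtu_minor: float = 0.3    # of non-switch DTU genes: shift spares the major
    fraction_dge: float = 0.20
    fraction_ir: float = 0.15
    replicates_per_condition: int = 3
    expression_log10_mean: float = 1.0
    expression_log10_sd: float = 1.0
    #: sorted-Dirichlet concentration for isoform proportions; < 1 gives the
    #: major-dominated transcriptomes seen in real data
    isoform_alpha: float = 0.6
    coupling_slope: float = 1.0
    noise_sd: float = 0.25             # log2 sd of replicate noise (master noise dial)
    low_signal_noise: float = 3.0      # extra noise factor near the detection floor
    #: isoform-deconvolution quantification bias on the RNA side, as a
    #: multiple of noise_sd: one log-normal factor per transcript x condition,
    #: shared across replicates (it does not average out), emulating the
    #: uncertainty of transcript-level expression estimates
    rna_quant_bias: float = 2.0
    dynamic_range_orders: float = 4.4
    response_log10_sd: float = 1.0     # per-peptide MS response spread
    #: log10 sd of the per-peptide precision multiplier: some peptides are
    #: measured much more precisely than others, so a significance filter
    #: selects the well-measured ones
    peptide_cv_spread: float = 0.3
    intensity_scale: float = 1e5
    shared_words: int = 5              # tryptic words common to all isoforms of a gene
    partial_words: int = 2             # words shared by a proper subset of >= 2 isoforms
    unique_words: int = 3              # isoform-specific tryptic words
    word_len: tuple[int, int] = (7, 12)
    sample_log2_sd: float = 0.0        # per-column technical scaling (0 = pre-normalized)
    dge_log2_range: tuple[float, float] = (0.8, 2.5)
    #: log2 sd of the gene-total drift accompanying usage changes: real DTU
    #: genes are not expression-neutral, so shared peptides carry signal
    dtu_total_log2_sd: float = 0.5
    #: probability that the complementary shifted isoform is also flagged DTU
    #: (upstream calls flag ~1.2 transcripts per DTU gene)
    dtu_partner_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.fraction_dtu, self.fraction_dge, self.fraction_ir, self.fraction_switch)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("fractions must lie in [0, 1]")
        if self.fraction_switch > self.fraction_dtu:
            raise ConfigError("fraction_switch must not exceed fraction_dtu")
        if self.fraction_dtu + self.fraction_dge + self.fraction_ir > 1 + 1e-12:
            raise ConfigError("category fractions sum to more than 1")
        if self.replicates_per_condition < 2:
            raise ConfigError("need >= 2 replicates per condition")
        needs_multi = self.fraction_dtu > 0 or self.fraction_ir > 0
        if needs_multi and sum(self.isoform_weights[1:]) == 0:
            raise ConfigError("DTU/switch/IR genes require multi-isoform genes")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, never read by the pipeline."""

    gene_labels: dict[str, str]
    dtu_transcripts: set[str]
    #: expected (pre-noise) expression per (transcript_id, condition)
    transcript_expected: dict[tuple[str, str], float]
    #: expected (pre-noise, pre-censoring) intensity per (peptide, condition)
    peptide_expected: dict[tuple[str, str], float] = field(default_factory=dict)

    def genes_with_label(self, label: str) -> set[str]:
        return {g for g, lab in self.gene_labels.items() if lab == label}


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    transcripts: list[TranscriptRecord]
    expression: ExpressionTable
    intensities: IntensityMatrix
    truth: GroundTruth
    calls: DifferentialCalls


# -- label bookkeeping ------------------------------------------------------


def _gene_labels(cfg: SimulationConfig) -> list[str]:
    n = cfg.n_genes
    n_switch = round(cfg.fraction_switch * n)
    n_dtu = round(cfg.fraction_dtu * n) - n_switch
    n_dge = round(cfg.fraction_dge * n)
    n_ir = round(cfg.fraction_ir * n)
    labels = (
        [LABEL_SWITCH] * n_switch
        + [LABEL_DTU] * n_dtu
        + [LABEL_DGE] * n_dge
        + [LABEL_IR] * n_ir
    )
    labels += [LABEL_NULL] * (n - len(labels))
    return labels[:n]


def _random_word(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(_WORD_ALPHABET, size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _sorted_dirichlet(rng: np.random.Generator, k: int, alpha: float = 1.2) -> np.ndarray:
    return np.sort(rng.dirichlet(np.full(k, alpha)))[::-1]


# -- per-gene construction --------------------------------------------------


def _switch_proportions(
    rng: np.random.Generator, k: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Top two isoforms clearly separated, then inverted in depleted.

    Returns (control, depleted, primary shifted index, partner index); the
    primary is the rising isoform (the new major).
    """
    if k == 2:
        p1 = rng.uniform(0.60, 0.75)
        ctrl = np.array([p1, 1 - p1])
    else:
        for _ in range(200):
            tail = _sorted_dirichlet(rng, k - 2) * rng.uniform(0.08, 0.18)
            rem = 1 - tail.sum()
            p1 = rem * rng.uniform(0.58, 0.68)
            p2 = rem - p1
            if p1 - p2 >= 0.15 and p2 > tail.max() + 0.02:
                break
        else:  # pragma: no cover
            raise ConfigError("could not draw feasible switch proportions")
        ctrl = np.concatenate([[p1, p2], tail])
    depl = ctrl.copy()
    depl[[0, 1]] = depl[[1, 0]]
    return ctrl, depl, 1, 0


def _major_shift_proportions(
    rng: np.random.Generator, k: int, alpha: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Usage shift centred on the major: it gains from (or yields to) the
    minor isoforms proportionally, so the major is the primary shifted
    transcript and remains the major in both conditions."""
    for _ in range(200):
        ctrl = _sorted_dirichlet(rng, k, alpha)
        delta = rng.uniform(0.15, 0.30)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        p1 = ctrl[0] + sign * delta
        if not 0.05 < p1 < 0.97:
            continue
        minors = ctrl[1:] * (1 - p1) / (1 - ctrl[0])
        if p1 > minors.max() + 0.02:
            return ctrl, np.concatenate([[p1], minors]), 0, 1
    raise ConfigError("could not draw feasible DTU proportions")  # pragma: no cover


def _minor_shift_proportions(
    rng: np.random.Generator, k: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """DTU confined to lowly expressed minor isoforms; the major is untouched.

    The primary shifted transcript is the gaining minor isoform.
    """
    assert k >= 3
    for _ in range(200):
        ctrl = _sorted_dirichlet(rng, k, alpha=1.0)
        if ctrl[0] - ctrl[1] < 0.2 or ctrl[2] < 0.02:
            continue
        room = min(ctrl[1] - 0.01, ctrl[0] - ctrl[2] - 0.12)
        if room >= 0.10:
            break
    else:  # pragma: no cover
        raise ConfigError("could not draw feasible minor-DTU proportions")
    delta = min(rng.uniform(0.10, 0.18), room)
    depl = ctrl.copy()
    depl[1] -= delta
    depl[2] += delta
    return ctrl, depl, 2, 1


@dataclass
class _GeneSim:
    gene_id: str
    label: str
    records: list[TranscriptRecord]
    expected: dict[tuple[str, str], float]
    words_of: dict[str, list[str]]          # transcript -> its tryptic words
    dtu_transcripts: list[str]


def _simulate_gene(
    cfg: SimulationConfig, gene_id: str, label: str, rng: np.random.Generator
) -> _GeneSim:
    weights = np.asarray(cfg.isoform_weights, dtype=float)
    weights = weights / weights.sum()
    k = int(rng.choice(np.arange(1, len(weights) + 1), p=weights))
    minor_shift = False
    if label in (LABEL_SWITCH, LABEL_DTU, LABEL_IR):
        k = max(k, 2)
    if label == LABEL_DTU:
        minor_shift = rng.random() < cfg.fraction_dtu_minor
        if minor_shift:
            k = max(k, 3)

    total = 10.0 ** rng.normal(cfg.expression_log10_mean, cfg.expression_log10_sd)
    dtu_idx: list[int] = []
    retained_q: tuple[float, float] | None = None
    drift = 2.0 ** rng.normal(0.0, cfg.dtu_total_log2_sd) if cfg.dtu_total_log2_sd > 0 else 1.0
    if label in (LABEL_SWITCH, LABEL_DTU):
        if label == LABEL_SWITCH:
            ctrl_p, depl_p, primary, partner = _switch_proportions(rng, k)
        elif minor_shift:
            ctrl_p, depl_p, primary, partner = _minor_shift_proportions(rng, k)
        else:
            ctrl_p, depl_p, primary, partner = _major_shift_proportions(
                rng, k, cfg.isoform_alpha
            )
        # upstream DTU calls are sparse within a gene (~1.2 flagged
        # transcripts per DTU gene in practice): flag the primary shifted
        # isoform, and its partner only occasionally
        dtu_idx = [primary]
        if rng.random() < cfg.dtu_partner_prob:
            dtu_idx.append(partner)
        totals = (total, total * drift)
    elif label == LABEL_DGE:
        ctrl_p = depl_p = _sorted_dirichlet(rng, k, cfg.isoform_alpha)
        effect = rng.uniform(*cfg.dge_log2_range) * (1 if rng.random() < 0.5 else -1)
        totals = (total, total * 2.0 ** effect)
    elif label == LABEL_IR:
        # coding isoforms keep their relative mix; an untranslated
        # retained-intron isoform soaks up gene output in the depleted state
        ctrl_p = depl_p = _sorted_dirichlet(rng, k, cfg.isoform_alpha)
        q0 = rng.uniform(0.02, 0.10)
        q1 = min(q0 + rng.uniform(0.05, 0.55), 0.65)   # boosts span mild to severe
        retained_q = (q0, q1)
        totals = (total, total)
    else:
        ctrl_p = depl_p = _sorted_dirichlet(rng, k, cfg.isoform_alpha)
        totals = (total, total)

    shared = [_random_word(rng, *cfg.word_len) for _ in range(cfg.shared_words)]
    # words shared by a proper subset of isoforms (shared exon subsets), only
    # possible with >= 3 isoforms
    partial: list[tuple[str, frozenset[int]]] = []
    if k >= 3:
        for _ in range(cfg.partial_words):
            size = int(rng.integers(2, k))
            members = frozenset(rng.choice(k, size=size, replace=False).tolist())
            partial.append((_random_word(rng, *cfg.word_len), members))
    records: list[TranscriptRecord] = []
    expected: dict[tuple[str, str], float] = {}
    words_of: dict[str, list[str]] = {}
    tids: list[str] = []
    for j in range(k):
        tid = f"{gene_id}.t{j + 1}"
        tids.append(tid)
        own = [_random_word(rng, *cfg.word_len) for _ in range(cfg.unique_words)]
        words = shared + [w for w, members in partial if j in members] + own
        records.append(
            TranscriptRecord(tid, gene_id, Biotype.PROTEIN_CODING, "".join(words))
        )
        words_of[tid] = words
    coding_scale = (1.0, 1.0)
    if retained_q is not None:
        tid = f"{gene_id}.ir"
        records.append(TranscriptRecord(tid, gene_id, Biotype.RETAINED_INTRON, None))
        words_of[tid] = []
        expected[(tid, CONTROL)] = totals[0] * retained_q[0]
        expected[(tid, DEPLETED)] = totals[1] * retained_q[1]
        coding_scale = (1 - retained_q[0], 1 - retained_q[1])
    for j, tid in enumerate(tids):
        expected[(tid, CONTROL)] = totals[0] * coding_scale[0] * ctrl_p[j]
        expected[(tid, DEPLETED)] = totals[1] * coding_scale[1] * depl_p[j]

    return _GeneSim(
        gene_id=gene_id,
        label=label,
        records=records,
        expected=expected,
        words_of=words_of,
        dtu_transcripts=[tids[i] for i in dtu_idx],
    )


# -- public operations ------------------------------------------------------


def _noise_factor(
    rng: np.random.Generator,
    expected: float,
    cfg: SimulationConfig,
    ref: float,
    size: int,
    scale: float = 1.0,
) -> np.ndarray:
    sd = scale * cfg.noise_sd * (1 + cfg.low_signal_noise * np.sqrt(ref / (expected + ref)))
    if sd == 0:
        return np.ones(size)
    return 2.0 ** rng.normal(0.0, sd, size=size)


def generate_transcriptome(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptRecord], ExpressionTable, GroundTruth]:
    """Draw genes, isoform structures and replicate expression values."""
    labels = _gene_labels(cfg)
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_genes)
    width = max(4, len(str(cfg.n_genes)))

    records: list[TranscriptRecord] = []
    rows: list[tuple] = []
    truth = GroundTruth(gene_labels={}, dtu_transcripts=set(), transcript_expected={})
    reps = range(1, cfg.replicates_per_condition + 1)
    for i, (label, ss) in enumerate(zip(labels, children)):
        structure_seed, noise_seed = ss.spawn(2)
        sim = _simulate_gene(
            cfg, f"G{i + 1:0{width}d}", label, np.random.default_rng(structure_seed)
        )
        rng = np.random.default_rng(noise_seed)
        records.extend(sim.records)
        truth.gene_labels[sim.gene_id] = sim.label
        truth.dtu_transcripts.update(sim.dtu_transcripts)
        truth.transcript_expected.update(sim.expected)
        for rec in sim.records:
            for cond in CONDITIONS:
                mu = sim.expected[(rec.transcript_id, cond)]
                # isoform-level quantification bias: one factor per
                # transcript x condition, shared across replicates
                bias_sd = cfg.rna_quant_bias * cfg.noise_sd * (
                    1 + cfg.low_signal_noise * np.sqrt(1.0 / (mu + 1.0))
                )
                mu_obs = mu * (2.0 ** rng.normal(0.0, bias_sd) if bias_sd > 0 else 1.0)
                vals = mu_obs * _noise_factor(rng, mu, cfg, ref=1.0, size=len(reps))
                for rep, v in zip(reps, vals):
                    rows.append((rec.transcript_id, sim.gene_id, cond, rep, float(v)))
    expr = ExpressionTable(
        pd.DataFrame(rows, columns=list(ExpressionTable.COLUMNS))
    )
    logger.info(
        "simulated %d genes (%s)", cfg.n_genes,
        ", ".join(f"{lab}={labels.count(lab)}" for lab in
                  (LABEL_SWITCH, LABEL_DTU, LABEL_DGE, LABEL_IR, LABEL_NULL)),
    )
    return records, expr, truth


def generate_proteome(
    cfg: SimulationConfig,
    transcripts: Sequence[TranscriptRecord],
    expr: ExpressionTable,
    truth: GroundTruth,
) -> IntensityMatrix:
    """Expected peptide intensities from expected transcript expression,
    censored at the dynamic-range floor, with multiplicative replicate noise.

    Censoring is applied once per peptide on its expected intensity (a peptide
    is either consistently detectable or absent), not per replicate.
    Untranslated (retained-intron) isoforms contribute no signal.
    """
    from .peptide_layer import digest  # local import to avoid cycle at module load

    pep_tids: dict[str, set[str]] = {}
    for t in transcripts:
        if t.protein_sequence is None:
            continue
        for pep in digest(t.protein_sequence, min_len=7, max_len=30, max_missed_cleavages=0):
            pep_tids.setdefault(pep, set()).add(t.transcript_id)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_919]))
    expected: dict[str, dict[str, float]] = {}
    for pep in sorted(pep_tids):
        eff = 10.0 ** rng.normal(0.0, cfg.response_log10_sd)
        per_cond = {}
        for cond in CONDITIONS:
            signal = sum(
                truth.transcript_expected[(tid, cond)] ** cfg.coupling_slope
                for tid in pep_tids[pep]
            )
            per_cond[cond] = cfg.intensity_scale * eff * signal
        expected[pep] = per_cond

    peak = max((max(v.values()) for v in expected.values()), default=0.0)
    floor = peak / 10.0 ** cfg.dynamic_range_orders
    kept = [pep for pep, v in expected.items() if max(v.values()) >= floor]
    n_censored = len(expected) - len(kept)
    if n_censored:
        logger.info("censored %d / %d peptides below the dynamic-range floor",
                    n_censored, len(expected))

    reps = range(1, cfg.replicates_per_condition + 1)
    columns = pd.MultiIndex.from_tuples(
        [(cond, rep) for cond in CONDITIONS for rep in reps],
        names=["condition", "replicate"],
    )
    sample_shift = (
        2.0 ** rng.normal(0.0, cfg.sample_log2_sd, size=len(columns))
        if cfg.sample_log2_sd > 0
        else np.ones(len(columns))
    )
    data = np.zeros((len(kept), len(columns)))
    for i, pep in enumerate(kept):
        truth.peptide_expected[(pep, CONTROL)] = expected[pep][CONTROL]
        truth.peptide_expected[(pep, DEPLETED)] = expected[pep][DEPLETED]
        precision = 10.0 ** rng.normal(0.0, cfg.peptide_cv_spread)
        j = 0
        for cond in CONDITIONS:
            mu = expected[pep][cond]
            vals = mu * _noise_factor(
                rng, mu, cfg, ref=floor, size=len(list(reps)), scale=precision
            )
            for v in vals:
                data[i, j] = v * sample_shift[j]
                j += 1
    matrix = pd.DataFrame(data, index=pd.Index(kept, name="peptide"), columns=columns)
    return IntensityMatrix(matrix, normalized=cfg.sample_log2_sd == 0)


def truth_calls(truth: GroundTruth) -> DifferentialCalls:
    """Ground-truth differential calls, standing in for the upstream
    transcript-level and exon-level differential testing."""
    dtu_genes = truth.genes_with_label(LABEL_DTU) | truth.genes_with_label(LABEL_SWITCH)
    ir_genes = truth.genes_with_label(LABEL_IR)
    return DifferentialCalls(
        dtu_transcripts=frozenset(truth.dtu_transcripts),
        dtu_genes=frozenset(dtu_genes),
        dge_genes=frozenset(truth.genes_with_label(LABEL_DGE)),
        ir_genes=frozenset(ir_genes),
        non_ir_genes=frozenset(set(truth.gene_labels) - ir_genes),
    )


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full coupled dataset: annotation, expression, intensities, truth, calls."""
    transcripts, expr, truth = generate_transcriptome(cfg)
    intensities = generate_proteome(cfg, transcripts, expr, truth)
    return SyntheticDataset(cfg, transcripts, expr, intensities, truth, truth_calls(truth))
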