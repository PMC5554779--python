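# Methods

## The integration procedure

The package addresses a two-condition perturbation experiment (labels
`control` and `depleted`, after the spliceosome-depletion design it
emulates) measured on two layers: transcript-level RNA-seq expression
estimates (FPKM-like, ≥ 2 biological replicates per condition) and a
peptide-level intensity matrix from DIA/SWATH-style MS on the same design.
Upstream differential calls — DTU transcripts/genes, DGE genes, IR genes —
are *inputs*: producing them (isoform quantification, Bayesian model
comparison, exon/intron-level testing) is out of scope, and in synthetic
runs they come from the generator's ground truth.

Pipeline stages, in order:

1. **Expressed-gene floor.** Genes whose summarised expression (median
   across replicates of per-replicate isoform sums) stays below 1
   FPKM-equivalent in both conditions are removed before anything else.
2. **In-silico digestion and mapping.** Every translated isoform
   (protein-coding and NMD biotypes; retained-intron isoforms are treated
   as untranslated) is digested with the tryptic rule *cleave C-terminal to
   K/R except before P*, defaults length 7–30 and ≤ 2 missed cleavages. A
   peptide's mapped transcripts are all isoforms whose digest contains it;
   peptides hitting more than one gene are removed. Ile and Leu are kept
   distinct (sequence-level mapping, not MS-ambiguity level).
3. **Normalization.** Raw intensity matrices are quantile-normalized
   (rank-wise column averaging, ties receiving the mean of the values their
   ranks span); matrices declared already-normalized pass through.
4. **Assignment.** Three strategies (unique-only, major-guided,
   expression-agnostic), described in the README; the summary reports four
   rows because the major-guided strategy is additionally run restricted to
   uniquely mapping peptides.
5. **Fold changes.** Condition summary is always the median across
   replicates. Transcript RNA FC: log2 ratio of condition medians,
   pseudocount 0 by default (DTU transcripts are expressed). Protein FC per
   transcript: sum allocated peptide intensities per replicate, then log2
   ratio of condition medians (`sum`), or the median of per-peptide log2
   FCs (`median`); both are exposed, `sum` is the default.
6. **Concordance.** Spearman's ρ (primary) and Pearson's r with two-sided
   correlation-test p-values over (RNA FC, protein FC) pairs restricted to
   DTU-called transcripts, plus sign-agreement tallies.
7. **IR analysis.** Gene-level protein FC = median over the gene's detected
   peptides' FCs. IR vs non-IR genes: two-sided Mann–Whitney on the FC
   distributions; 2×2 of down-regulated (FC < 0) counts with cross-product
   odds ratio and two-sided Fisher-exact p. Among IR genes, the
   protein-coding relative-abundance fraction (depleted condition) is
   compared between protein-up and protein-down genes by rank-sum.
8. **DGE analysis.** Gene-level RNA FC vs per-peptide protein FC over
   DGE-called genes, reported for all peptides, for the subset significant
   after Welch t-test + Holm (adjusted p < 0.1), for non-DGE genes
   (contrast), and gene-summarised (median peptide FC per gene).

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| expression floor | 1.0 FPKM-eq | expressed-gene threshold applied before all analyses |
| digestion | 7–30 aa, ≤ 2 missed | routine tryptic window for bottom-up MS |
| intensity pseudocount | half the smallest nonzero normalized intensity | added to *both* condition medians, and only when one of them is zero, so fully observed ratios stay exact |
| RNA pseudocount (transcript FC) | 0 | DTU transcripts are expressed; configurable |
| RNA pseudocount (gene FC, DGE) | 0.5 | guards file-based inputs against exact zeros |
| significance level | adjusted p < 0.1 | Holm-adjusted Welch t-test on log2 intensities |
| t-test variant | Welch | unequal variances are the norm for MS intensities |

Numerical choices: major-transcript ties break towards the lexicographically
smaller transcript id (logged); genes with zero summarised expression in a
condition have an undefined major and are skipped by switch detection rather
than raising; sign agreement with a zero FC on either side counts as
disagreement (zero FCs are measure-zero in practice); constant inputs give
NaN correlations with counts still reported; fewer than 3 points give NaN
correlations.

## The synthetic-data generator

`SimulationConfig` defines the study conditions; the defaults are the
conditions every test and the acceptance script use.

**Structure.** `n_genes` genes with 1–4 isoforms
(`isoform_weights = (0.25, 0.35, 0.25, 0.15)`); isoform proportions from a
sorted Dirichlet with concentration `isoform_alpha = 0.6`, giving the
major-dominated mixes seen in real transcriptomes. Gene totals are
log-normal, `10^N(1.0, 1.0)` FPKM-like — a spread wide enough that, with
per-peptide MS response factors of `10^N(0, 1.0)`, a 4.4-order
dynamic-range window censors the majority of the tryptic universe (~60% at
the defaults), as in the study this emulates, where most expressed genes
had no detected peptides.

**Gene classes** (exact counts by construction): `switch` 5% — top-two
isoform proportions inverted (gap ≥ 0.15); `dtu` 10% — usage shift ≥ 0.15
centred on the major (the major gains from or yields to the minors
proportionally), except a `fraction_dtu_minor = 0.3` subset where the shift
(≥ 0.10) is confined to minor isoforms and the major is untouched; `dge`
20% — totals scaled by ±0.8–2.5 log2, proportions fixed; `ir` 15% — an
untranslated retained-intron isoform rises from ~2–10% to up to 65% of gene
output (boost drawn 0.05–0.55, so mild and severe retention both occur),
totals fixed; the rest null. DTU/switch genes additionally receive a
log-normal gene-total drift (`dtu_total_log2_sd = 0.5`): usage changes in
real data co-occur with expression changes, and without that drift every
gene-shared peptide would have exactly zero fold change by construction —
contradicting the observed near-equivalence of the sum-based and
median-of-peptide-FC aggregations. Upstream-style DTU calls are sparse
within a gene: the primary shifted isoform is always flagged, its partner
with probability `dtu_partner_prob = 0.2` (matching the ~1.2 flagged
transcripts per DTU gene in the data the design mirrors).

**Proteins.** Each gene's isoforms share `shared_words = 5` "tryptic words"
(7–12 aa, K/R only at the end, no P), carry `unique_words = 3` private
words, and, with ≥ 3 isoforms, `partial_words = 2` words shared by a proper
subset — so unique, gene-shared, and partially shared peptides all arise by
construction, and tryptic digestion recovers the words exactly.

**Signal and noise.** A peptide's expected intensity is proportional to the
summed expression (power `coupling_slope = 1`) of the transcripts containing
it, times its response factor; retained-intron isoforms contribute nothing.
Censoring is applied once per peptide on expected intensity (a peptide is
consistently detectable or absent), not per replicate. All stochastic error
scales with one master dial, `noise_sd` (log2 sd of replicate noise,
default 0.25), so `noise_sd = 0` is an exactly noise-free limit:
replicate noise is multiplicative log-normal, inflated by
`1 + low_signal_noise·sqrt(ref/(x+ref))` near the detection reference
(1 FPKM for RNA, the censoring floor for MS); the RNA side additionally
carries an isoform-deconvolution bias (`rna_quant_bias = 2`× `noise_sd`,
one factor per transcript × condition, shared across replicates — the
component of transcript-quantification error that replicate averaging
cannot remove, and the reason all assignment strategies plateau near
ρ ≈ 0.5 at the default noise rather than separating); each peptide has a
precision multiplier `10^N(0, 0.3)`, so a significance filter selects the
well-measured peptides. Per-column technical scaling (`sample_log2_sd`)
defaults to 0 — the written matrices are then already normalized; setting
it > 0 produces raw matrices for exercising quantile normalization.

**Determinism.** One seed; per-gene substreams (`SeedSequence.spawn`) for
the transcriptome so a gene's draw does not depend on the others; the
proteome uses a single derived stream because the censoring floor is a
global property. Same seed ⇒ bit-identical datasets.

**What it does not emulate.** Real ionization physics and
missing-at-random dropout beyond the floor rule; charge states and
modifications; junction-spanning peptides at sub-peptide resolution;
within-gene correlation of isoform structure (words are independent draws,
so rare cross-gene word collisions occur and are removed as multi-gene
peptides). Passing tests therefore show the *procedures* behave as
specified under a faithful abstraction of the design, not that any
particular biological dataset would reach a given ρ.

## Design choices where the design was open

* Major-transcript determination uses condition-summarised (median)
  expression, consistent with the fold-change summary, rather than
  per-replicate majors.
* For a switch gene, "regions distinguishing the two majors" is implemented
  at peptide granularity: a peptide must map to exactly one of the two
  majors; one mapping to both is reported (`shared_between_majors`) but
  excluded from isoform-level fold changes.
* Without a switch, mapping to additional minor isoforms does not
  disqualify a peptide from the single major.
* The unique-only strategy needs a discard label for shared peptides;
  `not_unique` was added to the discard-reason vocabulary.
* The heuristic differential classifier
  (`classify_differential_synthetic`) is a documented threshold stand-in
  (gene |log2 FC|, max per-transcript usage shift, retained-isoform rise),
  validated by recovering 100% of constructed DTU/DGE genes in the
  noise-free limit; pipeline runs on synthetic data take their calls from
  ground truth instead, mirroring the fact that differential calls are an
  upstream input.
* DGE correlation pairs the gene RNA FC with each peptide individually (the
  gene-summarised variant is also emitted).

## Problem sizes and known limitations

The analysis drivers and acceptance script use 150–500 genes and 10 seeds
per condition grid point — large enough that strategy comparisons stabilise
(the unique-peptide row then covers ~30–50 transcripts, comparable to the
real study's 30), small enough to run on one CPU in about a minute per
sweep. Single runs at ≤ 200 genes give noisy correlations; aggregate
readouts are the multi-seed means. The Holm-significant peptide subset is
small at these sizes (3–15 points per run), so its correlation is reported
as a multi-seed aggregate; the coding-fraction contrast among IR genes is
likewise underpowered in single desk-scale runs and is reported
descriptively.
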