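# isopept

Transcriptome-guided integration of quantitative mass-spectrometry peptides
with transcript isoforms: does a change in mRNA splicing show up in the
proteome?

`isopept` is for computational biologists who have, for a two-condition
experiment, (a) transcript-level RNA-seq expression estimates, (b) upstream
differential calls — differential transcript usage (DTU), differential gene
expression (DGE), intron retention (IR) — and (c) a peptide intensity matrix
from DIA/SWATH-style MS, and want to ask how concordant the two layers are.
The hard part is that most tryptic peptides map to several isoforms of a
gene. The package implements three assignment strategies and quantifies what
each buys you:

* **unique-only** — keep peptides mapping to a single isoform, and only when
  that isoform carries a DTU call;
* **major-guided** — use transcript abundance: per gene, peptides are
  allocated to the *major* (most highly expressed) transcript per condition;
  when the major's identity switches between conditions, only peptides in the
  regions distinguishing the two majors are allocated, and a peptide shared
  by both majors is reported but excluded from per-isoform fold changes;
* **expression-agnostic** — allocate a peptide iff exactly one of its
  isoforms carries a DTU call, regardless of expression; peptides touching
  two or more DTU isoforms are ambiguous and dropped.

## Model and statistics

For transcript *t* with per-condition median expression
$\tilde{x}_t^{(c)}$, the RNA fold change is
$\mathrm{FC}^{RNA}_t = \log_2\!\big(\tilde{x}_t^{(depleted)}/\tilde{x}_t^{(control)}\big)$.
Peptide intensities are quantile-normalized across samples; the protein-level
fold change of a transcript sums its allocated peptides' intensities per
replicate and takes the log2 ratio of condition medians (a median-of-peptide-
fold-changes variant is also provided). Concordance is Spearman's ρ (Pearson
as comparison) plus the percentage of targets whose RNA and protein fold
changes agree in sign. IR genes are compared with non-IR genes by a two-sided
rank-sum test on gene-level protein fold changes and a Fisher-exact 2×2 of
down-regulated counts with the cross-product odds ratio
$(a/(n_1-a))/(b/(n_2-b))$. Per-peptide significance is a Welch t-test on
log2 intensities with Holm adjustment (significant: adjusted p < 0.1).

Because real RNA-seq + SWATH data cannot ship with the package, a first-class
synthetic-data generator (`isopept.synthetic_data`) emulates the study
design: two conditions × 3 replicates, log-normal FPKM-like totals,
major-dominated isoform mixes, DTU/switch/DGE/IR gene classes with ground
truth, shared + isoform-specific protein blocks so all peptide uniqueness
classes arise, and censoring of peptides below a ~4.4-order dynamic-range
floor. See `docs/methods.md` for every parameter and its rationale.

## Worked example

```bash
isopept simulate --out data --seed 0 --n-genes 400
isopept run --data-dir data --out out --normalized
```

The `simulate` step prints the dataset census:

```
simulated 400 genes (seed 0):
  dge     80
  dtu     40
  ir      60
  null    200
  switch  20
  transcripts 1034, detected peptides 2160
wrote 6 files to data
```

and `run` prints the four strategy × peptide-set summary rows (columns
truncated here):

```
    strategy_row  n_transcripts  n_peptides  spearman_rho  agreement_pct
  dtu_all_unique             49          88      0.498980        71.4286
     dtu_all_all             59         232      0.325015        62.7119
dtu_major_unique             36          65      0.368855        72.2222
   dtu_major_all             38         111      0.525331        73.6842
IR vs non-IR protein FC: rank-sum p = 3.76e-07, odds ratio = 8.212
DGE rho (all peptides) = 0.708, (significant) = 1.000
reports written to out
```

Reading: 88 uniquely mapping peptides cover 49 DTU transcripts with rank
concordance ρ ≈ 0.50 and ~71% sign agreement; abundance-guided assignment
(`dtu_major_all`) keeps that concordance (ρ ≈ 0.53) while allocating 111
peptides, whereas ignoring abundance (`dtu_all_all`) grows the set to 232
peptides but drops ρ to 0.33 — shared peptides are only informative when
transcript abundance guides their assignment. Genes with a rising
retained-intron isoform make measurably less protein (rank-sum p ≈ 4·10⁻⁷).

At realistic scale, the numbered drivers under `analysis/` run the full
study: `01` writes a 400-gene reference dataset, `02` compares the four
strategy rows on it, `03` sweeps measurement noise, `04` runs the
intron-retention analysis, `05` the DGE/proteome correlation. Each writes
its tables under `results/`.

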