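#!/usr/bin/env python
"""How far do gene-expression changes propagate into the proteome?

Correlates gene-level RNA fold changes of DGE genes with the fold changes of
the peptides mapping to them, overall and restricted to peptides whose Welch
t-test survives Holm adjustment (adjusted p < 0.1).  Non-DGE genes provide
the background contrast.  Writes results/dge_correlation.tsv.
"""
from pathlib import Path

import pandas as pd

import isopept as ip

OUT = Path(__file__).resolve().parents[1] / "results" / "dge_correlation.tsv"


def main() -> None:
    cfg = ip.SimulationConfig(n_genes=400, seed=7)
    res = ip.run_on_dataset(ip.simulate_dataset(cfg))
    dge = res.dge
    rows = []
    for name, summ in (
        ("dge_all_peptides", dge.all_peptides),
        ("dge_significant_peptides", dge.significant_peptides),
        ("dge_gene_summarised", dge.gene_summarised),
        ("non_dge_genes", dge.non_dge_genes),
    ):
        rows.append(
            {
                "subset": name,
                "n_points": summ.n_transcripts,
                "spearman_rho": round(summ.spearman_rho, 3),
                "spearman_p": summ.spearman_p,
            }
        )
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(OUT, sep="\t", index=False)
    print(frame.to_string(index=False))
    print(
        f"\nDGE-gene peptides track RNA (rho {dge.all_peptides.spearman_rho:.2f}) "
        f"while the non-DGE background does not "
        f"(rho {dge.non_dge_genes.spearman_rho:.2f}); the Holm-significant "
        f"subset is small here ({dge.significant_peptides.n_transcripts} points, "
        f"rho {dge.significant_peptides.spearman_rho:.2f}) - single runs are "
        f"noisy, the multi-seed aggregate in scripts/acceptance.py is the "
        f"stable readout"
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
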