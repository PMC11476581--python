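#!/usr/bin/env python
"""Simulate the default synthetic study and write it to disk.

Six TCGA-like cohorts of 500 samples x 2,000 genes: an 8-gene MHC-I
signature driven by a latent interferon-activity variable, 25 planted
negative regulators anti-correlated with it (5 doubling as essential
dual-effectors in a 40-line cell panel), immune fractions coupled to
the latent activity, and four survival endpoints with hazards
increasing in planted-gene expression.
"""

import json
from pathlib import Path

from mhcscreen import io as mio
from mhcscreen.simulate import SimulationConfig, simulate_bulk_cohort, simulate_cellline_panel

SEED = 1
# full matrices are large; they go under scratch/ and are regenerated on demand
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    cohort = simulate_bulk_cohort(cfg)
    panel = simulate_cellline_panel(cfg)

    mio.write_expression_matrix(cohort.expression, OUT / "expression.tsv")
    mio.write_clinical_table(cohort.clinical, OUT / "clinical.tsv")
    mio.write_gmt(cohort.signature, OUT / "signature.gmt")
    cohort.fractions.to_frame().to_csv(OUT / "fractions.tsv", sep="\t")
    panel.dependency.to_csv(OUT / "dependency.tsv", sep="\t")
    mio.write_expression_matrix(panel.expression, OUT / "cellline_expression.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps({
        "planted_negative": cohort.truth.planted_negative,
        "planted_dual": cohort.truth.planted_dual,
        "signature_genes": cohort.truth.signature_genes,
        "hazard_beta": cohort.truth.hazard_beta,
        "seed": SEED,
    }, indent=2) + "\n")

    print(f"wrote {cohort.expression.n_genes} genes x {cohort.expression.n_samples} samples "
          f"({cfg.n_cohorts} cohorts), {panel.expression.n_samples} cell lines -> {OUT}")
    print(f"planted: {len(cohort.truth.planted_negative)} negative regulators, "
          f"{len(cohort.truth.planted_dual)} dual-effectors")


if __name__ == "__main__":
    main()
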