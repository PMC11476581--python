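#!/usr/bin/env python
"""Score the focal cohort against the MHC-I signature and look at how
planted negative regulators separate from decoys in the correlation
between gene expression and the score."""

from pathlib import Path

import numpy as np
import pandas as pd

from mhcscreen.scoring import gsva_score, spearman
from mhcscreen.simulate import SimulationConfig, simulate_bulk_cohort

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = simulate_bulk_cohort(SimulationConfig(seed=SEED))
    focal = cohort.expression.subset_samples(cohort.clinical.samples_in_cohort("BRCA"))
    scores = gsva_score(focal, cohort.signature)["MHC1"]
    pd.Series(scores.scores, index=scores.unit_ids, name="mhc1_gsva").to_csv(
        OUT / "signature_scores.tsv", sep="\t")

    rows = []
    for gene in focal.gene_ids:
        if gene in set(cohort.truth.signature_genes):
            continue
        r = spearman(focal.gene_values(gene), scores.scores)
        kind = "planted" if gene in set(cohort.truth.planted_negative) else "decoy"
        rows.append({"gene": gene, "kind": kind, "rho": r.rho, "p": r.p_value})
    df = pd.DataFrame(rows).set_index("gene")
    scratch = OUT.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    df.to_csv(scratch / "signature_correlations_full.tsv", sep="\t")
    df[(df.kind == "planted") | (df.rho <= -0.15)].to_csv(
        OUT / "signature_correlations_hits.tsv", sep="\t")

    planted = df[df.kind == "planted"]["rho"]
    decoys = df[df.kind == "decoy"]["rho"]
    print(f"planted rho: median {planted.median():.3f} "
          f"(range {planted.min():.3f} .. {planted.max():.3f})")
    print(f"decoy rho:   median {decoys.median():.3f}, "
          f"{(decoys <= -0.15).mean() * 100:.2f}% below the -0.15 cutoff")
    print(f"planted below cutoff: {(planted <= -0.15).mean() * 100:.0f}%")


if __name__ == "__main__":
    main()
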