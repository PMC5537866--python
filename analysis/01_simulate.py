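#!/usr/bin/env python
"""Generate the synthetic study cohort.

A 500-sample, 2,000-probe methylation cohort with two correlated weekly
servings exposures (fruit, juice), chip/chip-position batch effects, three
latent cell-composition factors, and planted exposure-associated CpG sets:
50 fruit-only, 50 juice-only, 25 shared-concordant, 25 shared-discordant.
Writes all tables plus the truth tables under results/simulated/.
"""

import pathlib

from dietmeth import io
from dietmeth.config import EffectConfig
from dietmeth.simulate import (generate_gene_sets, generate_methylation,
                               generate_phenotypes, generate_probe_annotation,
                               generate_region_sets)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "simulated"
N_SAMPLES = 500

config = EffectConfig(seed=20170714)   # one master seed for the whole study


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config.to_yaml(OUT / "config.yaml")

    pheno = generate_phenotypes(N_SAMPLES, config)
    beta, detp, truth = generate_methylation(pheno, config)
    # ~2k genes over the simulated 5 Mb gene territories gives ~25 kb TSS
    # spacing, so a realistic ~40% of probes fall within the 5 kb window
    ann, tss, nearest = generate_probe_annotation(
        config.n_probes_total, 2000, config)

    io.write_table(pheno, OUT / "phenotypes.tsv")
    io.write_matrix(beta, OUT / "beta.tsv")
    io.write_matrix(detp, OUT / "detection_p.tsv")
    io.write_table(ann, OUT / "probe_annotation.tsv")
    io.write_table(tss, OUT / "tss.tsv")
    io.write_table(truth, OUT / "truth_probes.tsv")
    io.write_table(nearest, OUT / "truth_nearest_tss.tsv")

    # gene sets over all simulated genes, with one set enriched for genes
    # near planted fruit probes (filled in by later stages as the oracle)
    gene_sets = generate_gene_sets(list(tss["gene_id"]), n_sets=40,
                                   set_size=25, seed=config.seed)
    io.write_gmt(gene_sets, OUT / "gene_sets.gmt")

    planted = truth.loc[truth["set"] != "null", "probe_id"]
    region_sets = generate_region_sets(
        ann, ["NK", "Tcell", "Bcell", "Monocyte"], list(planted),
        enrichment_factor=5, enriched_cell_type="NK", seed=config.seed)
    for ct, regions in region_sets.items():
        io.write_bed(regions, OUT / f"regions_{ct}.bed")

    print(f"cohort: {N_SAMPLES} samples x {config.n_probes_total} probes")
    print(truth["set"].value_counts().to_string())
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
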