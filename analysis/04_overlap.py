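#!/usr/bin/env python
"""Signature overlap: permutation nulls and gene-level partition.

Quantifies (1) low-P-value enrichment of each signature under permuted
exposure, (2) the CpG-level overlap of the fruit and juice signatures
against the random-subset null, (3) the nearest-TSS gene mapping and the
gene-level overlap null, and (4) the same/opposite-direction partition of
shared genes. Writes a JSON summary and the partition id lists.
"""

import json
import pathlib

import pandas as pd

from dietmeth import io
from dietmeth.annotate import map_probes_to_genes, partition_signatures
from dietmeth.ewas import Signature, energy_adjust, extract_signature
from dietmeth.resampling import low_p_enrichment_test, overlap_permutation_test

RES = pathlib.Path(__file__).resolve().parent.parent / "results"
SIM, PRE, EW, OUT = (RES / "simulated", RES / "preprocessed", RES / "ewas",
                     RES / "overlap")
N_PERM = 1000


def load_signature(exposure: str, threshold: float, tag: str) -> Signature:
    result = pd.read_csv(EW / f"ewas_{exposure}.tsv", sep="\t",
                         index_col="probe_id")
    return extract_signature(result, threshold, exposure)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = io.read_phenotypes(SIM / "phenotypes.tsv")
    beta = io.read_matrix(PRE / "beta_adjusted.tsv")
    svs = pd.read_csv(PRE / "surrogate_variables.tsv", sep="\t",
                      index_col=0).to_numpy()
    svs = svs if svs.shape[1] else None
    ann = io.read_table(SIM / "probe_annotation.tsv")
    tss = io.read_table(SIM / "tss.tsv")

    summary: dict = {}
    sigs = {}
    for exposure in ("fruit", "juice"):
        sig = load_signature(exposure, 0.01, "p01")
        sigs[exposure] = sig
        x = energy_adjust(pheno[f"{exposure}_servings"], pheno["total_energy"])
        enr = low_p_enrichment_test(beta, x, svs, sig, n_perm=200, seed=1)
        summary[f"{exposure}_low_p_sites"] = len(sig)
        summary[f"{exposure}_enrichment_empirical_p"] = enr.empirical_p
        summary[f"{exposure}_enrichment_n_elevated"] = enr.n_elevated
        print(f"{exposure}: {len(sig)} sites, low-P enrichment empirical "
              f"P = {enr.empirical_p:.4g} ({enr.n_elevated}/200 permutations "
              "elevated)")

    universe = list(beta.columns)
    observed = len(sigs["fruit"].probe_set() & sigs["juice"].probe_set())
    cpg = overlap_permutation_test(len(universe), len(sigs["fruit"]),
                                   len(sigs["juice"]), observed,
                                   n_perm=N_PERM, seed=2)
    summary["cpg_overlap"] = {
        "observed": observed, "expected": cpg.expected_overlap,
        "analytic_expected": cpg.analytic_expected,
        "fold": cpg.fold_enrichment, "empirical_p": cpg.empirical_p}
    print(f"CpG overlap: {observed} observed vs {cpg.expected_overlap:.1f} "
          f"expected (empirical P = {cpg.empirical_p:.4g})")

    gmap = map_probes_to_genes(ann, tss)
    io.write_table(gmap, OUT / "probe_gene_map.tsv")
    part = partition_signatures(sigs["fruit"], sigs["juice"], gmap)
    for name in ("shared_genes", "a_only_genes", "b_only_genes",
                 "same_direction_genes", "opposite_direction_genes"):
        io.write_id_list(sorted(getattr(part, name)), OUT / f"{name}.txt")
    summary["partition"] = part.summary()

    gmap_idx = gmap.dropna(subset=["gene_id"]).set_index("probe_id")
    gene_universe = sorted(set(gmap_idx.loc[gmap_idx.index.intersection(
        universe), "gene_id"]))
    genes_f = part.shared_genes | part.a_only_genes
    genes_j = part.shared_genes | part.b_only_genes
    gene = overlap_permutation_test(len(gene_universe), len(genes_f),
                                    len(genes_j), len(part.shared_genes),
                                    n_perm=N_PERM, seed=3)
    summary["gene_overlap"] = {
        "observed": len(part.shared_genes), "expected": gene.expected_overlap,
        "fold": gene.fold_enrichment, "empirical_p": gene.empirical_p}
    print(f"gene overlap: {len(part.shared_genes)} observed vs "
          f"{gene.expected_overlap:.1f} expected "
          f"({gene.fold_enrichment:.2f}-fold, "
          f"empirical P = {gene.empirical_p:.4g}); "
          f"{len(part.same_direction_genes)} same-direction / "
          f"{len(part.opposite_direction_genes)} opposite-direction")

    with open(OUT / "overlap_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
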