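#!/usr/bin/env python
"""Probe QC, batch adjustment and surrogate variables for the cohort.

Filters sex-chromosome / detection-failing / multimap / SNP probes, removes
chip and chip-position effects while protecting the two exposures, checks
which covariates drive the principal components, and estimates surrogate
variables on the adjusted matrix. Writes the adjusted beta matrix, the
filter report, the PCA association table and the SV matrix.
"""

import pathlib

import pandas as pd

from dietmeth import io
from dietmeth.batch import adjust_chip_and_position
from dietmeth.preprocess import filter_probes
from dietmeth.sva import estimate_surrogate_variables, pca_covariate_association
from dietmeth.transform import beta_to_m

RES = pathlib.Path(__file__).resolve().parent.parent / "results"
SIM, OUT = RES / "simulated", RES / "preprocessed"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = io.read_phenotypes(SIM / "phenotypes.tsv")
    beta = io.read_matrix(SIM / "beta.tsv")
    detp = io.read_matrix(SIM / "detection_p.tsv")
    ann = io.read_table(SIM / "probe_annotation.tsv")

    kept, report = filter_probes(beta, detp, ann)
    report.to_frame().to_csv(OUT / "filter_report.tsv", sep="\t", index=False)
    print(f"probes: {report.n_input} in, {report.n_retained} retained "
          f"(sex {report.n_removed_sex}, detection {report.n_removed_detection}, "
          f"multimap {report.n_removed_multimap}, snp {report.n_removed_snp})")

    pca = pca_covariate_association(
        kept, pheno[["chip", "chip_position", "age", "sex"]], n_pc=5)
    io.write_table(pca, OUT / "pca_covariates.tsv")
    top = pca.iloc[0]
    print(f"strongest PC association: PC{int(top['pc'])} ~ {top['covariate']} "
          f"(P = {top['p_value']:.2e})")

    adjusted = adjust_chip_and_position(kept, pheno)
    io.write_matrix(adjusted, OUT / "beta_adjusted.tsv")

    m = pd.DataFrame(beta_to_m(adjusted.to_numpy()), index=adjusted.index,
                     columns=adjusted.columns)
    svs = estimate_surrogate_variables(
        m, pheno[["fruit_servings", "juice_servings"]], max_k=10,
        seed=0)
    svs.as_frame(index=adjusted.index).to_csv(OUT / "surrogate_variables.tsv",
                                              sep="\t", index_label="sample_id")
    io.write_table(svs.diagnostics, OUT / "sv_diagnostics.tsv")
    print(f"surrogate variables retained: k = {svs.k}")


if __name__ == "__main__":
    main()
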