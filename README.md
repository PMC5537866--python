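# dietmeth

An epigenome-wide association (EWAS) pipeline for dietary exposures, built
around the question of whether two closely related foods — fruit and fruit
juice — leave distinct DNA-methylation signatures in peripheral blood
mononuclear cells. Cohorts with 450k-array methylation and food-frequency
data are access-restricted, so the package ships a first-class synthetic
cohort generator with planted ground truth, and every analysis stage is
validated against it.

## Who this is for

Epigenetics analysts who want a tested, end-to-end reference for the
"low-P-value signature" style of EWAS: instead of interpreting individual
genome-wide-significant CpGs, the analysis treats the set of modestly
associated sites (P < 0.01) as a collective fingerprint, then asks whether
two exposures' fingerprints overlap more than chance at the CpG and gene
level, and which cell types' regulatory regions they occupy.

## The model

Per CpG probe *j*, methylation is a beta value β ∈ [0, 1]. After probe QC
(sex chromosomes, detection P > 0.001 in ≥ 75% of samples, multi-mapping
and SNP-overlapping probes), chip and chip-position batch effects are
removed on the logit scale by empirical-Bayes location/scale adjustment
(ComBat-style) while protecting the exposures, and surrogate variables
**Z** are estimated from the residual matrix (SVD + parallel-analysis rank
selection). The association model per probe is

    beta_ij = alpha_j + b_j * x_i + Z_i' * g_j + e_ij

where x is the energy-adjusted exposure (residual of weekly servings on
total energy intake, re-centered). Residual variances are shrunk by
empirical Bayes — posterior s²_post = (d0·s0² + d·s²)/(d0 + d) — giving a
moderated t with d0 + d degrees of freedom (identical to limma's eBayes,
verified against it). Signatures are the probes with P below a threshold;
overlap between two signatures is tested against a null of two independent
uniform subsets (expected overlap a·b/N), and signature CpGs are tested
for enrichment in per-cell-type open-chromatin region sets against uniform
probe redraws. All empirical P-values use the (r + 1)/(n + 1) convention.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (500 samples × 2,000 probes; 50 fruit-only, 50 juice-only, 25
shared-concordant and 25 shared-discordant planted CpGs):

```
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_ewas.py
python analysis/04_overlap.py
python analysis/05_enrichment.py
```

which prints, among other lines:

```
probes: 2000 in, 1808 retained (sex 100, detection 9, multimap 42, snp 41)
surrogate variables retained: k = 3
fruit: 172 low-P sites (P<0.01); planted-probe recall 100%
fruit: 172 sites, low-P enrichment empirical P = 0.004975 (200/200 permutations elevated)
CpG overlap: 53 observed vs 22.1 expected (empirical P = 0.000999)
gene overlap: 10 observed vs 4.2 expected (2.36-fold, empirical P = 0.005994); 5 same-direction / 5 opposite-direction
regions fruit/all (112 sites): top cell type NK (empirical P = 0.000999, z = 10.01)
```

Reading: probe QC removed 192 probes; SVA recovered the three planted
latent cell-composition factors; both exposures' signatures recover every
planted probe and are significantly enriched for low P-values under the
permuted-exposure null (the minimum attainable empirical P at 200
permutations); the two signatures share more CpGs and genes than the
random-subset null expects — the shared CpGs are exactly the planted
shared-concordant/discordant sets plus chance hits — and the designated
"NK" cell type, whose simulated open-chromatin regions were enriched for
planted probes, ranks first in the region-enrichment scan.

Tables land under `results/`. A single-stage CLI (`dietmeth simulate`,
`dietmeth ewas`, `dietmeth overlap`, `dietmeth ora`) is available for
ad-hoc runs on files.

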