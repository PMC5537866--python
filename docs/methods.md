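# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic cohort does and does not establish about
real data.

## Synthetic cohort generator

The generator emulates a food-frequency-questionnaire EWAS on a 450k-style
methylation array.

**Phenotypes.** The two exposures (fruit and juice, weekly servings) are
exponentiated correlated Gaussians rounded to quarter servings: latent
bivariate normal with correlation `exposure_correlation` (default 0.3),
medians ~7 and ~5 servings/week, lognormal sigma 0.5. This gives
nonnegative, right-skewed FFQ-like servings; the observed Pearson
correlation is mildly attenuated relative to the latent one (within ±0.1
at n ≥ 500). No cohort publishes the fruit–juice servings correlation, so
the default is a deliberate, configurable placeholder. Total energy intake
is 1800 kcal/day plus 40 kcal per weekly serving of either exposure plus
N(0, 300) noise, clipped at 800 — enough positive coupling to make the
residuals-method energy adjustment non-trivial. Ages are uniform on 40–92
and the female fraction is 1169/2148, matching the demographic range of
the offspring-generation heart-study cohorts this design emulates. Chips
are filled round-robin (12 samples/chip), which guarantees ≥ 2 samples per
chip for any n ≥ 4. Three latent cell-composition factors are Gaussian,
partially driven by age (factor 1) and sex (factor 2), and centered.
Family structure is a pedigree label only (consecutive triples); no
kinship matrix is simulated.

**Methylation.** Per probe, the logit-scale signal is baseline + chip
effect + chip-position effect + sparse latent loadings + planted exposure
slopes + N(0, `noise_sd`); beta = inverse-logit. Baselines come from a
three-component normal mixture (40% unmethylated ~N(−2, 0.7), 40%
methylated ~N(+2, 0.7), 20% intermediate), reproducing the bimodal 450k
beta distribution. Planted slopes are ±`effect_size` logit units per
weekly serving, with the four set types (A-only, B-only, shared-concordant,
shared-discordant) assigned to randomly chosen probes and recorded in a
truth table. Defaults — 2,000 probes, 50/50/25/25 planted, effect 0.05
logit/serving, noise sd 0.3, chip sd 0.2, position sd 0.05 — are the study
conditions every calibration and recovery test runs at. Detection-P
failures are probe-level events (a failing probe fails in ~90% of
samples), matching the probe-removal reading of array QC; the failing
fraction defaults to 0.5%.

**Seeding.** One master seed; each operation draws from an independent
substream keyed by (seed, operation name), so stages can be re-run in any
order without perturbing one another.

**Annotation.** Probes land uniformly on chr1–22 with a configurable
minority on chrX/chrY (default 5%) to exercise the sex-chromosome filter.
Genes occupy the first ~5 Mb of each chromosome; 15% of probes are placed
in gene deserts beyond every TSS so the 5 kb mapping window is guaranteed
to leave them unassigned. The truth table records each probe's nearest TSS
by brute-force all-pairs scan — deliberately a different algorithm from
the sorted-search used by the mapping module, so the two can check each
other.

**What the generator does not emulate**: raw array intensities, type I/II
probe chemistry and within-array normalization; genomic autocorrelation of
methylation; realistic CpG-island structure; genetic relatedness beyond a
family label; exposure measurement error. Passing tests therefore show the
*statistical machinery* is correct and calibrated under the stated
generative model, not that real-cohort effect sizes would be recovered.

## Preprocessing

**Filtering** removes, with precedence sex > detection > multimap > SNP
(each probe counted once): sex-chromosome probes; probes with detection
P > 0.001 in ≥ 75% of samples (the boundary is inclusive: failing in
exactly 75% removes; 74% retains); flagged multi-mapping probes; flagged
SNP-overlap probes. `fail_fraction` is configurable because many pipelines
use far stricter values (e.g. 0.25 or a per-sample rule).

**Batch adjustment** is parametric empirical-Bayes location/scale
correction. Betas are clipped to [1e−6, 1−1e−6] and logit-transformed
first — the additive location/scale model belongs on an unbounded scale —
and back-transformed afterwards, so the public interface stays on the beta
scale. Per probe, data are standardized against a design of batch
indicators plus the protected exposure columns; per-batch locations get a
normal prior and scales an inverse-gamma prior, both moment-matched across
probes, solved by fixed-point iteration to 1e−4; shrunken effects are
removed and the protected fit restored. The implementation agrees with the
R reference implementation (`sva::ComBat`) to ~1e−5 on shared fixtures.
Chip and chip-position are adjusted sequentially (chip first), each step
protecting both exposures, since no joint two-factor model is specified
for these arrays. A single-batch input is returned unchanged.

*On idempotency:* a second adjustment pass is not a strict no-op. After
one pass the per-batch means are at noise level O(σ/√n_batch), and the
empirical-Bayes shrinkage of a noise-level batch mean removes roughly half
of it, so the second pass moves values by a small but non-negligible
amount (observed ~10% of the first-pass change at 200 samples). This is
intrinsic to the shrinkage estimator, not an implementation artifact; the
property test asserts the realistic contract (second pass ≪ first pass)
rather than exact fixity.

**Surrogate variables.** The exposures are regressed out; the left
singular vectors of the residual matrix are candidate SVs. Rank selection
is parallel analysis: a component is kept when its singular value exceeds
the 90th percentile of same-rank singular values from 20 column-wise
permutations of the residuals, stopping at the first failure and capping
at `max_k`. This rule is deterministic given a seed and easy to calibrate
(pure noise yields k = 0 in ≥ 90% of runs); it replaces iterative
reweighting schemes that have no closed acceptance criterion. Known
covariates (age, sex, relatedness) are intentionally *not* added to the
downstream regression design — the surrogate variables are expected to
capture them, as the diagnostics table lets one verify — though callers
can pass any design they wish.

**PCA diagnostics** associate the top principal components with known
covariates: Pearson correlation test for continuous, one-way ANOVA for
categorical, constants flagged and skipped.

## Association testing

The exposure is energy-adjusted by the residuals method (OLS on total
energy; residuals re-centered at the original mean so units stay
servings/week). Each probe is fit by OLS of beta on intercept + exposure +
SVs. Regression is on the beta scale by default — effect sizes are then
"beta units per weekly serving", directly interpretable as methylation
fraction change — with an M-value switch for users who prefer
variance-stabilized fits. Variance moderation follows the standard
empirical-Bayes scheme: (d0, s0²) estimated from the marginal distribution
of log sample variances (trigamma inversion by Newton iteration), posterior
variance (d0·s0² + d·s²)/(d0 + d), t on d0 + d df; with no excess spread
in the log variances d0 = ∞ and a normal reference is used. The
implementation matches limma's `eBayes` to machine precision on shared
fixtures and is tested in both moderated and unmoderated modes. Probes
with > 5% missing betas are dropped, the rest fit complete-case.

Signatures are probes with P strictly below the threshold (0.01 for the
main signatures, 0.001 for the capped regulatory-region analysis),
ordered by probe id, with slope signs attached.

## Permutation procedures

**Low-P enrichment**: the exposure is permuted, the regression refit on
the signature probes only (SVs fixed), and the permuted P-value
distribution compared with the observed one. Two summaries are reported:
the number of permutations whose P-values are significantly elevated over
the observed ones (one-sided two-sample t-test at 0.05) — a fidelity
readout — and an empirical P defined as the (r+1)/(n+1) fraction of
permutations whose mean P is at or below the observed mean, since the
t-test count alone does not define a probability. Refits inside the loop
use plain OLS; the observed distribution is computed identically so the
comparison is like-for-like.

**Set overlap**: both the CpG-level and gene-level overlap nulls draw two
independent uniform subsets of the id universe without replacement per
permutation and record the intersection size. The analytic mean a·b/N is
computed alongside as an oracle; the permutation distribution matches the
hypergeometric law (verified by exhaustive enumeration on small
universes). Note the arithmetic fact that with a 325,963-probe universe
and signatures of 5,221 and 5,434 sites the expected chance overlap is
≈ 87 sites; published analyses of this design have printed 84, which
implies a slightly restricted universe that is not documented anywhere —
both numbers are surfaced, neither is forced.

**Conventions**: every empirical P uses (r+1)/(n+1) and therefore can
never be zero; the smallest attainable value at 10,000 permutations is
≈ 1×10⁻⁴. Claims below that floor cannot come out of a 10,000-permutation
test and are reported at the floor. All procedures are bit-for-bit
reproducible given (seed, n_perm).

## Gene mapping and enrichment

Probes are assigned to the gene with the nearest TSS by absolute genomic
distance (strand ignored; probe positions 1-based), unmapped beyond 5 kb.
The window is measured probe-to-TSS — the stricter of the two plausible
readings ("within 5 kb of a TSS" vs "within 5 kb of a gene"). Distance
ties break to the lexicographically smallest gene id, making the map a
pure function. Shared genes between two signatures are classified
same-direction vs opposite-direction by the slope sign of each gene's
most significant low-P CpG per analysis; a majority-sign variant would be
a one-line change but the most-significant rule is the default because it
is deterministic under ties and uses the strongest evidence. Gene counts
are of unique gene ids throughout.

Gene-set enrichment is hypergeometric overrepresentation of the
thresholded gene list (sets intersected with an explicit, caller-supplied
universe; BH FDR across sets; rows with q < 5% or the 100 smallest P
flagged for reporting). A weighted running-sum statistic is deliberately
not implemented: the inputs here are thresholded lists, for which ORA is
the standard formulation.

Region enrichment counts signature CpGs inside merged, 0-based half-open
BED intervals per cell type (binary search after a single merge pass;
membership of 1-based position p means p−1 ∈ [start, end)). The null
redraws equally sized probe sets uniformly from the retained-probe
universe. This replaces annotation-matched backgrounds (CpG-island/probe
type matching) used by hosted tools; with the uniform background,
enrichment P-values for probe sets with unusual annotation composition
will be anti-conservative on real arrays — acceptable here because the
synthetic annotation has no such composition structure, but worth noting
before pointing the module at real 450k data. The P < 0.001 signature is
capped at the 1000 most significant sites before this analysis, and also
stratified by slope sign (zero slopes go to the positive stratum with a
warning).

## Problem sizes

Simulated studies run at 500 samples × 2,000 probes (calibration,
recovery), 200 samples × 400–500 probes (batch/SVA checks), and 10,000 or
2,000 permutations for the overlap oracles — sizes at which every
distributional check has comfortable Monte-Carlo resolution while the full
suite and the acceptance script each run in well under a minute. The
cohort-scale overlap arithmetic uses the published counts themselves
(325,963 probes; 5,221/5,434 sites; 108 shared CpGs; 4,323/4,539 genes;
1,246 shared genes vs 804 expected) as inputs.

## Known limitations

* No mixed-model or kinship correction; family structure is a label.
* The uniform region-enrichment background (above).
* Sequential chip→position adjustment is one of several defensible joint
  treatments; with strongly unbalanced designs a joint model would differ.
* Beta-scale regression slightly violates homoskedasticity near the
  bounds; the M-value switch exists for sensitivity analysis.
* The generator's exposure distribution and effect-size defaults are
  field-realistic choices, not estimates from any cohort.
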