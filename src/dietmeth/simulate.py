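"""Synthetic methylation cohort generator.

Emulates the structure of a food-frequency-questionnaire EWAS on a 450k-style
array: two correlated, right-skewed weekly-servings exposures; total energy
intake; chip/chip-position batch effects and latent cell-composition factors
acting on the logit scale; and planted exposure-associated CpG sets
(A-only, B-only, shared-concordant, shared-discordant). Truth tables record
the planted structure so recall/precision of every downstream stage can be
computed.

Reproducibility: one master seed; each operation draws from an independent
substream derived from (seed, operation name).
"""

from __future__ import annotations

import zlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import EffectConfig
from .io import merge_regions
from .transform import m_to_beta

CHROMS = [f"chr{i}" for i in range(1, 23)]
SEX_CHROMS = ["chrX", "chrY"]

# cohort demographics: ages span 40-92, slight female excess, as in large
# offspring-generation heart-study cohorts
AGE_RANGE = (40, 92)
FEMALE_FRACTION = 1169 / 2148


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for one named operation under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))


def probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:06d}" for i in range(n)], name="probe_id")


# ------------------------------------------------------------- phenotypes

def generate_phenotypes(n_samples: int, config: EffectConfig) -> pd.DataFrame:
    """Simulate the phenotype table: exposures, energy, demographics, batches.

    Exposures are exponentiated correlated Gaussians rounded to
    quarter-servings (right-skewed, nonnegative, FFQ-like). Total energy is
    positively correlated with both exposures. Chips are assigned round-robin
    so every chip holds at least two samples; latent cell-composition factors
    are Gaussian, partially driven by age and sex, and centered to zero mean.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4 to form batches")
    config.validate()
    rng = substream(config.seed, "phenotypes")

    r = config.exposure_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]],
                                size=n_samples)
    # median ~7 fruit and ~5 juice servings/week, lognormal sigma 0.5
    fruit = np.round(4 * np.exp(np.log(7) + 0.5 * z[:, 0])) / 4
    juice = np.round(4 * np.exp(np.log(5) + 0.5 * z[:, 1])) / 4

    energy = 1800 + 40 * (fruit + juice) + rng.normal(0, 300, n_samples)
    energy = np.clip(energy, 800, None)

    age = rng.uniform(*AGE_RANGE, n_samples)
    sex = np.where(rng.random(n_samples) < FEMALE_FRACTION, "F", "M")

    n_chips = max(1, int(np.ceil(n_samples / config.chip_size)))
    if n_samples // n_chips < 2:          # round-robin guarantees >=2 per chip
        n_chips = n_samples // 2
    idx = np.arange(n_samples)
    chip = idx % n_chips
    chip_position = idx // n_chips + 1

    pedigree = idx // 3                   # small family clusters

    latent = rng.normal(0, 1, (n_samples, config.n_latent))
    if config.n_latent >= 1:
        latent[:, 0] += 0.03 * (age - age.mean())
    if config.n_latent >= 2:
        latent[:, 1] += 0.5 * (sex == "F")
    latent -= latent.mean(axis=0, keepdims=True)

    df = pd.DataFrame({
        "sample_id": [f"s{i:05d}" for i in idx],
        "fruit_servings": fruit,
        "juice_servings": juice,
        "total_energy": energy,
        "age": age,
        "sex": sex,
        "chip": [f"chip{c:03d}" for c in chip],
        "chip_position": [f"R{p:02d}" for p in chip_position],
        "pedigree_id": [f"fam{f:05d}" for f in pedigree],
    })
    for k in range(config.n_latent):
        df[f"latent_{k + 1}"] = latent[:, k]
    return df


def latent_columns(phenotypes: pd.DataFrame) -> list[str]:
    return [c for c in phenotypes.columns if c.startswith("latent_")]


# ------------------------------------------------------------ methylation

def generate_methylation(
    phenotypes: pd.DataFrame, config: EffectConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate beta values, detection P-values, and the planted-probe truth.

    Per probe j and sample i the logit-scale signal is

        m_ij = baseline_j + chip_j[chip_i] + pos_j[slot_i]
               + loadings_j . latent_i + slopeA_j * fruit_i
               + slopeB_j * juice_i + eps_ij,

    with exposures centered, eps ~ N(0, noise_sd), and beta = expit(m). The
    baseline is drawn from a three-component mixture mimicking the bimodal
    450k beta distribution. Planted probes carry slope +/- effect_size per
    their set; the truth table records set membership and slopes.
    """
    if len(phenotypes) == 0:
        raise ValueError("phenotypes table is empty")
    config.validate()
    rng = substream(config.seed, "methylation")

    n = len(phenotypes)
    p = config.n_probes_total
    probes = probe_ids(p)
    samples = phenotypes["sample_id"].astype(str).to_numpy()

    # planted set assignment, randomized over probe indices
    sets = np.array(["null"] * p, dtype=object)
    order = rng.permutation(p)
    bounds = np.cumsum([config.n_a_only, config.n_b_only,
                        config.n_shared_concordant,
                        config.n_shared_discordant])
    sets[order[:bounds[0]]] = "a_only"
    sets[order[bounds[0]:bounds[1]]] = "b_only"
    sets[order[bounds[1]:bounds[2]]] = "shared_concordant"
    sets[order[bounds[2]:bounds[3]]] = "shared_discordant"

    sign = rng.choice([-1.0, 1.0], size=p)
    slope_a = np.zeros(p)
    slope_b = np.zeros(p)
    es = config.effect_size
    slope_a[sets == "a_only"] = es * sign[sets == "a_only"]
    slope_b[sets == "b_only"] = es * sign[sets == "b_only"]
    for s in ("shared_concordant", "shared_discordant"):
        m = sets == s
        slope_a[m] = es * sign[m]
        slope_b[m] = es * sign[m] * (1 if s == "shared_concordant" else -1)

    # bimodal baseline: unmethylated, methylated, intermediate
    comp = rng.choice(3, size=p, p=[0.4, 0.4, 0.2])
    baseline = np.where(comp == 0, rng.normal(-2.0, 0.7, p),
                        np.where(comp == 1, rng.normal(2.0, 0.7, p),
                                 rng.normal(0.0, 0.7, p)))

    chips, chip_idx = np.unique(phenotypes["chip"].astype(str), return_inverse=True)
    slots, slot_idx = np.unique(phenotypes["chip_position"].astype(str),
                                return_inverse=True)
    chip_fx = rng.normal(0, config.batch_sd, (len(chips), p))
    slot_fx = rng.normal(0, config.position_sd, (len(slots), p))

    lat_cols = latent_columns(phenotypes)
    latent = phenotypes[lat_cols].to_numpy() if lat_cols else np.zeros((n, 0))
    loadings = rng.normal(0, config.latent_loading_sd, (latent.shape[1], p))
    loadings *= rng.random((latent.shape[1], p)) < config.loading_sparsity

    fruit_c = phenotypes["fruit_servings"].to_numpy(dtype=float)
    juice_c = phenotypes["juice_servings"].to_numpy(dtype=float)
    fruit_c = fruit_c - fruit_c.mean()
    juice_c = juice_c - juice_c.mean()

    m = (baseline[None, :]
         + chip_fx[chip_idx, :]
         + slot_fx[slot_idx, :]
         + latent @ loadings
         + np.outer(fruit_c, slope_a)
         + np.outer(juice_c, slope_b)
         + rng.normal(0, config.noise_sd, (n, p)))
    beta = pd.DataFrame(m_to_beta(m), index=pd.Index(samples, name="sample_id"),
                        columns=probes)

    # detection P: probe-level failure events
    detp = rng.uniform(0, 5e-4, (n, p))
    n_fail = int(round(config.detection_fail_probe_fraction * p))
    fail_probes = rng.choice(p, size=n_fail, replace=False)
    for j in fail_probes:
        bad = rng.random(n) < config.detection_fail_sample_rate
        detp[bad, j] = rng.uniform(0.01, 1.0, bad.sum())
    detp = pd.DataFrame(detp, index=beta.index, columns=probes)

    truth = pd.DataFrame({
        "probe_id": probes,
        "set": sets,
        "slope_a": slope_a,
        "slope_b": slope_b,
        "detection_fail": np.isin(np.arange(p), fail_probes),
    })
    return beta, detp, truth


# -------------------------------------------------------------- annotation

def generate_probe_annotation(
    n_probes: int, n_genes: int, config: EffectConfig,
    desert_fraction: float = 0.15, window: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate probe genomic annotation, a gene TSS table, and nearest truth.

    Probes land on autosomes plus a ``sex_probe_fraction`` minority on
    chrX/chrY (to exercise the sex-chromosome filter). Genes occupy the first
    5 Mb of each chromosome; a ``desert_fraction`` of probes is placed beyond
    every gene so they are guaranteed unmappable within ``window``. QC flags
    (multimap, SNP overlap) are set on configured fractions. The truth table
    records each probe's nearest TSS and distance by brute-force all-pairs
    scan.
    """
    if n_probes < 1 or n_genes < 1:
        raise ValueError("n_probes and n_genes must be >= 1")
    rng = substream(config.seed, "annotation")

    probes = probe_ids(n_probes)
    n_sex = int(round(config.sex_probe_fraction * n_probes))
    is_sex = np.zeros(n_probes, dtype=bool)
    is_sex[rng.choice(n_probes, size=n_sex, replace=False)] = True

    gene_span = (100_000, 5_000_000)
    desert_span = (gene_span[1] + 2 * window, gene_span[1] + 2_000_000)

    chrom = np.empty(n_probes, dtype=object)
    chrom[~is_sex] = rng.choice(CHROMS, size=(~is_sex).sum())
    chrom[is_sex] = rng.choice(SEX_CHROMS, size=n_sex)

    n_desert = int(np.ceil(desert_fraction * n_probes))
    is_desert = np.zeros(n_probes, dtype=bool)
    is_desert[rng.choice(n_probes, size=n_desert, replace=False)] = True
    pos = np.where(is_desert,
                   rng.integers(*desert_span, size=n_probes),
                   rng.integers(*gene_span, size=n_probes)).astype(np.int64)

    annotation = pd.DataFrame({
        "probe_id": probes,
        "chrom": chrom,
        "pos": pos,
        "sex_chromosome": is_sex,
        "multimap": rng.random(n_probes) < config.multimap_fraction,
        "snp_overlap": rng.random(n_probes) < config.snp_fraction,
    })

    gene_chrom = rng.choice(CHROMS + ["chrX"], size=n_genes)
    tss = pd.DataFrame({
        "gene_id": [f"GENE{i:05d}" for i in range(n_genes)],
        "chrom": gene_chrom,
        "tss_pos": rng.integers(*gene_span, size=n_genes).astype(np.int64),
        "strand": rng.choice(["+", "-"], size=n_genes),
    })

    truth = _brute_force_nearest(annotation, tss, window)
    return annotation, tss, truth


def _brute_force_nearest(annotation: pd.DataFrame, tss: pd.DataFrame,
                         window: int) -> pd.DataFrame:
    """All-pairs nearest-TSS scan; ties broken by smallest gene id."""
    rows = []
    tss_by_chrom = dict(tuple(tss.groupby("chrom")))
    for _, pr in annotation.iterrows():
        cand = tss_by_chrom.get(pr["chrom"])
        gene, dist = None, None
        if cand is not None:
            d = (cand["tss_pos"] - pr["pos"]).abs()
            best = d.min()
            if best <= window:
                gene = cand.loc[d == best, "gene_id"].min()
                dist = int(best)
        rows.append((pr["probe_id"], gene, dist))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "tss_distance"])


# ------------------------------------------------------------- region sets

def generate_region_sets(
    annotation: pd.DataFrame,
    cell_types: Sequence[str],
    enriched_probe_set: Iterable[str],
    enrichment_factor: float,
    enriched_cell_type: str | None = None,
    background_rate: float = 0.1,
    half_width: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate per-cell-type open-chromatin (DHS-style) BED region sets.

    Each probe is covered by a small region with probability
    ``background_rate``; in the designated enriched cell type, probes of
    ``enriched_probe_set`` are covered at ``enrichment_factor`` times that
    rate (capped at 0.95). Returned intervals are 0-based half-open, merged.
    """
    if len(cell_types) == 0:
        raise ValueError("cell_types must be non-empty")
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if enriched_cell_type is None:
        enriched_cell_type = cell_types[0]
    rng = substream(seed, "region_sets")
    enriched = set(enriched_probe_set)
    in_set = annotation["probe_id"].isin(enriched).to_numpy()
    pos0 = annotation["pos"].to_numpy(dtype=np.int64) - 1  # 1-based -> 0-based

    out: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        p_cover = np.full(len(annotation), background_rate)
        if ct == enriched_cell_type:
            p_cover[in_set] = min(0.95, background_rate * enrichment_factor)
        covered = rng.random(len(annotation)) < p_cover
        regions = pd.DataFrame({
            "chrom": annotation.loc[covered, "chrom"].to_numpy(),
            "start": np.maximum(0, pos0[covered] - half_width),
            "end": pos0[covered] + half_width + 1,
        })
        if len(regions) == 0:
            regions = pd.DataFrame(columns=["chrom", "start", "end"])
        else:
            regions = merge_regions(regions)
        out[ct] = regions
    return out


# --------------------------------------------------------------- gene sets

def generate_gene_sets(
    genes: Sequence[str], n_sets: int = 50, set_size: int = 20,
    enriched_genes: Iterable[str] | None = None, seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene sets for overrepresentation testing.

    If ``enriched_genes`` is given, the first set (``SET_ENRICHED``) is drawn
    mostly (80%) from that list so a planted enrichment exists.
    """
    rng = substream(seed, "gene_sets")
    genes = list(genes)
    out: dict[str, set[str]] = {}
    if enriched_genes is not None:
        pool = list(enriched_genes)
        n_from_pool = min(len(pool), int(0.8 * set_size))
        chosen = list(rng.choice(pool, size=n_from_pool, replace=False))
        rest = [g for g in genes if g not in set(chosen)]
        chosen += list(rng.choice(rest, size=set_size - n_from_pool,
                                  replace=False))
        out["SET_ENRICHED"] = set(chosen)
    for i in range(n_sets):
        out[f"SET{i:03d}"] = set(rng.choice(genes, size=min(set_size, len(genes)),
                                            replace=False))
    return out
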