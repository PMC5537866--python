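"""CpG-to-gene assignment and signature set arithmetic.

Probes are assigned to the gene with the nearest transcription start site
(absolute genomic distance on the same chromosome, strand ignored) and left
unmapped when the nearest TSS is farther than the window (5 kb by default).
Two signatures are then partitioned into shared / exposure-specific probe
and gene sets, and shared genes are classified as same-direction or
opposite-direction by comparing the slope sign of each gene's most
significant low-P CpG in the two analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewas import Signature

DEFAULT_TSS_WINDOW = 5000


def map_probes_to_genes(annotation: pd.DataFrame, tss: pd.DataFrame,
                        window: int = DEFAULT_TSS_WINDOW) -> pd.DataFrame:
    """Nearest-TSS assignment of probes to genes within ``window`` bp.

    ``annotation`` needs (probe_id, chrom, pos) with 1-based positions;
    ``tss`` needs (gene_id, chrom, tss_pos). Distance ties are broken by the
    lexicographically smallest gene id. Returns (probe_id, gene_id,
    tss_distance) with gene_id = NA for unmapped probes.
    """
    ann_chroms = set(annotation["chrom"].astype(str))
    tss_chroms = set(tss["chrom"].astype(str))
    if not ann_chroms & tss_chroms:
        offenders = sorted(ann_chroms)
        raise ValueError(
            "no shared chromosome names between probe annotation and TSS "
            f"table; probe chromosomes: {', '.join(offenders[:10])}")
    stripped = {c.removeprefix("chr") for c in tss_chroms}
    mism = sorted(c for c in ann_chroms - tss_chroms
                  if c.removeprefix("chr") in stripped)
    if mism:
        raise ValueError("chromosome naming mismatch between tables for: "
                         + ", ".join(mism))

    # per chromosome: sorted unique TSS positions with the smallest gene id
    # at each position, so ties resolve deterministically
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in tss.groupby("chrom"):
        agg = grp.groupby("tss_pos")["gene_id"].min().sort_index()
        per_chrom[str(chrom)] = (agg.index.to_numpy(dtype=np.int64),
                                 agg.to_numpy(dtype=object))

    gene_out = np.full(len(annotation), None, dtype=object)
    dist_out = np.full(len(annotation), np.nan)
    chroms = annotation["chrom"].astype(str).to_numpy()
    pos = annotation["pos"].to_numpy(dtype=np.int64)
    for chrom in np.unique(chroms):
        if chrom not in per_chrom:
            continue
        tpos, tgene = per_chrom[chrom]
        sel = np.flatnonzero(chroms == chrom)
        idx = np.searchsorted(tpos, pos[sel])
        left = np.clip(idx - 1, 0, len(tpos) - 1)
        right = np.clip(idx, 0, len(tpos) - 1)
        dl = np.abs(pos[sel] - tpos[left])
        dr = np.abs(pos[sel] - tpos[right])
        for k, i in enumerate(sel):
            cand = []
            if dl[k] <= window:
                cand.append((dl[k], tgene[left[k]]))
            if dr[k] <= window:
                cand.append((dr[k], tgene[right[k]]))
            if cand:
                best = min(cand)       # distance first, then gene id
                dist_out[i] = best[0]
                gene_out[i] = best[1]
    return pd.DataFrame({
        "probe_id": annotation["probe_id"].to_numpy(),
        "gene_id": gene_out,
        "tss_distance": pd.array(
            [int(d) if np.isfinite(d) else pd.NA for d in dist_out],
            dtype="Int64"),
    })


@dataclass
class SignaturePartition:
    """Shared / specific probe and gene sets of two signatures."""
    shared_probes: set[str]
    a_only_probes: set[str]
    b_only_probes: set[str]
    shared_genes: set[str]
    a_only_genes: set[str]
    b_only_genes: set[str]
    same_direction_genes: set[str]
    opposite_direction_genes: set[str]

    def summary(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in (
            "shared_probes", "a_only_probes", "b_only_probes",
            "shared_genes", "a_only_genes", "b_only_genes",
            "same_direction_genes", "opposite_direction_genes")}


def _gene_sign(sig: Signature, probes_of_gene: dict[str, list[str]],
               gene: str) -> int:
    """Slope sign of the gene's most significant CpG in one analysis."""
    probes = probes_of_gene[gene]
    best = min(probes, key=lambda pr: (sig.pvalues[pr], pr))
    return int(sig.directions[best])


def partition_signatures(sig_a: Signature, sig_b: Signature,
                         probe_gene_map: pd.DataFrame) -> SignaturePartition:
    """Partition two signatures at the CpG and gene level.

    Gene sets contain the unique genes mapped from each signature's probes;
    a shared gene is same-direction when the slope sign of its most
    significant low-P CpG agrees between the two analyses.
    """
    a, b = sig_a.probe_set(), sig_b.probe_set()
    shared_p, a_only_p, b_only_p = a & b, a - b, b - a

    gmap = probe_gene_map.dropna(subset=["gene_id"]).set_index("probe_id")

    def genes_and_probes(probes: set[str]):
        sub = gmap.loc[gmap.index.intersection(list(probes))]
        per_gene: dict[str, list[str]] = {}
        for pid, gene in sub["gene_id"].items():
            per_gene.setdefault(gene, []).append(pid)
        return set(per_gene), per_gene

    genes_a, by_gene_a = genes_and_probes(a)
    genes_b, by_gene_b = genes_and_probes(b)
    shared_g = genes_a & genes_b

    same, opposite = set(), set()
    for g in shared_g:
        if _gene_sign(sig_a, by_gene_a, g) == _gene_sign(sig_b, by_gene_b, g):
            same.add(g)
        else:
            opposite.add(g)

    return SignaturePartition(shared_p, a_only_p, b_only_p,
                              shared_g, genes_a - genes_b, genes_b - genes_a,
                              same, opposite)


def eforge_cap(signature: Signature, result: pd.DataFrame | None = None,
               cap: int = 1000) -> Signature:
    """Trim a signature to the ``cap`` most significant probes.

    Mirrors tools that accept at most 1000 CpG sites. If the signature is
    within the cap it is returned unchanged; ties at the cut are broken by
    probe id. ``result`` optionally supplies P-values (defaults to the
    signature's own).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(signature) <= cap:
        return signature
    pvals = (result["p"] if result is not None else signature.pvalues)
    order = sorted(signature.probe_ids, key=lambda pr: (pvals[pr], pr))
    keep = sorted(order[:cap])
    return Signature(signature.exposure_name, signature.p_threshold, keep,
                     signature.directions[keep], signature.pvalues[keep])


def stratify_by_direction(signature: Signature) -> tuple[Signature, Signature]:
    """Split a signature into positively and negatively associated probes.

    Probes with a slope of exactly zero are assigned to the positive stratum
    with a warning.
    """
    dirs = signature.directions
    if (dirs == 0).any():
        warnings.warn("zero slopes assigned to the positive stratum",
                      stacklevel=2)
    pos = sorted(p for p in signature.probe_ids if dirs[p] >= 0)
    neg = sorted(p for p in signature.probe_ids if dirs[p] < 0)

    def sub(probes, tag):
        return Signature(f"{signature.exposure_name}_{tag}",
                         signature.p_threshold, probes,
                         signature.directions[probes],
                         signature.pvalues[probes])

    return sub(pos, "pos"), sub(neg, "neg")
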