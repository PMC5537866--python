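"""Gene-set overrepresentation and regulatory-region enrichment.

Gene lists derived from a signature are tested against GMT gene sets with
the upper-tail hypergeometric test (overrepresentation analysis) and BH
correction; rows with q < 5% or the 100 smallest P-values are flagged for
reporting. Signature CpGs are tested for enrichment inside per-cell-type
open-chromatin (DHS-style) region sets against a null of uniform probe
draws from the retained-probe universe — a documented simplification of
server-side annotation-matched backgrounds.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import Signature, bh_fdr
from .io import merge_regions


def hypergeometric_ora(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_threshold: float = 0.05,
    top_n: int = 100,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of a gene list.

    Gene sets are intersected with the universe before testing; the list
    must be a subset of the universe. The ``reported`` flag marks rows with
    q < ``fdr_threshold`` plus, if fewer, the ``top_n`` smallest-P rows.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    lst = set(gene_list)
    if not lst <= uni:
        raise ValueError(f"{len(lst - uni)} gene(s) in the list are outside "
                         "the universe")
    n_uni, n_list = len(uni), len(lst)
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & uni
        k = len(m & lst)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(m), n_list))
        rows.append((name, k, len(m), n_list, n_uni, p))
    out = pd.DataFrame(rows, columns=["set_name", "overlap_count", "set_size",
                                      "list_size", "universe_size", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["p", "set_name"]).reset_index(drop=True)
    out["reported"] = (out["q"] < fdr_threshold) | (np.arange(len(out)) < top_n)
    return out


def interval_membership(position, starts: np.ndarray,
                        ends: np.ndarray):
    """Is a 1-based position inside any of the merged, sorted 0-based
    half-open intervals? Vectorized over ``position``."""
    pos0 = np.asarray(position, dtype=np.int64) - 1
    idx = np.searchsorted(starts, pos0, side="right") - 1
    inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, max(len(ends) - 1, 0))])
    if len(starts) == 0:
        inside = np.zeros_like(pos0, dtype=bool)
    return bool(inside) if np.isscalar(position) else inside


def _membership_lookup(annotation: pd.DataFrame,
                       regions: pd.DataFrame) -> pd.Series:
    """Boolean per-probe membership in a (possibly unmerged) region set."""
    member = np.zeros(len(annotation), dtype=bool)
    if len(regions):
        merged = merge_regions(regions)
        chroms = annotation["chrom"].astype(str).to_numpy()
        pos = annotation["pos"].to_numpy(dtype=np.int64)
        for chrom, grp in merged.groupby("chrom"):
            sel = chroms == str(chrom)
            if sel.any():
                member[sel] = interval_membership(
                    pos[sel], grp["start"].to_numpy(), grp["end"].to_numpy())
    return pd.Series(member, index=annotation["probe_id"].to_numpy())


def region_overlap_enrichment(
    signature: Signature,
    annotation: pd.DataFrame,
    region_sets: Mapping[str, pd.DataFrame],
    probe_universe: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of signature CpGs inside per-cell-type region sets.

    Observed = signature probes falling inside any region of the set; the
    null redraws ``len(signature)`` probes uniformly from the universe
    ``n_perm`` times. Empirical P uses the >= convention with (r+1)/(n+1);
    z = (obs - null_mean)/null_sd when the null sd is positive.
    """
    universe = sorted(set(probe_universe))
    ann = annotation.set_index("probe_id")
    missing = [p for p in signature.probe_ids if p not in ann.index]
    if missing:
        raise ValueError("signature probe(s) lacking positions: "
                         + ", ".join(missing[:10]))
    uni_ann = ann.loc[universe].reset_index()
    sig_idx = pd.Index(universe).get_indexer(signature.probe_ids)
    if (sig_idx < 0).any():
        raise ValueError("signature probes missing from the probe universe")
    m = len(signature)
    rng = np.random.default_rng(seed)
    draws = np.stack([rng.choice(len(universe), size=m, replace=False)
                      for _ in range(n_perm)])

    rows = []
    for cell_type, regions in region_sets.items():
        member = _membership_lookup(uni_ann, regions).to_numpy()
        observed = int(member[sig_idx].sum())
        null_counts = member[draws].sum(axis=1)
        null_mean = float(null_counts.mean())
        null_sd = float(null_counts.std(ddof=1))
        emp_p = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
        z = (observed - null_mean) / null_sd if null_sd > 0 else np.nan
        rows.append((cell_type, observed, null_mean, null_sd, emp_p, z))
    out = pd.DataFrame(rows, columns=["cell_type", "observed_in_region",
                                      "null_mean", "null_sd", "empirical_p",
                                      "z"])
    out["q"] = bh_fdr(out["empirical_p"].to_numpy())
    return out.sort_values("empirical_p").reset_index(drop=True)
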