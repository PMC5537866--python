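"""Readers and writers for the pipeline's plain-text formats.

On disk, methylation matrices follow the array convention: probes as rows,
header = sample ids. In memory everything is samples x probes (pandas
DataFrame, index = sample ids, columns = probe ids), so matrices are
transposed on the way in and out.

BED intervals are 0-based half-open; probe and TSS positions are 1-based
(array-annotation convention). Conversions are centralized here and in
:mod:`dietmeth.enrich`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- matrices

def write_matrix(df: pd.DataFrame, path: str) -> None:
    """Write a samples x probes matrix as a probes-as-rows TSV."""
    df.T.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path: str) -> pd.DataFrame:
    """Read a probes-as-rows TSV into a samples x probes DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=0).T


# ------------------------------------------------------------------ tables

def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("chip", "chip_position", "pedigree_id", "sample_id", "sex"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


# ---------------------------------------------------------------- id lists

def write_id_list(ids: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_id_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# --------------------------------------------------------------------- GMT

def read_gmt(path: str) -> dict[str, set[str]]:
    """Read gene sets from GMT (set name, description, tab-separated ids)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# --------------------------------------------------------------------- BED

def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str, 1: np.int64, 2: np.int64})
    return df


def write_bed(regions: pd.DataFrame, path: str) -> None:
    regions[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    out = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
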