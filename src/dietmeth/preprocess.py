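"""Probe-level QC: beta computation and probe filtering.

Filtering removes, in order of precedence (each probe counted once):
sex-chromosome probes; probes whose detection P-value exceeds ``fail_p`` in
at least ``fail_fraction`` of samples; multi-mapping probes; SNP-overlapping
probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def compute_beta(meth_signal, unmeth_signal, offset: float = 0.0):
    """Beta value M / (M + U + offset) from methylated/unmethylated signals.

    Cells with an all-zero denominator become missing (NaN) and are logged.
    Accepts scalars or arrays.
    """
    m = np.asarray(meth_signal, dtype=float)
    u = np.asarray(unmeth_signal, dtype=float)
    if np.any(m < 0) or np.any(u < 0) or offset < 0:
        raise ValueError("signals and offset must be nonnegative")
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), np.nan)
    n_missing = int(np.isnan(beta).sum())
    if n_missing:
        log.warning("compute_beta: %d cell(s) with zero total signal set to "
                    "missing", n_missing)
    if beta.ndim == 0:
        return float(beta) if not np.isnan(beta) else float("nan")
    return beta


@dataclass
class FilterReport:
    n_input: int
    n_removed_sex: int
    n_removed_detection: int
    n_removed_multimap: int
    n_removed_snp: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (self.n_removed_sex + self.n_removed_detection
                   + self.n_removed_multimap + self.n_removed_snp)
        assert self.n_input - removed == self.n_retained, \
            "filter accounting does not balance"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_probes(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    annotation: pd.DataFrame,
    fail_p: float = 0.001,
    fail_fraction: float = 0.75,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove sex-chromosome, detection-failing, multimap and SNP probes.

    ``beta`` and ``detection_p`` are samples x probes and must be aligned;
    ``annotation`` must cover every probe and carry boolean columns
    ``sex_chromosome``, ``multimap``, ``snp_overlap``. A probe fails
    detection when detection P > ``fail_p`` in >= ``fail_fraction`` of
    samples. Precedence for report accounting: sex > detection > multimap >
    SNP.
    """
    probes = beta.columns
    if not probes.equals(detection_p.columns):
        detection_p = detection_p.reindex(columns=probes)
        if detection_p.isna().any().any():
            raise ValueError("detection_p is not aligned with beta")
    ann = annotation.set_index("probe_id")
    missing = probes.difference(ann.index)
    if len(missing):
        raise ValueError(
            f"annotation missing for {len(missing)} probe(s): "
            f"{', '.join(missing[:10])}")
    ann = ann.loc[probes]

    is_sex = ann["sex_chromosome"].to_numpy(dtype=bool)
    fail_frac = (detection_p.to_numpy() > fail_p).mean(axis=0)
    is_det = fail_frac >= fail_fraction
    is_multi = ann["multimap"].to_numpy(dtype=bool)
    is_snp = ann["snp_overlap"].to_numpy(dtype=bool)

    remove_sex = is_sex
    remove_det = is_det & ~remove_sex
    remove_multi = is_multi & ~remove_sex & ~remove_det
    remove_snp = is_snp & ~remove_sex & ~remove_det & ~remove_multi
    keep = ~(remove_sex | remove_det | remove_multi | remove_snp)

    report = FilterReport(
        n_input=len(probes),
        n_removed_sex=int(remove_sex.sum()),
        n_removed_detection=int(remove_det.sum()),
        n_removed_multimap=int(remove_multi.sum()),
        n_removed_snp=int(remove_snp.sum()),
        n_retained=int(keep.sum()),
    )
    log.info("filter_probes: %s", report)
    return beta.loc[:, probes[keep]], report
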