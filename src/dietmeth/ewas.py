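"""Per-CpG association testing of methylation against a dietary exposure.

The exposure is first energy-adjusted by the residuals method (residual from
an OLS fit on total energy intake, re-centered at the original mean). Each
probe is then fit by OLS of (beta-scale) methylation on intercept +
exposure + surrogate variables. With moderation on (the default), per-probe
residual variances are shrunk toward a common prior by empirical Bayes —
the posterior variance is (d0*s0^2 + d*s^2)/(d0 + d) with (d0, s0^2)
estimated from the marginal distribution of log sample variances — and the
moderated t-statistic has d0 + d degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .sva import SurrogateVariables
from .transform import beta_to_m


# ----------------------------------------------------------- energy adjust

def energy_adjust(servings, total_energy) -> np.ndarray:
    """Residuals-method energy adjustment of a servings variable.

    OLS of servings on intercept + total energy; returns residuals plus the
    unadjusted mean, so the adjusted exposure keeps the original center but
    is orthogonal to energy intake.
    """
    s = np.asarray(servings, dtype=float)
    e = np.asarray(total_energy, dtype=float)
    if s.shape != e.shape:
        raise ValueError("servings and total_energy must have equal length")
    if np.any(e <= 0):
        raise ValueError("total_energy must be strictly positive")
    if np.ptp(e) == 0:
        warnings.warn("total_energy is constant; returning servings "
                      "unadjusted", stacklevel=2)
        return s.copy()
    x = np.column_stack([np.ones_like(e), e])
    coef, *_ = np.linalg.lstsq(x, s, rcond=None)
    return s - x @ coef + s.mean()


# ------------------------------------------------- variance moderation (EB)

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior (d0, s0^2).

    Uses the distribution of log sample variances: the excess variance of
    log(s^2) over trigamma(d/2) identifies d0; the mean identifies s0^2.
    d0 = inf (no excess) means all probes share one variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return d0, float(s0_sq)


# ------------------------------------------------------------------- EWAS

def _design(exposure: np.ndarray, svs) -> np.ndarray:
    n = len(exposure)
    cols = [np.ones(n), exposure]
    if svs is not None:
        mat = svs.matrix if isinstance(svs, SurrogateVariables) else np.asarray(svs)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.shape[1]:
            cols.extend(mat.T)
    return np.column_stack(cols)


def run_ewas(
    data: pd.DataFrame,
    exposure,
    svs: SurrogateVariables | np.ndarray | None = None,
    moderation: bool = True,
    use_m_values: bool = False,
    max_missing: float = 0.05,
) -> pd.DataFrame:
    """Fit the per-probe linear model and return the association table.

    Returns a DataFrame indexed by probe id with columns slope, se, t, df,
    p, q (BH FDR). Probes with more than ``max_missing`` missing values are
    dropped; remaining missingness is handled complete-case per probe. With
    ``moderation`` the reported se/t/df are the empirical-Bayes moderated
    ones.
    """
    exposure = np.asarray(exposure, dtype=float)
    if np.ptp(exposure) == 0:
        raise ValueError("exposure is constant")
    x = _design(exposure, svs)
    n, pcols = x.shape
    if n < pcols + 1:
        raise ValueError("too few samples for the design "
                         f"({n} samples, {pcols} columns)")
    if np.linalg.matrix_rank(x) < pcols:
        raise ValueError("rank-deficient design: exposure and/or surrogate "
                         "variables are collinear")

    y = data.to_numpy(dtype=float)
    if use_m_values:
        y = beta_to_m(y)
    miss = np.isnan(y)
    keep = miss.mean(axis=0) <= max_missing
    y = y[:, keep]
    miss = miss[:, keep]
    probes = data.columns[keep]

    slope = np.empty(y.shape[1])
    s2 = np.empty(y.shape[1])
    dfree = np.empty(y.shape[1])
    cslope = np.empty(y.shape[1])  # (X'X)^-1 [exposure, exposure] per probe

    complete = ~miss.any(axis=0)
    if complete.any():
        xtx_inv = np.linalg.inv(x.T @ x)
        coef, *_ = np.linalg.lstsq(x, y[:, complete], rcond=None)
        resid = y[:, complete] - x @ coef
        rss = (resid ** 2).sum(axis=0)
        d = n - pcols
        slope[complete] = coef[1]
        s2[complete] = rss / d
        dfree[complete] = d
        cslope[complete] = xtx_inv[1, 1]
    for j in np.flatnonzero(~complete):
        ok = ~miss[:, j]
        xj = x[ok]
        if xj.shape[0] < pcols + 1:
            slope[j], s2[j], dfree[j], cslope[j] = np.nan, np.nan, 0, np.nan
            continue
        xtx_inv_j = np.linalg.inv(xj.T @ xj)
        cj = xtx_inv_j @ xj.T @ y[ok, j]
        rj = y[ok, j] - xj @ cj
        slope[j] = cj[1]
        dfree[j] = xj.shape[0] - pcols
        s2[j] = (rj ** 2).sum() / dfree[j]
        cslope[j] = xtx_inv_j[1, 1]

    if moderation:
        d0, s0_sq = fit_variance_prior(s2, dfree)
        if np.isinf(d0):
            post_var = np.full_like(s2, s0_sq)
            df_total = np.full_like(dfree, np.inf)
        else:
            post_var = (d0 * s0_sq + dfree * s2) / (d0 + dfree)
            df_total = dfree + d0
    else:
        post_var = s2
        df_total = dfree

    se = np.sqrt(post_var * cslope)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / se
    p = np.where(np.isinf(df_total),
                 2.0 * stats.norm.sf(np.abs(t)),
                 2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1,
                                                      df_total)))
    result = pd.DataFrame({"slope": slope, "se": se, "t": t,
                           "df": df_total, "p": p}, index=probes)
    result = result.dropna(subset=["p"])
    result["q"] = bh_fdr(result["p"].to_numpy())
    return result


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------- signature

@dataclass
class Signature:
    """Probes below a P-value threshold for one exposure, with slope signs."""
    exposure_name: str
    p_threshold: float
    probe_ids: list[str]
    directions: pd.Series = field(repr=False)   # +1 / -1 per probe
    pvalues: pd.Series = field(repr=False)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def probe_set(self) -> set[str]:
        return set(self.probe_ids)


def extract_signature(result: pd.DataFrame, p_threshold: float,
                      exposure_name: str = "exposure") -> Signature:
    """Probes with p < threshold (strict), ordered by probe id."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    hit = result.index[result["p"] < p_threshold].sort_values()
    directions = np.sign(result.loc[hit, "slope"]).replace(0, 1).astype(int)
    return Signature(exposure_name, p_threshold, list(hit),
                     directions, result.loc[hit, "p"])


def manhattan_table(result: pd.DataFrame,
                    annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-probe (chrom, pos, -log10 p) export for external plotting."""
    ann = annotation.set_index("probe_id").loc[result.index]
    return pd.DataFrame({
        "probe_id": result.index,
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "neg_log10_p": -np.log10(np.clip(result["p"].to_numpy(), 1e-300, None)),
    })
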