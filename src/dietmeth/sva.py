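"""Surrogate variable estimation and PCA/covariate diagnostics.

Surrogate variables (SVs) capture unmodeled structure — cell-composition
shifts, residual technical artifacts — in the batch-adjusted matrix. The
primary exposures are regressed out first; the left singular vectors of the
residual matrix are candidate SVs, and the retained rank is chosen by
parallel analysis: a component survives if its singular value exceeds the
(1 - alpha) quantile of the same-rank singular values from column-wise
permutations of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurrogateVariables:
    """Orthonormal samples x k surrogate-variable matrix plus diagnostics."""
    matrix: np.ndarray
    k: int
    diagnostics: pd.DataFrame

    def as_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=index,
                            columns=[f"SV{i + 1}" for i in range(self.k)])


def _with_intercept(primary: pd.DataFrame | np.ndarray | None,
                    n: int) -> np.ndarray:
    if primary is None:
        return np.ones((n, 1))
    p = np.asarray(primary, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    return np.hstack([np.ones((n, 1)), p])


def estimate_surrogate_variables(
    data: pd.DataFrame,
    primary: pd.DataFrame | np.ndarray | None,
    max_k: int,
    alpha: float = 0.10,
    n_perm: int = 20,
    seed: int = 0,
) -> SurrogateVariables:
    """Estimate surrogate variables from residuals of the primary model.

    ``data`` is samples x probes; ``primary`` holds the exposure design
    columns (no intercept; one is added). Rank selection stops at the first
    component whose singular value fails the parallel-analysis threshold;
    the result is capped at ``max_k``.
    """
    y = data.to_numpy(dtype=float)
    n = y.shape[0]
    if max_k >= n:
        raise ValueError("max_k must be smaller than the number of samples")
    x = _with_intercept(primary, n)
    if n <= x.shape[1] + 1:
        raise ValueError("need more samples than primary design columns + 1")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef

    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    if s[0] <= 1e-10 * max(resid.shape):      # numerically zero residual
        return SurrogateVariables(np.zeros((n, 0)), 0,
                                  pd.DataFrame(columns=["rank", "singular_value",
                                                        "null_quantile",
                                                        "retained"]))

    rng = np.random.default_rng(seed)
    n_ranks = min(len(s), max_k + 1)
    null_sv = np.empty((n_perm, n_ranks))
    perm = resid.copy()
    for b in range(n_perm):
        for j in range(perm.shape[1]):        # permute each probe independently
            rng.shuffle(perm[:, j])
        null_sv[b] = np.linalg.svd(perm, compute_uv=False)[:n_ranks]
    thresh = np.quantile(null_sv, 1 - alpha, axis=0)

    k = 0
    rows = []
    for r in range(n_ranks):
        keep = s[r] > thresh[r] and k == r
        if keep and k < max_k:
            k += 1
        rows.append((r + 1, s[r], thresh[r], keep and (r < max_k)))
    diagnostics = pd.DataFrame(rows, columns=["rank", "singular_value",
                                              "null_quantile", "retained"])
    return SurrogateVariables(u[:, :k].copy(), k, diagnostics)


def pca_covariate_association(
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    n_pc: int = 10,
) -> pd.DataFrame:
    """Associate top principal components with known covariates.

    Continuous covariates are tested by the Pearson correlation test,
    categorical ones by one-way ANOVA across levels. Constant covariates are
    flagged and not tested. Returns one row per (PC, covariate), sorted by
    P-value.
    """
    y = data.to_numpy(dtype=float)
    n = y.shape[0]
    if n_pc >= n:
        raise ValueError("n_pc must be smaller than the number of samples")
    centered = y - y.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var_explained = s ** 2 / (s ** 2).sum()
    scores = u[:, :n_pc] * s[:n_pc]

    rows = []
    for j in range(n_pc):
        pc = scores[:, j]
        for name, col in covariates.items():
            if pd.api.types.is_numeric_dtype(col):
                if np.ptp(col.to_numpy(dtype=float)) == 0:
                    rows.append((j + 1, name, "constant", np.nan, np.nan,
                                 var_explained[j]))
                    continue
                r, p = stats.pearsonr(pc, col.to_numpy(dtype=float))
                rows.append((j + 1, name, "pearson", r, p, var_explained[j]))
            else:
                groups = [pc[(col == lev).to_numpy()]
                          for lev in pd.unique(col)]
                if len(groups) < 2:
                    rows.append((j + 1, name, "constant", np.nan, np.nan,
                                 var_explained[j]))
                    continue
                f, p = stats.f_oneway(*groups)
                rows.append((j + 1, name, "anova", f, p, var_explained[j]))
    out = pd.DataFrame(rows, columns=["pc", "covariate", "test", "statistic",
                                      "p_value", "variance_explained"])
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
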