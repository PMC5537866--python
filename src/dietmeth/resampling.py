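"""Permutation procedures: low-P-value enrichment and set-overlap nulls.

Three resampling tools back the signature analyses:

* ``low_p_enrichment_test`` — permutes the exposure, refits the regression
  on the signature probes with surrogate variables held fixed, and compares
  the permuted P-value distribution with the observed one (per-permutation
  one-sided t-test counts, plus a mean-based empirical P).
* ``overlap_permutation_test`` — draws two uniform random subsets of an id
  universe per permutation and compares their intersection size with the
  observed overlap; used identically for CpG-site and gene overlaps.
* ``exact_overlap_expectation`` — the analytic (hypergeometric-mean)
  expected overlap a*b/N, the oracle for the permutation null.

Empirical P-values everywhere use the (r + 1)/(n + 1) convention, so they
are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import Signature, _design


@dataclass
class LowPEnrichmentResult:
    n_perm: int
    observed_mean_p: float
    permuted_mean_ps: np.ndarray
    n_elevated: int          # permutations whose P distribution is
    #                          significantly elevated vs observed (t-test)
    empirical_p: float


@dataclass
class OverlapResult:
    universe_size: int
    size_a: int
    size_b: int
    observed_overlap: int
    expected_overlap: float
    fold_enrichment: float
    empirical_p: float
    analytic_expected: float
    overlaps: np.ndarray | None = None   # per-permutation intersection sizes


def _ols_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided OLS slope P-values for every column of y (no moderation)."""
    n, pcols = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ y)
    resid = y - x @ coef
    d = n - pcols
    s2 = (resid ** 2).sum(axis=0) / d
    se = np.sqrt(s2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef[1] / se
    return 2.0 * stats.t.sf(np.abs(t), d)


def low_p_enrichment_test(
    data: pd.DataFrame,
    exposure,
    svs,
    signature: Signature,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    max_regressions: int = 200_000_000,
) -> LowPEnrichmentResult:
    """Permutation test for enrichment of low P-values in a signature.

    For each permutation the exposure labels are shuffled (surrogate
    variables kept fixed as covariates), the per-probe regression is refit
    on the signature probes only, and the permuted P-value distribution is
    compared with the observed one. ``n_elevated`` counts permutations whose
    P-values are significantly elevated relative to the observed ones
    (one-sided two-sample t-test at ``alpha``); the empirical P is the
    (r+1)/(n+1) fraction of permutations whose mean P is at or below the
    observed mean.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm * len(signature) > max_regressions:
        raise ValueError(
            f"{n_perm} permutations x {len(signature)} probes exceeds the "
            f"regression budget ({max_regressions}); reduce n_perm or raise "
            "max_regressions")
    rng = np.random.default_rng(seed)
    exposure = np.asarray(exposure, dtype=float)
    y = data.loc[:, signature.probe_ids].to_numpy(dtype=float)

    obs_p = _ols_pvalues(_design(exposure, svs), y)
    observed_mean = float(obs_p.mean())

    perm_means = np.empty(n_perm)
    n_elev = 0
    for b in range(n_perm):
        xp = _design(rng.permutation(exposure), svs)
        pp = _ols_pvalues(xp, y)
        perm_means[b] = pp.mean()
        tt = stats.ttest_ind(pp, obs_p, alternative="greater")
        if tt.pvalue < alpha:
            n_elev += 1
    empirical_p = (1 + int((perm_means <= observed_mean).sum())) / (n_perm + 1)
    return LowPEnrichmentResult(n_perm, observed_mean, perm_means, n_elev,
                                empirical_p)


def overlap_permutation_test(
    universe,
    size_a: int,
    size_b: int,
    observed_overlap: int,
    n_perm: int = 10000,
    seed: int = 0,
) -> OverlapResult:
    """Permutation null for the overlap of two fixed-size subsets.

    ``universe`` may be a collection of ids or an integer universe size.
    Each permutation draws two independent uniform subsets without
    replacement and records their intersection size; the empirical P is the
    (r+1)/(n+1) fraction of permutations with overlap >= observed.
    """
    n_universe = universe if isinstance(universe, (int, np.integer)) \
        else len(set(universe))
    if size_a > n_universe or size_b > n_universe:
        raise ValueError("subset sizes exceed the universe")
    if observed_overlap > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller subset")
    rng = np.random.default_rng(seed)

    overlaps = np.empty(n_perm, dtype=np.int64)
    mask = np.zeros(n_universe, dtype=bool)
    for b in range(n_perm):
        a_idx = rng.choice(n_universe, size=size_a, replace=False)
        b_idx = rng.choice(n_universe, size=size_b, replace=False)
        mask[a_idx] = True
        overlaps[b] = int(mask[b_idx].sum())
        mask[a_idx] = False

    expected = float(overlaps.mean())
    empirical_p = (1 + int((overlaps >= observed_overlap).sum())) / (n_perm + 1)
    analytic = exact_overlap_expectation(n_universe, size_a, size_b)
    fold = observed_overlap / expected if expected > 0 else np.inf
    return OverlapResult(n_universe, size_a, size_b, observed_overlap,
                         expected, fold, empirical_p, analytic, overlaps)


def exact_overlap_expectation(universe_size: int, size_a: int,
                              size_b: int) -> float:
    """Expected overlap of two independent uniform subsets: a*b/N."""
    if universe_size == 0:
        raise ValueError("universe_size must be positive")
    if size_a > universe_size or size_b > universe_size:
        raise ValueError("subset sizes exceed the universe")
    return size_a * size_b / universe_size


def overlap_tail_p(universe_size: int, size_a: int, size_b: int,
                   observed_overlap: int) -> float:
    """Exact upper-tail P(overlap >= observed) under the hypergeometric null."""
    return float(stats.hypergeom.sf(observed_overlap - 1, universe_size,
                                    size_a, size_b))
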