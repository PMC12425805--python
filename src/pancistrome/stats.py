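"""Small statistical primitives shared across the pipeline.

The exact two-sided binomial test reproduces R's ``binom.test`` (and
scipy's ``binomtest``): the p-value is the sum of the probabilities of
all outcomes whose point probability does not exceed that of the
observed count ("minlike" method), with the same 1 + 1e-7 relative
tolerance R uses when comparing point probabilities.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# relative tolerance used by R's binom.test when comparing point masses
_RERR = 1.0 + 1e-7


def binom_two_sided_p(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minlike method)."""
    if n < 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return np.nan
    pmf = sps.binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[k] * _RERR].sum()))


def binom_two_sided_p_vec(k, n, p: float = 0.5) -> np.ndarray:
    """Vectorised exact two-sided binomial test.

    Point-probability vectors are cached per distinct ``n`` so that the
    typical AMP-calling workload (many sites at similar depths) stays
    fast.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    k, n = np.broadcast_arrays(k, n)
    out = np.full(k.shape, np.nan, dtype=float)
    flat_k, flat_n = k.ravel(), n.ravel()
    flat_out = out.ravel()
    cache: dict[int, np.ndarray] = {}
    for i in range(flat_k.size):
        ni = int(flat_n[i])
        if ni == 0:
            continue
        pmf = cache.get(ni)
        if pmf is None:
            pmf = sps.binom.pmf(np.arange(ni + 1), ni, p)
            cache[ni] = pmf
        flat_out[i] = min(1.0, pmf[pmf <= pmf[int(flat_k[i])] * _RERR].sum())
    return out.reshape(k.shape)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t-test needs at least two observations per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def hypergeom_enrichment_p(n_pop: int, n_marked: int, n_draw: int, k: int):
    """Upper and lower tail hypergeometric p-values for ``k`` marked draws."""
    upper = float(sps.hypergeom.sf(k - 1, n_pop, n_marked, n_draw))
    lower = float(sps.hypergeom.cdf(k, n_pop, n_marked, n_draw))
    return upper, lower
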