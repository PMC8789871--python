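"""Rank statistics shared across modules.

The two-sided rank-sum (Wilcoxon/Mann–Whitney) test is implemented here with
deterministic semantics: exact enumeration of the permutation null of the
rank-sum statistic for group sizes of at most ``EXACT_MAX`` per group
(average ranks for ties), and the tie-corrected normal approximation
otherwise.  The exact branch enumerates subsets of the pooled rank vector,
which handles ties correctly where the classical no-tie tables do not.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

#: per-group size at or below which the exact enumeration is used
EXACT_MAX = 8

_EPS = 1e-12


@lru_cache(maxsize=64)
def _subset_index_matrix(n_total: int, n_pick: int) -> np.ndarray:
    """All C(n_total, n_pick) index subsets as an integer matrix."""
    return np.array(list(combinations(range(n_total), n_pick)), dtype=np.intp)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test of ``x`` vs ``y``.

    Returns ``(W, p)`` where ``W`` is the sum of (average) ranks of ``x`` in
    the pooled sample.  Exact permutation p for group sizes <= EXACT_MAX,
    tie-corrected normal approximation otherwise.  Degenerate inputs (all
    pooled values identical) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0

    if max(n1, n2) <= EXACT_MAX:
        idx = _subset_index_matrix(n, n1)
        null_w = ranks[idx].sum(axis=1)
        observed_dev = abs(w - mu)
        p = float(np.mean(np.abs(null_w - mu) >= observed_dev - _EPS))
        return w, p

    # tie-corrected normal approximation (no continuity correction)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    z = (w - mu) / np.sqrt(var)
    return w, float(2.0 * norm.sf(abs(z)))


def bonferroni(pvals, n_tests: int | None = None) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p) if n_tests is None else n_tests
    return np.minimum(1.0, p * m)


def benjamini_hochberg(pvals) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
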