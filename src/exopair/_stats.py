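"""Shared statistical helpers: Fisher tables, rank-sum and one-sided KS."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .models import ValidationError

P_FLOOR = 1e-300  # keeps -log10(P) finite


def fisher_two_sided(table) -> tuple:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(p_value, direction_odds)`` where the direction odds ratio is
    Haldane-corrected (+0.5 on every cell) only when a cell is zero; the
    P-value itself is always the uncorrected exact one.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValidationError("negative cell in 2x2 table")
    if all(x == 0 for x in cells):
        raise ValidationError("all four cells of the 2x2 table are zero")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in cells:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return float(p), float(odds)


def ranksum_test(x, y, max_exact: int = 12) -> tuple:
    """Two-sided rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have <= ``max_exact``
    observations and there are no ties; tie-corrected normal approximation
    with continuity correction otherwise. All-tied input gives P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("rank-sum test needs >= 2 observations per group")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and x.size <= max_exact and y.size <= max_exact) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_one_sided(values, others, which: str, exact_limit: int = 10_000) -> tuple:
    """One-sided two-sample KS test of set ``values`` against ``others``.

    ``which='larger'`` tests whether ``values`` are stochastically larger
    (statistic D+), ``which='smaller'`` the opposite (D-). The exact
    small-sample null distribution is used while ``n*m <= exact_limit``,
    the asymptotic formula beyond. Returns ``(statistic, p_value)``.
    """
    values = np.asarray(values, dtype=float)
    others = np.asarray(others, dtype=float)
    if values.size == 0 or others.size == 0:
        raise ValidationError("one-sided KS needs non-empty samples on both sides")
    method = "exact" if values.size * others.size <= exact_limit else "asymp"
    # scipy convention: alternative='less' rejects when the first sample's
    # CDF lies below the second's, i.e. the first sample is larger.
    alternative = "less" if which == "larger" else "greater"
    res = stats.ks_2samp(values, others, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def ttest_two_sided(x, y) -> tuple:
    """Two-sided two-sample Student t-test; degenerate zero-variance ties give P=1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t-test needs >= 2 observations per side")
    with warnings.catch_warnings():
        # near-constant input degenerates to t=0/0; mapped to P=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=True)
    if np.isnan(p):
        t, p = 0.0, 1.0
    return float(t), float(p)
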