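"""Nonparametric group comparisons and correlations.

The Wilcoxon rank-sum statistic is reported in the Mann-Whitney
convention of the first sample (W = U of the controls when controls are
passed first), so 0 <= W <= n_x * n_y and swapping the samples maps W to
n_x * n_y - W. The rank correlation is Spearman's rho on midranks
(Pearson selectable), with an exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WilcoxonResult", "CorrelationResult", "wilcoxon_rank_sum", "rank_correlation"]


@dataclass(frozen=True)
class WilcoxonResult:
    W: float  # Mann-Whitney U of the first sample
    n_x: int
    n_y: int
    p: float
    alternative: str


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon/Mann-Whitney rank-sum test.

    Exact p by complete enumeration of rank assignments when both samples
    have at most 10 observations and there are no ties; normal
    approximation with continuity and tie correction otherwise.
    ``alternative`` is relative to the first sample ("greater": x tends
    to exceed y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return WilcoxonResult(
        W=float(res.statistic), n_x=len(x), n_y=len(y), p=float(res.pvalue), alternative=alternative
    )


def _exact_spearman_p(a_ranks, b_ranks, rho_obs, alternative):
    """Permutation p over all n! pairings (n <= 8)."""
    n = len(a_ranks)
    a = a_ranks - a_ranks.mean()
    denom = np.sqrt((a**2).sum())
    count = 0
    total = 0
    b_centered = b_ranks - b_ranks.mean()
    bden = np.sqrt((b_centered**2).sum())
    for perm in itertools.permutations(range(n)):
        r = float((a * b_centered[list(perm)]).sum()) / (denom * bden)
        total += 1
        if alternative == "two-sided":
            count += abs(r) >= abs(rho_obs) - 1e-12
        elif alternative == "greater":
            count += r >= rho_obs - 1e-12
        else:
            count += r <= rho_obs + 1e-12
    return count / total


def rank_correlation(
    a, b, method: str = "spearman", alternative: str = "two-sided"
) -> CorrelationResult:
    """Correlation between paired scores; incomplete pairs are dropped.

    Spearman (default): rho on midranks; exact permutation p when
    n <= 8, otherwise the t approximation. ``method="pearson"`` is
    offered for comparison.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input vector: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(a, b, alternative=alternative)
        return CorrelationResult(float(res.statistic), float(res.pvalue), n, "pearson")
    if method != "spearman":
        raise ValueError(f"unknown method {method!r}")
    rho = float(stats.spearmanr(a, b).statistic)
    if n <= 8:
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        p = float(_exact_spearman_p(ra, rb, rho, alternative))
    else:
        p = float(stats.spearmanr(a, b, alternative=alternative).pvalue)
    return CorrelationResult(rho, p, n, "spearman")
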