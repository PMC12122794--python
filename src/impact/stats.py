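"""Model-comparison statistics: rank-based AUC, Mann-Whitney U, Cliff's delta,
subject-level bootstrap confidence intervals, and Benjamini-Hochberg FDR
control."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "auc_rank", "mann_whitney_u", "cliffs_delta", "benjamini_hochberg",
    "bootstrap_ci",
]


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation; tied scores earn 1/2 credit.

    Equals the probability that a random positive outscores a random negative.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)                      # midranks for ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]
                   ) -> tuple[float, float]:
    """U statistic of ``sample_a`` and a two-sided p-value.

    Exact enumeration when n_a * n_b <= 400 and no cross-sample ties exist;
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cliffs_delta(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """(#{a > b} - #{a < b}) / (n_a n_b), computed by sorted counting; equals
    the all-pairs count exactly."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.sort(np.asarray(sample_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    greater = np.searchsorted(b, a, side="left").sum()     # b strictly below a
    less = (b.size - np.searchsorted(b, a, side="right")).sum()
    return float((greater - less) / (a.size * b.size))


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR procedure: adjusted p_i = min_{j >= rank(i)} m p_(j) / j
    (capped at 1); flags reject where adjusted <= q."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def bootstrap_ci(data: np.ndarray | tuple[np.ndarray, ...],
                 statistic: Callable[..., float],
                 n_resamples: int = 10_000,
                 seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI with subject-level resampling.

    ``data`` is one array or a tuple of aligned arrays (e.g. labels and
    scores); each resample draws subjects with replacement and applies
    ``statistic`` to the resampled columns. Resamples on which the statistic
    is undefined (e.g. a single-class draw for AUC) are redrawn; if more than
    half of all draws fail, an error is raised.
    """
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all data arrays must share the subject axis")
    rng = np.random.default_rng(seed)
    values = np.empty(n_resamples)
    failures = 0
    got = 0
    while got < n_resamples:
        idx = rng.integers(0, n, size=n)
        try:
            values[got] = statistic(*(a[idx] for a in arrays))
            got += 1
        except ValueError:
            failures += 1
            if failures > max(10, n_resamples):
                raise ValueError(
                    "statistic undefined on more than half of the bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
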