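"""Core statistical battery: paired Wilcoxon, Mann-Whitney U, two-sample t,
Fisher's exact test, Benjamini-Hochberg FDR control, and hierarchical
mean +/- SEM summaries.

All tests are two-sided and return a :class:`TestResult`.  Exact null
distributions are used wherever the sample size permits; the branch taken is
recorded in ``TestResult.note`` so analyses are auditable.  Conventions that
the underlying references leave open (dropping zero differences in the
signed-rank test, Welch's correction by default for the t test) are fixed
here and documented on each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "GroupSummary",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "two_sample_t",
    "fisher_exact",
    "benjamini_hochberg",
    "summarize",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p: float
    n: tuple[int, ...]
    method: str
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


@dataclass(frozen=True)
class GroupSummary:
    """Grand mean +/- SEM computed over per-worm means."""

    mean: float
    sem: float
    n_worms: int
    per_worm: dict[str, float] = field(default_factory=dict)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    ``x`` may be paired differences, or paired samples together with ``y``.
    Zero differences are dropped before ranking (the classical Wilcoxon
    convention); if every difference is zero the test degenerates and
    ``p = 1`` is returned.  The exact null distribution is used for up to 25
    nonzero untied pairs, otherwise a normal approximation with continuity
    correction.
    """
    x = _as_1d(x, "x")
    if y is not None:
        y = _as_1d(y, "y")
        if y.size != x.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    n_pairs = d.size
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult(0.0, 1.0, (n_pairs,), "wilcoxon_signed_rank",
                          note="all differences zero; p=1 by convention")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        res = _sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                            method="exact")
        note = f"exact, {d.size} nonzero pairs"
    else:
        res = _sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                            method="approx", correction=True)
        note = f"normal approx with continuity correction, {d.size} nonzero pairs"
        if has_ties:
            note += ", ties present"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      (n_pairs,), "wilcoxon_signed_rank", note)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Branches: exact distribution when ``n1*n2 <= 400`` and the pooled data
    are tie-free; full permutation enumeration when ties are present but the
    number of group assignments is small; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n1, n2 = a.size, b.size
    if not has_ties and n1 * n2 <= 400:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        note = "exact"
    elif has_ties and math.comb(n1 + n2, n1) <= 50_000:
        method = _sps.PermutationMethod(n_resamples=100_000,
                                        rng=np.random.default_rng(0))
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        note = "exact permutation enumeration (ties present)"
    else:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic")
        note = "tie-corrected normal approximation"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      (n1, n2), "mann_whitney_u", note)


def two_sample_t(a, b, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t test; Welch's unequal-variance form by default.

    If both groups are constant with equal means the statistic is undefined
    and ``p = 1`` is returned by convention.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, (a.size, b.size), "two_sample_t",
                              note="both groups constant and equal; p=1 by convention")
        return TestResult(math.inf if a.mean() > b.mean() else -math.inf, 0.0,
                          (a.size, b.size), "two_sample_t",
                          note="both groups constant and unequal")
    res = _sps.ttest_ind(a, b, equal_var=equal_var)
    note = "Welch" if not equal_var else "pooled variance"
    return TestResult(float(res.statistic), float(res.pvalue),
                      (a.size, b.size), "two_sample_t", note)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value sums hypergeometric probabilities of all tables
    (margins fixed) no more probable than the observed one.  A zero margin
    makes every admissible table identical, so ``p = 1``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("cells must be nonnegative integers")
        t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("table has no observations")
    odds, p = _sps.fisher_exact(t, alternative="two-sided")
    note = ""
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        note = "zero margin; p=1"
    return TestResult(float(odds), float(min(p, 1.0)),
                      (int(t[0].sum()), int(t[1].sum())), "fisher_exact", note)


def benjamini_hochberg(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)`` in the original input order; ``reject``
    marks the hypotheses discarded at false-discovery rate ``q`` (default 5%).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def summarize(values, worm_ids) -> GroupSummary:
    """Hierarchical mean +/- SEM: average within each worm first, then across
    worms.  SEM = SD(per-worm means, ddof=1) / sqrt(n_worms); NaN for a
    single worm.
    """
    values = _as_1d(values, "values")
    worm_ids = np.asarray(worm_ids).ravel()
    if worm_ids.size != values.size:
        raise ValueError("values and worm_ids must have equal length")
    per_worm: dict[str, float] = {}
    for w in dict.fromkeys(worm_ids.tolist()):  # preserve first-seen order
        per_worm[str(w)] = float(values[worm_ids == w].mean())
    means = np.array(list(per_worm.values()))
    n = means.size
    sem = float(np.std(means, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(mean=float(means.mean()), sem=sem, n_worms=n,
                        per_worm=per_worm)
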