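"""Nonparametric tests with explicit small-sample contracts.

Thin wrappers over scipy.stats that (a) validate shapes the way the
pipeline needs, (b) choose and *record* the exact-vs-approximate branch in
a method note, so every p-value in a report is attributable. Two-sided
alternatives throughout unless stated otherwise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

from .model import TestResult, ValidationError

__all__ = [
    "SIGNIFICANCE_ALPHA",
    "SMALL_SAMPLE_ALPHA",
    "chi_square",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "mann_whitney",
    "wilcoxon_signed_rank",
]

#: Conventional significance threshold used in reports.
SIGNIFICANCE_ALPHA = 0.05
#: Relaxed threshold used for very small samplings where the test's
#: discreteness does not allow a finer evaluation.
SMALL_SAMPLE_ALPHA = 0.06

#: Total sample size up to which the rank-sum test enumerates exactly
#: (in the absence of ties).
EXACT_MW_LIMIT = 12


def _clamp_p(p: float) -> float:
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney rank-sum test.

    Enumerates the exact null distribution when n_a + n_b <= 12 and the
    data are tie-free; otherwise uses the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= EXACT_MW_LIMIT and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    note = (
        "exact enumeration of the rank-sum null"
        if exact
        else "normal approximation with tie and continuity correction"
        + ("; ties present" if has_ties else "")
    )
    return TestResult("mann_whitney", float(res.statistic), _clamp_p(res.pvalue), note)


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p-value: the sum of hypergeometric probabilities of tables no
    more likely than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("table cells must be nonnegative integers")
    res = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        "fisher_exact_2x2",
        float(res.statistic),
        _clamp_p(res.pvalue),
        "exact hypergeometric enumeration, two-sided by probability ordering",
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups."""
    if len(groups) < 2:
        raise ValidationError("at least two groups required")
    arrays = [np.asarray(g, float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValidationError("all groups must be nonempty")
    res = sps.kruskal(*arrays)
    return TestResult(
        "kruskal_wallis",
        float(res.statistic),
        _clamp_p(res.pvalue),
        "chi-square approximation with tie correction",
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None) -> TestResult:
    """Wilcoxon signed-rank test on paired values (or precomputed differences).

    Zero differences are dropped before ranking; their count is recorded in
    the method note. Raises when no nonzero difference remains.
    """
    d = np.asarray(x, float) - (np.asarray(y, float) if y is not None else 0.0)
    nonzero = d[d != 0]
    dropped = d.size - nonzero.size
    if nonzero.size == 0:
        raise ValidationError("no nonzero paired differences")
    res = sps.wilcoxon(nonzero, mode="auto")
    exact = nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size
    note = (
        ("exact signed-rank null" if exact else "normal approximation")
        + f"; {dropped} zero difference(s) dropped"
    )
    return TestResult("wilcoxon_signed_rank", float(res.statistic), _clamp_p(res.pvalue), note)


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction).

    The method note warns when any expected cell count is below 5, where
    the chi-square approximation is unreliable.
    """
    t = np.asarray(table, float)
    if np.any(t < 0):
        raise ValidationError("table cells must be nonnegative")
    res = sps.chi2_contingency(t, correction=False)
    note = "Pearson chi-square, no continuity correction"
    if np.any(res.expected_freq < 5):
        note += "; WARNING: expected cell count < 5"
    return TestResult("chi_square", float(res.statistic), _clamp_p(res.pvalue), note)
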