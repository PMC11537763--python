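"""Registered hypothesis tests on per-rater agreement values.

Comparisons of MM1 across styles operate on each rater's Fisher-z
transformed leave-one-out correlation (one value per rater per style),
paired within rater: one-tailed paired t-tests with Holm adjustment for
the directional predictions, the TOST procedure for the equivalence
prediction, and the Wilcoxon signed-rank test as the nonparametric
fallback.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "DegenerateDifferencesError",
    "paired_t",
    "holm_adjust",
    "tost_paired",
    "wilcoxon_signed_rank",
    "group_contrasts",
]

ALTERNATIVES = ("two_sided", "greater", "less")


class DegenerateDifferencesError(ValueError):
    """Paired differences carry no variance (or no non-zero values)."""


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_raw: float
    n: int
    df: float | None = None
    p_adjusted: float | None = None
    alternative: str = "two_sided"
    dz: float | None = None
    degenerate: bool = False
    label: str | None = None

    @property
    def p(self) -> float:
        """Adjusted p when available, else raw."""
        return self.p_raw if self.p_adjusted is None else self.p_adjusted


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    return x, y


def _scipy_alt(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    return alternative.replace("two_sided", "two-sided")


def paired_t(x, y, alternative: str = "two_sided") -> TestResult:
    """Paired t-test on x - y with Cohen's dz attached.

    ``alternative='greater'`` tests mean(x - y) > 0.  Constant non-zero
    differences yield a degenerate result with p = 0 and infinite dz;
    all-zero differences raise :class:`DegenerateDifferencesError`.
    """
    x, y = _check_pair(x, y)
    d = x - y
    n = len(d)
    sd = float(d.std(ddof=1))
    if sd == 0:
        if d.mean() == 0:
            raise DegenerateDifferencesError("all paired differences are zero")
        return TestResult(
            test="paired_t",
            statistic=float(np.inf * np.sign(d.mean())),
            p_raw=0.0,
            n=n,
            df=n - 1,
            alternative=alternative,
            dz=float(np.inf * np.sign(d.mean())),
            degenerate=True,
        )
    res = stats.ttest_rel(x, y, alternative=_scipy_alt(alternative))
    return TestResult(
        test="paired_t",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n=n,
        df=n - 1,
        alternative=alternative,
        dz=float(d.mean() / sd),
    )


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adjusted]


def tost_paired(
    x, y, sesoi_dz: float = 0.5, alpha: float = 0.05
) -> tuple[TestResult, TestResult, bool]:
    """Two one-sided paired t-tests against +-sesoi_dz equivalence bounds.

    The bounds are expressed in dz units (standardized mean difference of
    the pairs), i.e. +-sesoi_dz * sd(diff) on the raw scale — the study's
    SESOI of dz = 0.5 corresponds to 0.1 raw MM1 points at sd = 0.2.
    Equivalence is declared when both one-sided tests reject; the TOST p
    is the larger of the two one-sided p-values.
    """
    if sesoi_dz <= 0:
        raise ValueError("sesoi_dz must be positive")
    x, y = _check_pair(x, y)
    d = x - y
    n = len(d)
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise DegenerateDifferencesError("zero-variance differences in TOST")
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (d.mean() + sesoi_dz * sd) / se  # H0: dz <= -sesoi
    t_upper = (d.mean() - sesoi_dz * sd) / se  # H0: dz >= +sesoi
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    lower = TestResult(
        test="tost_lower",
        statistic=float(t_lower),
        p_raw=p_lower,
        n=n,
        df=df,
        alternative="greater",
        dz=float(d.mean() / sd),
    )
    upper = TestResult(
        test="tost_upper",
        statistic=float(t_upper),
        p_raw=p_upper,
        n=n,
        df=df,
        alternative="less",
        dz=float(d.mean() / sd),
    )
    equivalent = (p_lower < alpha) and (p_upper < alpha)
    return lower, upper, equivalent


def _wilcoxon_exact_sf(w_plus: float, n: int) -> float:
    """P(W+ >= w_plus) under H0 for untied ranks 1..n, by convolution."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        counts[rank:] += counts[: max_w + 1 - rank].copy()
    total = counts.sum()
    w = int(np.ceil(w_plus - 1e-9))
    return float(counts[w:].sum() / total)


def wilcoxon_signed_rank(x, y, alternative: str = "two_sided") -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties in |d| receive mid-ranks.  The
    exact null distribution is used for n <= 25 without ties, otherwise
    the normal approximation with continuity and tie corrections.
    ``alternative='greater'`` tests a positive location shift of x - y.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x, y = _check_pair(x, y)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDifferencesError("all paired differences are zero")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    mu = n * (n + 1) / 4.0
    if not has_ties and n <= 25:
        p_greater = _wilcoxon_exact_sf(w_plus, n)
        p_less = _wilcoxon_exact_sf(2 * mu - w_plus, n)
        method = "exact"
    else:
        _, counts = np.unique(absd, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            raise DegenerateDifferencesError("no rank variance in Wilcoxon test")
        # continuity correction toward the mean
        p_greater = float(stats.norm.sf((w_plus - mu - 0.5) / sigma))
        p_less = float(stats.norm.cdf((w_plus - mu + 0.5) / sigma))
        method = "normal_approx"
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(
        test=f"wilcoxon_{method}",
        statistic=w_plus,
        p_raw=p,
        n=n,
        alternative=alternative,
    )


def group_contrasts(
    values_by_group: dict, correction: str = "holm"
) -> list[TestResult]:
    """All pairwise Welch t-tests between groups, with pooled-sd Cohen's d.

    Used for the fan-group comparisons (e.g. opera fans vs. non-fans vs.
    neutral listeners on per-rater z(MM1)).  Two-sided, with Holm-adjusted
    p-values across the contrasts.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in values_by_group.items():
        if len(np.asarray(vals)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    results = []
    for (name_a, a), (name_b, b) in itertools.combinations(
        values_by_group.items(), 2
    ):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        res = stats.ttest_ind(a, b, equal_var=False)
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        results.append(
            TestResult(
                test="welch_t",
                statistic=float(res.statistic),
                p_raw=float(res.pvalue),
                n=len(a) + len(b),
                df=float(res.df),
                alternative="two_sided",
                dz=d,
                label=f"{name_a} vs {name_b}",
            )
        )
    if correction == "holm":
        adjusted = holm_adjust([r.p_raw for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = p_adj
    elif correction not in (None, "none"):
        raise ValueError(f"unknown correction {correction!r}")
    return results
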