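"""Interrater agreement statistics for rating matrices.

All measures operate on a raters x stimuli matrix (a pandas DataFrame,
typically the output of :func:`sharedtaste.rating_data.average_sessions`)
and return a shared :class:`AgreementResult`, so that correlational
measures (MM1, Kendall's W), absolute-agreement measures (Krippendorff's
alpha, ICC(2,1)) and consistency measures (Cronbach's alpha) can be laid
side by side.

The headline statistic is MM1 ("mean-minus-one"): each rater's ratings are
Pearson-correlated with the mean ratings of all other raters, the
individual correlations are pooled on the Fisher-z scale, and the pooled z
is transformed back to an r.  High MM1 means taste is shared; low MM1 with
high test-retest reliability means taste is stable but idiosyncratic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "DegenerateDataError",
    "fisher_z",
    "fisher_z_inv",
    "mm1",
    "mm1_ci",
    "krippendorff_alpha",
    "krippendorff_bootstrap",
    "icc_2_1",
    "kendalls_w",
    "cronbach_alpha",
    "intrarater_reliability",
]

_FISHER_CLAMP = 1.0 - 1e-12


class DegenerateDataError(ValueError):
    """The input carries no usable variance for the requested measure."""


@dataclass
class AgreementResult:
    """One agreement estimate with its provenance.

    ``per_rater`` holds the individual leave-one-out correlations (MM1
    only); ``dropped_raters`` lists raters excluded for zero-variance
    vectors.  ``note`` flags caveats, e.g. that Cronbach's alpha measures
    consistency rather than agreement.
    """

    method: str
    estimate: float
    n_raters: int
    n_items: int
    per_rater: pd.Series | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    dropped_raters: list = field(default_factory=list)
    note: str | None = None

    def __repr__(self) -> str:  # compact, for reports
        ci = (
            f", 95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}]"
            if self.ci_low is not None
            else ""
        )
        return (
            f"AgreementResult({self.method}={self.estimate:.4f}{ci}, "
            f"raters={self.n_raters}, items={self.n_items})"
        )


# ---------------------------------------------------------------------------
# Fisher transform


def fisher_z(r):
    """Fisher r-to-z transform, clamping |r| to just under 1.

    Perfect correlations are mapped to a large finite z instead of
    infinity so that averages of z-scores stay finite.
    """
    r = np.clip(np.asarray(r, dtype=float), -_FISHER_CLAMP, _FISHER_CLAMP)
    return np.arctanh(r)


def fisher_z_inv(z):
    """Inverse Fisher transform (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def _as_matrix(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix.astype(float)
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr)


# ---------------------------------------------------------------------------
# MM1


def mm1(matrix) -> AgreementResult:
    """Leave-one-out correlational agreement (MM1).

    For each rater, compute the Pearson correlation between their ratings
    and the column-wise mean of all *other* raters; pool the correlations
    by averaging on the Fisher-z scale and transforming back.  Raters whose
    rating vector (or whose leave-one-out mean) has zero variance are
    dropped and listed in the result.
    """
    m = _as_matrix(matrix)
    n_raters, n_items = m.shape
    if n_raters < 3 or n_items < 3:
        raise DegenerateDataError(
            f"MM1 needs at least 3 raters and 3 items, got {n_raters}x{n_items}"
        )
    values = m.to_numpy()
    total = values.sum(axis=0)
    per_rater = {}
    dropped = []
    for i, rater in enumerate(m.index):
        own = values[i]
        others_mean = (total - own) / (n_raters - 1)
        if np.std(own) == 0 or np.std(others_mean) == 0:
            dropped.append(rater)
            continue
        per_rater[rater] = float(np.corrcoef(own, others_mean)[0, 1])
    if len(per_rater) < 2:
        raise DegenerateDataError(
            "fewer than 2 raters with usable variance for MM1"
        )
    if dropped:
        warnings.warn(
            f"MM1: dropped zero-variance raters {dropped}", stacklevel=2
        )
    rs = pd.Series(per_rater, name="mm1_per_rater")
    estimate = float(fisher_z_inv(np.mean(fisher_z(rs.to_numpy()))))
    return AgreementResult(
        method="mm1",
        estimate=estimate,
        n_raters=n_raters,
        n_items=n_items,
        per_rater=rs,
        dropped_raters=dropped,
    )


def mm1_ci(result: AgreementResult, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory CI for MM1 on the Fisher-z scale, mapped back to r.

    The standard error is the sample SD of the individual z-transformed
    correlations divided by sqrt(k); endpoints are back-transformed with
    tanh.  Requires ``per_rater`` correlations in the result.
    """
    if result.per_rater is None:
        raise ValueError(f"{result.method} carries no per-rater correlations")
    zs = fisher_z(result.per_rater.to_numpy())
    k = len(zs)
    if k < 3:
        raise DegenerateDataError("need at least 3 per-rater values for a CI")
    crit = stats.norm.ppf(0.5 + level / 2)
    mean, se = float(np.mean(zs)), float(np.std(zs, ddof=1) / np.sqrt(k))
    low, high = fisher_z_inv(mean - crit * se), fisher_z_inv(mean + crit * se)
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Krippendorff's alpha


def _coincidence(matrix: np.ndarray):
    """Coincidence matrix over observed values; columns are units."""
    vals, codes = np.unique(matrix[~np.isnan(matrix)], return_inverse=True)
    k = len(vals)
    coin = np.zeros((k, k))
    coded = np.full(matrix.shape, -1, dtype=int)
    coded[~np.isnan(matrix)] = codes
    for u in range(matrix.shape[1]):
        idx = coded[:, u]
        idx = idx[idx >= 0]
        m_u = len(idx)
        if m_u < 2:
            continue
        counts = np.bincount(idx, minlength=k).astype(float)
        coin += (np.outer(counts, counts) - np.diag(counts)) / (m_u - 1)
    return vals, coin


def _delta_sq(vals: np.ndarray, level: str, n_c: np.ndarray) -> np.ndarray:
    if level == "interval":
        return (vals[:, None] - vals[None, :]) ** 2
    if level == "nominal":
        return 1.0 - np.eye(len(vals))
    if level == "ordinal":
        # Krippendorff's ordinal metric on cumulative marginals
        cum = np.cumsum(n_c)
        d = np.zeros((len(vals), len(vals)))
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                s = n_c[i : j + 1].sum() - (n_c[i] + n_c[j]) / 2.0
                d[i, j] = d[j, i] = s**2
        _ = cum
        return d
    raise ValueError(f"unknown level {level!r}; use nominal, ordinal or interval")


def krippendorff_alpha(matrix, level: str = "interval") -> AgreementResult:
    """Krippendorff's alpha: 1 - D_o / D_e over the coincidence matrix.

    ``level`` selects the difference metric delta^2; the default
    ``interval`` (squared value difference) matches the parametric
    treatment of the 1-9 liking scale elsewhere in the pipeline.
    """
    m = _as_matrix(matrix)
    if m.shape[0] < 2:
        raise DegenerateDataError("Krippendorff's alpha needs at least 2 raters")
    vals, coin = _coincidence(m.to_numpy())
    n_c = coin.sum(axis=1)
    n_total = n_c.sum()
    if len(vals) < 2:
        raise DegenerateDataError(
            "all ratings identical everywhere: expected disagreement is zero, "
            "alpha is undefined"
        )
    d2 = _delta_sq(vals, level, n_c)
    d_o = float((coin * d2).sum() / n_total)
    d_e = float((np.outer(n_c, n_c) * d2).sum() / (n_total * (n_total - 1)))
    if d_e == 0:
        raise DegenerateDataError("expected disagreement is zero; alpha undefined")
    return AgreementResult(
        method="krippendorff_alpha",
        estimate=1.0 - d_o / d_e,
        n_raters=m.shape[0],
        n_items=m.shape[1],
        note=f"level={level}",
    )


def krippendorff_bootstrap(
    matrix,
    iterations: int = 100,
    level: str = "interval",
    seed: int | None = None,
    unit: str = "items",
) -> tuple[float, float, float]:
    """Bootstrap Krippendorff's alpha; returns (mean, ci_low, ci_high).

    ``unit='items'`` (default) resamples stimulus columns with replacement
    and recomputes alpha per replicate.  ``unit='pairs'`` instead resamples
    within-unit value pairs from the coincidence distribution (a
    pair-resampling scheme in the spirit of Krippendorff's own bootstrap
    algorithm).  The reported value is the mean of the replicates with
    their empirical 2.5/97.5 percentiles.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    m = _as_matrix(matrix)
    rng = np.random.default_rng(seed)
    reps = np.empty(iterations)
    if unit == "items":
        n_items = m.shape[1]
        arr = m.to_numpy()
        for b in range(iterations):
            cols = rng.integers(0, n_items, size=n_items)
            reps[b] = krippendorff_alpha(arr[:, cols], level=level).estimate
    elif unit == "pairs":
        vals, coin = _coincidence(m.to_numpy())
        n_c = coin.sum(axis=1)
        n_total = n_c.sum()
        if len(vals) < 2:
            raise DegenerateDataError("alpha undefined: no value variation")
        d2 = _delta_sq(vals, level, n_c)
        d_e = float((np.outer(n_c, n_c) * d2).sum() / (n_total * (n_total - 1)))
        probs = (coin / coin.sum()).ravel()
        pair_d2 = d2.ravel()
        n_pairs = int(round(coin.sum() / 2))
        for b in range(iterations):
            draw = rng.choice(len(probs), size=n_pairs, p=probs)
            reps[b] = 1.0 - float(np.mean(pair_d2[draw])) / d_e
    else:
        raise ValueError("unit must be 'items' or 'pairs'")
    low, high = np.percentile(reps, [2.5, 97.5])
    return float(np.mean(reps)), float(low), float(high)


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_2_1(matrix) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Stimuli are the targets (columns of the matrix), raters the judges.
    From the two-way ANOVA mean squares with n targets and k raters:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    m = _as_matrix(matrix)
    k, n = m.shape  # k raters, n targets
    if k < 2 or n < 2:
        raise DegenerateDataError("ICC needs at least 2 raters and 2 items")
    x = m.to_numpy()
    grand = x.mean()
    target_means = x.mean(axis=0)
    rater_means = x.mean(axis=1)
    ss_target = k * np.sum((target_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_target - ss_rater
    msr = ss_target / (n - 1)  # between targets
    msc = ss_rater / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateDataError("ICC undefined: no variance in the matrix")
    return AgreementResult(
        method="icc_2_1",
        estimate=float((msr - mse) / denom),
        n_raters=k,
        n_items=n,
    )


# ---------------------------------------------------------------------------
# Kendall's W


def kendalls_w(matrix) -> AgreementResult:
    """Kendall's coefficient of concordance with the standard ties correction.

    Each rater's ratings are converted to within-rater ranks (mid-ranks for
    ties); W = 12 S / (m^2 (n^3 - n) - m * sum T_j) where S is the sum of
    squared deviations of rank sums and T_j the tie correction of rater j.
    """
    m = _as_matrix(matrix)
    n_raters, n_items = m.shape
    if n_raters < 2 or n_items < 2:
        raise DegenerateDataError("Kendall's W needs at least 2 raters and 2 items")
    ranks = np.vstack([stats.rankdata(row) for row in m.to_numpy()])
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    t_corr = 0.0
    for row in m.to_numpy():
        _, counts = np.unique(row, return_counts=True)
        t_corr += float(np.sum(counts**3 - counts))
    denom = n_raters**2 * (n_items**3 - n_items) - n_raters * t_corr
    if denom <= 0:
        raise DegenerateDataError(
            "Kendall's W undefined: every rater ties all items"
        )
    return AgreementResult(
        method="kendall_w",
        estimate=12.0 * s / denom,
        n_raters=n_raters,
        n_items=n_items,
    )


# ---------------------------------------------------------------------------
# Cronbach's alpha


def cronbach_alpha(matrix) -> AgreementResult:
    """Cronbach's alpha with raters as scale items.

    alpha_C = k/(k-1) * (1 - sum var_rater / var_totals), sample variances
    with n-1 denominator.  Reported for comparison only: it is a
    *consistency* coefficient, inflated by the number of raters, not a
    measure of absolute agreement (flagged in ``note``).
    """
    m = _as_matrix(matrix)
    k, n = m.shape
    if k < 2 or n < 2:
        raise DegenerateDataError("Cronbach's alpha needs at least 2 raters")
    x = m.to_numpy()
    item_vars = x.var(axis=1, ddof=1)  # per-rater variance over stimuli
    total_var = x.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("Cronbach's alpha undefined: total scores constant")
    est = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return AgreementResult(
        method="cronbach_alpha",
        estimate=float(est),
        n_raters=k,
        n_items=n,
        note="consistency coefficient, not an agreement measure",
    )


# ---------------------------------------------------------------------------
# Intrarater (test-retest) reliability


def intrarater_reliability(table) -> tuple[pd.Series, dict]:
    """Per-rater Pearson correlation between session 1 and session 2 ratings.

    Returns the per-rater correlations (NaN where a rater's ratings are
    constant within a session) and a summary dict with mean, sd, a 95%
    normal-theory CI over raters, and the range.
    """
    sessions = table.sessions
    if len(sessions) != 2:
        raise ValueError(f"test-retest reliability needs exactly 2 sessions, got {sessions}")
    wide = table.records.pivot_table(
        index="rater_id", columns=["session", "stimulus_id"], values="rating"
    )
    s1 = wide[sessions[0]].to_numpy(dtype=float)
    s2 = wide[sessions[1]].to_numpy(dtype=float)
    if np.isnan(s1).any() or np.isnan(s2).any():
        from .rating_data import IncompleteDesignError

        raise IncompleteDesignError(
            "test-retest reliability requires every rater to rate every "
            "stimulus in both sessions"
        )
    rs = {}
    for i, rater in enumerate(wide.index):
        if np.std(s1[i]) == 0 or np.std(s2[i]) == 0:
            rs[rater] = np.nan
            continue
        rs[rater] = float(np.corrcoef(s1[i], s2[i])[0, 1])
    series = pd.Series(rs, name="r_test_retest")
    valid = series.dropna().to_numpy()
    se = valid.std(ddof=1) / np.sqrt(len(valid))
    crit = stats.norm.ppf(0.975)
    summary = {
        "mean": float(valid.mean()),
        "sd": float(valid.std(ddof=1)),
        "ci_low": float(valid.mean() - crit * se),
        "ci_high": float(valid.mean() + crit * se),
        "min": float(valid.min()),
        "max": float(valid.max()),
        "n": int(len(valid)),
        "n_missing": int(series.isna().sum()),
    }
    return series, summary
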