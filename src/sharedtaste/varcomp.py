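"""Variance-component decomposition of the crossed rater x item x session design.

The rating model (per vocalization style) is

    y_{rit} = mu + a_r + b_i + c_t + d_{ri} + e_{rt} + eps_{rit}

with independent zero-mean random effects for rater, item (stimulus),
time (session), rater x item ("private taste"), rater x time, and residual
noise.  The item x time cluster is omitted: in the study it captured no
variance, and with one observation per cell it is confounded with the
residual anyway.

From the estimated components two *beholder indices* summarize how much of
the time-stable, non-residual variance is private rather than shared:

    bi1 = s2_rater_item / (s2_item + s2_rater_item)
    bi2 = (s2_rater + s2_rater_item) / (s2_item + s2_rater + s2_rater_item)

bi1 disregards the rater main effect (scale-use differences); bi2 counts
it as private.  Their complements 1 - bi are the shared-taste fractions.

For the balanced crossed design the components are estimated in closed
form from expected mean squares (Henderson's method 1); unbalanced tables
fall back to an EM algorithm maximizing the restricted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLUSTERS",
    "VarianceComponents",
    "BeholderIndices",
    "NotCrossedError",
    "ConvergenceError",
    "estimate_variance_components",
    "beholder_indices",
    "shared_taste_complement",
]

CLUSTERS = ("rater", "item", "time", "rater_item", "rater_time", "residual")


class NotCrossedError(ValueError):
    """The table is not a crossed rater x item x time design."""


class ConvergenceError(RuntimeError):
    """EM restricted-likelihood estimation failed to converge."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class VarianceComponents:
    """Estimated variance per cluster, in squared Likert points."""

    rater: float
    item: float
    time: float
    rater_item: float
    rater_time: float
    residual: float
    estimator: str
    n_rater: int
    n_item: int
    n_time: int

    def as_dict(self) -> dict:
        return {c: float(getattr(self, c)) for c in CLUSTERS}

    @property
    def total(self) -> float:
        return float(sum(self.as_dict().values()))


@dataclass
class BeholderIndices:
    """Private-taste fractions of the time-stable meaningful variance."""

    bi1: float
    bi2: float


def _design_arrays(table):
    """Extract y and integer factor codes; verify the crossed structure."""
    rec = table.records
    raters, r_idx = np.unique(rec["rater_id"], return_inverse=True)
    items, i_idx = np.unique(rec["stimulus_id"], return_inverse=True)
    times, t_idx = np.unique(rec["session"], return_inverse=True)
    n_r, n_i, n_t = len(raters), len(items), len(times)
    if n_r < 2 or n_i < 2 or n_t < 2:
        raise NotCrossedError(
            f"need >= 2 levels per facet, got raters={n_r}, items={n_i}, times={n_t}"
        )
    counts = np.zeros((n_r, n_i, n_t), dtype=int)
    np.add.at(counts, (r_idx, i_idx, t_idx), 1)
    if (counts > 1).any():
        raise NotCrossedError("duplicated (rater, item, time) observations")
    y = rec["rating"].to_numpy(dtype=float)
    balanced = bool((counts == 1).all())
    return y, r_idx, i_idx, t_idx, (n_r, n_i, n_t), balanced


def _henderson_balanced(y, r_idx, i_idx, t_idx, dims):
    """Closed-form expected-mean-squares estimates for the balanced design.

    The item x time and three-way interactions are pooled into the
    residual (matching the reduced model).  Returns untruncated estimates.
    """
    n_r, n_i, n_t = dims
    cell = np.zeros((n_r, n_i, n_t))
    cell[r_idx, i_idx, t_idx] = y
    grand = cell.mean()
    m_r = cell.mean(axis=(1, 2))
    m_i = cell.mean(axis=(0, 2))
    m_t = cell.mean(axis=(0, 1))
    m_ri = cell.mean(axis=2)
    m_rt = cell.mean(axis=1)
    m_it = cell.mean(axis=0)

    ss_r = n_i * n_t * np.sum((m_r - grand) ** 2)
    ss_i = n_r * n_t * np.sum((m_i - grand) ** 2)
    ss_t = n_r * n_i * np.sum((m_t - grand) ** 2)
    ss_ri = n_t * np.sum((m_ri - m_r[:, None] - m_i[None, :] + grand) ** 2)
    ss_rt = n_i * np.sum((m_rt - m_r[:, None] - m_t[None, :] + grand) ** 2)
    ss_it = n_r * np.sum((m_it - m_i[:, None] - m_t[None, :] + grand) ** 2)
    ss_tot = np.sum((cell - grand) ** 2)
    ss_rit = ss_tot - ss_r - ss_i - ss_t - ss_ri - ss_rt - ss_it

    df_ri = (n_r - 1) * (n_i - 1)
    df_rt = (n_r - 1) * (n_t - 1)
    # residual pools item:time and the three-way remainder
    df_res = (n_i - 1) * (n_t - 1) + (n_r - 1) * (n_i - 1) * (n_t - 1)
    ms_r = ss_r / (n_r - 1)
    ms_i = ss_i / (n_i - 1)
    ms_t = ss_t / (n_t - 1)
    ms_ri = ss_ri / df_ri
    ms_rt = ss_rt / df_rt
    ms_e = (ss_it + ss_rit) / df_res

    s2_ri = (ms_ri - ms_e) / n_t
    s2_rt = (ms_rt - ms_e) / n_i
    s2_i = (ms_i - ms_ri) / (n_r * n_t)
    s2_t = (ms_t - ms_rt) / (n_r * n_i)
    s2_r = (ms_r - ms_ri - ms_rt + ms_e) / (n_i * n_t)
    return {
        "rater": s2_r,
        "item": s2_i,
        "time": s2_t,
        "rater_item": s2_ri,
        "rater_time": s2_rt,
        "residual": ms_e,
    }


def _em_reml(y, r_idx, i_idx, t_idx, dims, tol, max_iter):
    """REML for the five-cluster crossed model: EM sweeps with
    average-information acceleration, dense linear algebra.

    Plain EM approaches the optimum at a linear rate far too slow for a
    tight tolerance, so after a few monotone warm-up sweeps each
    iteration attempts an average-information (Newton-type) update,
    falling back to the EM step whenever the AI step fails or lowers the
    restricted likelihood.  Convergence is declared when the restricted
    log-likelihood gain drops below ``tol``.  Suited to the moderate
    problem sizes where unbalanced tables occur; the balanced study
    design takes the closed-form path instead.
    """
    n = len(y)
    n_r, n_i, n_t = dims
    z_blocks = []
    codes = [
        r_idx,
        i_idx,
        t_idx,
        r_idx * n_i + i_idx,
        r_idx * n_t + t_idx,
    ]
    sizes = [n_r, n_i, n_t, n_r * n_i, n_r * n_t]
    for code, q in zip(codes, sizes):
        z = np.zeros((n, q))
        z[np.arange(n), code] = 1.0
        z_blocks.append(z)
    x = np.ones((n, 1))
    floor = 1e-10

    def state(sig):
        v = sig[5] * np.eye(n)
        for k in range(5):
            v += sig[k] * (z_blocks[k] @ z_blocks[k].T)
        vinv = np.linalg.inv(v)
        xvx = x.T @ vinv @ x
        p = vinv - vinv @ x @ np.linalg.solve(xvx, x.T @ vinv)
        py = p @ y
        loglik = -0.5 * (
            np.linalg.slogdet(v)[1]
            + np.linalg.slogdet(xvx)[1]
            + float(y @ py)
        )
        return p, py, loglik

    def em_step(sig, p, py):
        new = np.empty_like(sig)
        for k in range(5):
            zk = z_blocks[k]
            q_k = zk.shape[1]
            quad = float(py @ zk @ zk.T @ py)
            tr = float(np.trace(zk.T @ p @ zk))
            new[k] = sig[k] + (sig[k] ** 2 / q_k) * (quad - tr)
        new[5] = sig[5] + (sig[5] ** 2 / n) * (float(py @ py) - np.trace(p))
        return np.maximum(new, floor)

    def ai_step(sig, p, py):
        w = [z @ (z.T @ py) for z in z_blocks] + [py]
        grad = np.empty(6)
        for k, zk in enumerate(z_blocks):
            grad[k] = -0.5 * (np.trace(zk.T @ p @ zk) - float(py @ w[k]))
        grad[5] = -0.5 * (np.trace(p) - float(py @ py))
        ai = np.empty((6, 6))
        pw = [p @ wk for wk in w]
        for j in range(6):
            for k in range(j, 6):
                ai[j, k] = ai[k, j] = 0.5 * float(w[j] @ pw[k])
        step = np.linalg.solve(ai, grad)
        return np.maximum(sig + step, floor)

    var_y = max(float(np.var(y, ddof=1)), 1e-8)
    sig = np.full(6, var_y / 6.0)  # 5 clusters + residual
    trace = []
    p, py, loglik = state(sig)
    delta = np.inf
    for it in range(max_iter):
        candidate = None
        if it >= 3:  # EM warm-up first
            try:
                candidate = ai_step(sig, p, py)
            except np.linalg.LinAlgError:
                candidate = None
        if candidate is not None:
            p_new, py_new, loglik_new = state(candidate)
            if not np.isfinite(loglik_new) or loglik_new < loglik:
                candidate = None
        if candidate is None:
            candidate = em_step(sig, p, py)
            p_new, py_new, loglik_new = state(candidate)
        delta = float(loglik_new - loglik)
        sig, p, py, loglik = candidate, p_new, py_new, loglik_new
        trace.append((it, delta, sig.copy()))
        if 0 <= delta < tol:
            break
    else:
        raise ConvergenceError(
            f"REML did not converge within {max_iter} iterations "
            f"(last log-likelihood gain {delta:.3e})",
            trace=trace,
        )
    sig = np.where(sig <= 2 * floor, 0.0, sig)
    return {
        "rater": sig[0],
        "item": sig[1],
        "time": sig[2],
        "rater_item": sig[3],
        "rater_time": sig[4],
        "residual": sig[5],
    }


def estimate_variance_components(
    table,
    estimator: str = "anova_mom",
    truncate: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarianceComponents:
    """Estimate the five cluster variances plus residual for one style slice.

    ``estimator='anova_mom'`` uses the closed-form expected-mean-squares
    solution (requires the fully crossed balanced design; unbalanced
    tables automatically fall back to EM-REML).  ``estimator='reml_em'``
    forces the EM path.  Negative solutions are truncated to zero after
    all components are computed, unless ``truncate=False``.
    """
    y, r_idx, i_idx, t_idx, dims, balanced = _design_arrays(table)
    if estimator == "anova_mom" and balanced:
        comps = _henderson_balanced(y, r_idx, i_idx, t_idx, dims)
        label = "anova_mom"
    elif estimator in ("anova_mom", "reml_em"):
        if estimator == "anova_mom" and not balanced:
            label = "reml_em"  # documented fallback for unbalanced tables
        else:
            label = "reml_em"
        comps = _em_reml(y, r_idx, i_idx, t_idx, dims, tol, max_iter)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if truncate:
        comps = {k: max(v, 0.0) for k, v in comps.items()}
    return VarianceComponents(
        estimator=label,
        n_rater=dims[0],
        n_item=dims[1],
        n_time=dims[2],
        **{k: float(v) for k, v in comps.items()},
    )


def beholder_indices(
    vc: VarianceComponents, include_time: bool = False
) -> BeholderIndices:
    """Beholder indices bi1 and bi2 from estimated variance components.

    Session-related clusters and the residual are excluded from both
    ratios: they are neither stable taste nor signal.  Set
    ``include_time=True`` to add the time clusters to the denominators for
    sensitivity analysis.
    """
    extra = (vc.time + vc.rater_time) if include_time else 0.0
    denom1 = vc.item + vc.rater_item + extra
    denom2 = vc.item + vc.rater + vc.rater_item + extra
    if denom1 == 0 or denom2 == 0:
        raise ZeroDivisionError(
            "beholder index undefined: no non-residual variance"
        )
    return BeholderIndices(
        bi1=float(vc.rater_item / denom1),
        bi2=float((vc.rater + vc.rater_item) / denom2),
    )


def shared_taste_complement(bi: BeholderIndices) -> tuple[float, float]:
    """Shared-taste fractions (1 - bi1, 1 - bi2)."""
    return (1.0 - bi.bi1, 1.0 - bi.bi2)
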