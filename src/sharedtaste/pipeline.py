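"""End-to-end analysis pipeline for a rating experiment.

Runs the full registered + exploratory analysis on a rating table (real
or synthetic): the participant-exclusion filter, per-style agreement
profiles (MM1 with CI, Krippendorff's alpha with bootstrap CI, ICC(2,1),
Kendall's W, Cronbach's alpha, variance components and beholder indices),
the directional hypothesis on singing styles (H1A), the equivalence
hypothesis on speech styles (H1B), interstyle consistency with the 0.8
threshold (H2), liking-distribution contrasts, intrarater reliability,
and optional covariate analyses.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    cronbach_alpha,
    fisher_z,
    icc_2_1,
    intrarater_reliability,
    kendalls_w,
    krippendorff_alpha,
    krippendorff_bootstrap,
    mm1,
    mm1_ci,
)
from .inference import (
    DegenerateDifferencesError,
    TestResult,
    holm_adjust,
    paired_t,
    tost_paired,
)
from .rating_data import RatingTable, average_sessions, filter_flat_raters
from .varcomp import beholder_indices, estimate_variance_components

__all__ = [
    "PipelineConfig",
    "FAN_GROUPS",
    "grand_average_by_singer",
    "interstyle_mm1",
    "consistency_verdict",
    "pairwise_style_correlations",
    "liking_contrasts",
    "covariate_agreement_correlation",
    "run_full_analysis",
]

#: Mapping of the five musical-preference questionnaire options onto fan
#: groups, as used for the opera/pop fan contrasts.
FAN_GROUPS = {
    "I like it a lot": "fan",
    "I like it a bit": "fan",
    "neutral": "neutral",
    "I don't know/hardly know": "neutral",
    "I rather dislike it": "nonfan",
    "I don't like it at all": "nonfan",
}


@dataclass
class PipelineConfig:
    """Tunable thresholds of the registered analysis."""

    styles: tuple | None = None  # None = all styles present in the data
    flat_threshold: float = 0.85
    interstyle_threshold: float = 0.8
    sesoi_dz: float = 0.5
    alpha: float = 0.05
    adjust: str = "holm"
    bootstrap_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flat_threshold", "interstyle_threshold"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Interstyle consistency (hypothesis 2)


def grand_average_by_singer(table: RatingTable) -> pd.DataFrame:
    """Grand-average liking per singer per style (over raters, melodies, sessions).

    Returns a singers x styles DataFrame (22 x 5 in the study design).
    """
    merged = table.merged()
    matrix = merged.pivot_table(
        index="singer_id", columns="style", values="rating", aggfunc="mean"
    )
    if matrix.isna().to_numpy().any():
        missing = [
            (r, c)
            for r, c in zip(*np.nonzero(matrix.isna().to_numpy()))
        ]
        named = [(matrix.index[r], matrix.columns[c]) for r, c in missing[:10]]
        from .rating_data import IncompleteDesignError

        raise IncompleteDesignError(
            f"missing singer x style cells: {named}", cells=named
        )
    return matrix.astype(float)


def interstyle_mm1(singer_by_style: pd.DataFrame) -> dict:
    """MM1 with styles as 'raters' judging the singers.

    The singers x styles grand-average matrix is transposed so that each
    style is one row; :func:`sharedtaste.agreement.mm1` then yields one
    leave-one-out correlation per style, pooled on the z scale, with a CI
    from the spread of the five per-style correlations.
    """
    result = mm1(singer_by_style.T)
    low, high = mm1_ci(result)
    return {
        "estimate": result.estimate,
        "ci_low": low,
        "ci_high": high,
        "per_style": result.per_rater,
        "n_styles": result.n_raters,
        "n_singers": result.n_items,
    }


def consistency_verdict(interstyle: dict, threshold: float = 0.8) -> dict:
    """H2 decision: consistency is 'high' iff the CI lower bound >= threshold."""
    high = bool(interstyle["ci_low"] >= threshold)
    verdict = (
        "highly consistent across styles"
        if high
        else "not highly consistent across styles"
    )
    return {
        "high_consistency": high,
        "threshold": threshold,
        "verdict": (
            f"interstyle agreement {interstyle['estimate']:.2f} "
            f"(95% CI [{interstyle['ci_low']:.2f}, {interstyle['ci_high']:.2f}]): "
            f"average preferences are {verdict}"
        ),
    }


def pairwise_style_correlations(singer_by_style: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between styles' average singer preferences."""
    styles = list(singer_by_style.columns)
    if len(styles) < 2:
        raise ValueError("need at least 2 styles")
    out = pd.DataFrame(np.eye(len(styles)), index=styles, columns=styles)
    for a, b in itertools.combinations(styles, 2):
        x = singer_by_style[a].to_numpy()
        y = singer_by_style[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        out.loc[a, b] = out.loc[b, a] = r
    return out


# ---------------------------------------------------------------------------
# Liking-distribution contrasts


def liking_contrasts(table: RatingTable, alpha: float = 0.05) -> list:
    """Paired t-tests on per-rater mean liking for every style pair.

    Ratings are averaged over sessions and stimuli within rater and style;
    the 10 pairwise contrasts (for 5 styles) are Holm-adjusted.
    """
    merged = table.merged()
    per_rater = merged.pivot_table(
        index="rater_id", columns="style", values="rating", aggfunc="mean"
    )
    styles = list(per_rater.columns)
    results = []
    for a, b in itertools.combinations(styles, 2):
        res = paired_t(per_rater[a].to_numpy(), per_rater[b].to_numpy())
        res.label = f"{a} vs {b}"
        results.append(res)
    adjusted = holm_adjust([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    return results


def covariate_agreement_correlation(
    z_mm1_by_style: pd.DataFrame, covariate: pd.Series
) -> pd.DataFrame:
    """Pearson r between a numeric rater covariate and per-style z(MM1).

    ``z_mm1_by_style``: raters x styles frame of Fisher-z transformed
    individual MM1 correlations; ``covariate``: one value per rater,
    indexed by rater id.  Returns one row per style with r and n.
    """
    cov = covariate.dropna()
    if cov.std(ddof=1) == 0:
        raise ValueError("constant covariate: correlation undefined")
    rows = []
    for style in z_mm1_by_style.columns:
        joined = pd.concat(
            [z_mm1_by_style[style], cov], axis=1, join="inner"
        ).dropna()
        z, c = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
        r = float(np.corrcoef(z, c)[0, 1]) if len(joined) > 2 else np.nan
        rows.append({"style": style, "r": r, "n": len(joined)})
    return pd.DataFrame(rows).set_index("style")


# ---------------------------------------------------------------------------
# Full analysis


def _style_profile(style_table: RatingTable, cfg: PipelineConfig, seed) -> dict:
    matrix = average_sessions(style_table)
    res_mm1 = mm1(matrix)
    low, high = mm1_ci(res_mm1)
    alpha_point = krippendorff_alpha(matrix)
    boot_mean, boot_lo, boot_hi = krippendorff_bootstrap(
        matrix, iterations=cfg.bootstrap_iterations, seed=seed
    )
    vc = estimate_variance_components(style_table)
    try:
        bi = beholder_indices(vc)
        bi1, bi2 = bi.bi1, bi.bi2
    except ZeroDivisionError:
        bi1 = bi2 = float("nan")
    per_rater_mean = matrix.mean(axis=1)
    mean_se = per_rater_mean.std(ddof=1) / np.sqrt(len(per_rater_mean))
    return {
        "mean_liking": float(per_rater_mean.mean()),
        "mean_liking_ci": [
            float(per_rater_mean.mean() - 1.959963984540054 * mean_se),
            float(per_rater_mean.mean() + 1.959963984540054 * mean_se),
        ],
        "mm1": res_mm1.estimate,
        "mm1_ci": [low, high],
        "mm1_per_rater": {k: float(v) for k, v in res_mm1.per_rater.items()},
        "krippendorff_alpha": alpha_point.estimate,
        "krippendorff_bootstrap": {
            "mean": boot_mean,
            "ci": [boot_lo, boot_hi],
            "iterations": cfg.bootstrap_iterations,
        },
        "icc_2_1": icc_2_1(matrix).estimate,
        "kendall_w": kendalls_w(matrix).estimate,
        "cronbach_alpha": cronbach_alpha(matrix).estimate,
        "variance_components": vc.as_dict(),
        "bi1": bi1,
        "bi2": bi2,
        "shared_taste_1": 1.0 - bi1,
        "shared_taste_2": 1.0 - bi2,
    }


def _test_result_dict(res) -> dict:
    return {
        "test": res.test,
        "label": res.label,
        "statistic": res.statistic,
        "df": res.df,
        "p_raw": res.p_raw,
        "p_adjusted": res.p_adjusted,
        "alternative": res.alternative,
        "dz": res.dz,
        "n": res.n,
    }


def run_full_analysis(
    config: PipelineConfig,
    table: RatingTable,
    participants: pd.DataFrame | None = None,
) -> dict:
    """Run the complete registered + exploratory analysis; return a report dict.

    The report is JSON-serializable and deterministic for a fixed config
    (bootstrap seeds are derived from ``config.seed``).  Stages: exclusion
    filter, per-style profiles, H1A (directional singing contrasts on
    per-rater z(MM1), Holm-adjusted, all three must be significant), H1B
    (TOST/NHST quadrant for AD vs ID), H2 (interstyle consistency against
    the 0.8 threshold), liking contrasts, intrarater reliability, and
    covariate analyses when a participants frame is given.
    """
    filtered, excluded = filter_flat_raters(table, config.flat_threshold)
    styles = list(config.styles) if config.styles else filtered.styles
    seeds = np.random.SeedSequence(config.seed).generate_state(len(styles) + 1)

    profiles = {}
    for i, style in enumerate(styles):
        profiles[style] = _style_profile(
            filtered.subset_style(style), config, int(seeds[i] % (2**31))
        )

    z_mm1 = pd.DataFrame(
        {
            style: pd.Series(profiles[style]["mm1_per_rater"]).map(
                lambda r: float(fisher_z(r))
            )
            for style in styles
        }
    )

    # H1A: lullaby > pop, pop > opera, lullaby > opera (one-tailed, Holm)
    h1a = None
    singing = [s for s in ("lullaby", "pop", "opera") if s in styles]
    if len(singing) == 3:
        contrasts = [("lullaby", "pop"), ("pop", "opera"), ("lullaby", "opera")]
        tests = []
        for a, b in contrasts:
            try:
                res = paired_t(
                    z_mm1[a].to_numpy(), z_mm1[b].to_numpy(), alternative="greater"
                )
            except DegenerateDifferencesError:
                # all per-rater z's identical: no evidence of a direction
                res = TestResult(
                    test="paired_t", statistic=0.0, p_raw=1.0,
                    n=len(z_mm1), df=len(z_mm1) - 1,
                    alternative="greater", dz=0.0, degenerate=True,
                )
            res.label = f"{a} > {b}"
            tests.append(res)
        adjusted = holm_adjust([t.p_raw for t in tests])
        for t, p_adj in zip(tests, adjusted):
            t.p_adjusted = p_adj
        supported = all(t.p_adjusted < config.alpha for t in tests)
        h1a = {
            "contrasts": [_test_result_dict(t) for t in tests],
            "supported": bool(supported),
            "verdict": (
                "H1A supported: all three directional contrasts significant"
                if supported
                else "H1A not supported"
            ),
        }

    # H1B: AD equivalent to ID (TOST + NHST quadrant)
    h1b = None
    if "AD" in styles and "ID" in styles:
        x, y = z_mm1["AD"].to_numpy(), z_mm1["ID"].to_numpy()
        try:
            lower, upper, equivalent = tost_paired(
                x, y, sesoi_dz=config.sesoi_dz, alpha=config.alpha
            )
            nhst = paired_t(x, y, alternative="two_sided")
        except DegenerateDifferencesError:
            n = len(x)
            if np.allclose(x, y):
                # identical agreement in both styles: trivially equivalent
                lower = TestResult(
                    test="tost_lower", statistic=np.inf, p_raw=0.0, n=n,
                    df=n - 1, alternative="greater", dz=0.0, degenerate=True,
                )
                upper = TestResult(
                    test="tost_upper", statistic=-np.inf, p_raw=0.0, n=n,
                    df=n - 1, alternative="less", dz=0.0, degenerate=True,
                )
                equivalent = True
                nhst = TestResult(
                    test="paired_t", statistic=0.0, p_raw=1.0, n=n, df=n - 1,
                    alternative="two_sided", dz=0.0, degenerate=True,
                )
            else:
                raise
        nhst_sig = nhst.p_raw < config.alpha
        if equivalent and not nhst_sig:
            verdict = "no meaningful difference (equivalent)"
        elif equivalent and nhst_sig:
            verdict = "statistically different but within the SESOI"
        elif nhst_sig:
            verdict = "meaningfully different"
        else:
            verdict = "inconclusive"
        h1b = {
            "tost_lower": _test_result_dict(lower),
            "tost_upper": _test_result_dict(upper),
            "tost_p": max(lower.p_raw, upper.p_raw),
            "equivalent": bool(equivalent),
            "nhst": _test_result_dict(nhst),
            "verdict": verdict,
        }

    # H2: interstyle consistency
    singer_matrix = grand_average_by_singer(filtered)
    inter = interstyle_mm1(singer_matrix[styles] if config.styles else singer_matrix)
    verdict = consistency_verdict(inter, config.interstyle_threshold)
    inter_matrix = singer_matrix.T
    interstyle = {
        "mm1": inter["estimate"],
        "ci": [inter["ci_low"], inter["ci_high"]],
        "per_style": {k: float(v) for k, v in inter["per_style"].items()},
        **verdict,
        "krippendorff_alpha": krippendorff_alpha(inter_matrix).estimate,
        "icc_2_1": icc_2_1(inter_matrix).estimate,
        "pairwise_correlations": pairwise_style_correlations(singer_matrix)
        .round(10)
        .to_dict(),
        "singer_by_style": singer_matrix.round(10).to_dict(),
    }

    # exploratory: liking contrasts and intrarater reliability
    liking = [
        _test_result_dict(r) for r in liking_contrasts(filtered, config.alpha)
    ]
    _, intrarater = intrarater_reliability(filtered)

    covariates = None
    if participants is not None:
        participants = participants.set_index("rater_id")
        covariates = {}
        if "gold_msi" in participants.columns:
            gm = pd.to_numeric(participants["gold_msi"], errors="coerce")
            covariates["gold_msi_mm1_correlation"] = (
                covariate_agreement_correlation(z_mm1, gm).to_dict("index")
            )
        from .inference import group_contrasts

        for genre, col in (("opera", "opera_pref"), ("pop", "pop_pref")):
            if col not in participants.columns or genre not in styles:
                continue
            groups = participants[col].map(FAN_GROUPS).dropna()
            z_style = z_mm1[genre]
            by_group = {
                name: z_style.reindex(members.index).dropna().to_numpy()
                for name, members in groups.groupby(groups)
            }
            by_group = {k: v for k, v in by_group.items() if len(v) >= 2}
            if len(by_group) >= 2:
                covariates[f"{genre}_fan_contrasts"] = [
                    _test_result_dict(r) for r in group_contrasts(by_group)
                ]

    mm1_ranking = sorted(styles, key=lambda s: profiles[s]["mm1"], reverse=True)
    report = {
        "software": {"package": "sharedtaste", "version": __version__},
        "config": {
            "styles": styles,
            "flat_threshold": config.flat_threshold,
            "interstyle_threshold": config.interstyle_threshold,
            "sesoi_dz": config.sesoi_dz,
            "alpha": config.alpha,
            "adjust": config.adjust,
            "bootstrap_iterations": config.bootstrap_iterations,
            "seed": config.seed,
        },
        "excluded_raters": excluded,
        "n_raters": len(filtered.raters),
        "style_profiles": profiles,
        "mm1_ranking": mm1_ranking,
        "h1a": h1a,
        "h1b": h1b,
        "interstyle": interstyle,
        "liking_contrasts": liking,
        "intrarater": intrarater,
        "covariates": covariates,
        "cross_measure_table": {
            style: {
                "mm1": profiles[style]["mm1"],
                "kendall_w": profiles[style]["kendall_w"],
                "krippendorff_alpha": profiles[style]["krippendorff_alpha"],
                "icc_2_1": profiles[style]["icc_2_1"],
                "cronbach_alpha": profiles[style]["cronbach_alpha"],
                "shared_taste_1": profiles[style]["shared_taste_1"],
                "shared_taste_2": profiles[style]["shared_taste_2"],
            }
            for style in styles
        },
    }
    return report


def report_to_json(report: dict, path) -> None:
    """Serialize a report bundle to JSON (stable key order)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
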