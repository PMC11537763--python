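import numpy as np
import pandas as pd
import pytest

from sharedtaste import (
    BeholderIndices,
    RatingTable,
    SyntheticConfig,
    average_sessions,
    beholder_indices,
    estimate_variance_components,
    generate_ratings,
    icc_2_1,
    shared_taste_complement,
)
from sharedtaste.varcomp import NotCrossedError, _henderson_balanced


def _tiny_table(values: np.ndarray) -> RatingTable:
    """values shaped (n_raters, n_items, n_sessions)."""
    n_r, n_i, n_t = values.shape
    meta = pd.DataFrame(
        {
            "stimulus_id": [f"x{i}" for i in range(n_i)],
            "singer_id": "s1",
            "melody_id": "m1",
            "style": "pop",
        }
    )
    rows = []
    for r in range(n_r):
        for i in range(n_i):
            for t in range(n_t):
                rows.append((f"r{r}", f"x{i}", t + 1, values[r, i, t]))
    records = pd.DataFrame(
        rows, columns=["rater_id", "stimulus_id", "session", "rating"]
    )
    return RatingTable(records, meta)


class TestHendersonEstimator:
    def test_constant_table_all_zero(self):
        table = _tiny_table(np.full((3, 4, 2), 5.0))
        vc = estimate_variance_components(table)
        assert all(v == 0 for v in vc.as_dict().values())

    def test_hand_computed_mean_squares(self):
        """2x2x2 design checked against mean squares computed from scratch."""
        vals = np.array(
            [[[1.0, 2.0], [3.0, 5.0]], [[2.0, 2.0], [6.0, 9.0]]]
        )  # (rater, item, time)
        table = _tiny_table(vals)
        vc = estimate_variance_components(table, truncate=False)

        # independent oracle: marginal means and EMS solved by hand rules
        grand = vals.mean()
        ms_r = 4 * np.sum((vals.mean(axis=(1, 2)) - grand) ** 2) / 1
        ms_i = 4 * np.sum((vals.mean(axis=(0, 2)) - grand) ** 2) / 1
        ms_t = 4 * np.sum((vals.mean(axis=(0, 1)) - grand) ** 2) / 1
        m_ri = vals.mean(axis=2)
        ss_ri = 2 * np.sum(
            (
                m_ri
                - vals.mean(axis=(1, 2))[:, None]
                - vals.mean(axis=(0, 2))[None, :]
                + grand
            )
            ** 2
        )
        m_rt = vals.mean(axis=1)
        ss_rt = 2 * np.sum(
            (
                m_rt
                - vals.mean(axis=(1, 2))[:, None]
                - vals.mean(axis=(0, 1))[None, :]
                + grand
            )
            ** 2
        )
        m_it = vals.mean(axis=0)
        ss_it = 2 * np.sum(
            (
                m_it
                - vals.mean(axis=(0, 2))[:, None]
                - vals.mean(axis=(0, 1))[None, :]
                + grand
            )
            ** 2
        )
        ss_tot = np.sum((vals - grand) ** 2)
        ss_rit = ss_tot - (ms_r + ms_i + ms_t) / 4 * 4 - ss_ri - ss_rt - ss_it
        mse = (ss_it + ss_rit) / (1 + 1)
        assert vc.residual == pytest.approx(mse)
        assert vc.rater_item == pytest.approx((ss_ri / 1 - mse) / 2)
        assert vc.rater_time == pytest.approx((ss_rt / 1 - mse) / 2)
        assert vc.item == pytest.approx((ms_i - ss_ri) / 4)
        assert vc.time == pytest.approx((ms_t - ss_rt) / 4)
        assert vc.rater == pytest.approx((ms_r - ss_ri - ss_rt + mse) / 4)

    def test_recovery_at_study_size(self):
        """Mean estimate across seeds within 3 SE of the configured truth."""
        truth = {
            "item": 1.0,
            "rater": 0.5,
            "rater_item": 1.0,
            "time": 0.0,
            "rater_time": 0.0,
            "residual": 0.25,
        }
        estimates = {k: [] for k in truth}
        for seed in range(15):
            cfg = SyntheticConfig(
                sigma2_item=1.0,
                sigma2_rater=0.5,
                sigma2_rater_item=1.0,
                sigma2_time=0.0,
                sigma2_rater_time=0.0,
                sigma2_res=0.25,
                discretize=False,
                singer_quality_share=0.0,
                seed=seed,
            )
            table, _ = generate_ratings(cfg)
            vc = estimate_variance_components(
                table.subset_style("lullaby"), truncate=False
            )
            for k in truth:
                estimates[k].append(getattr(vc, k))
        for k, vals in estimates.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth[k]) <= 3 * max(se, 1e-6), k

    def test_too_few_facet_levels_rejected(self):
        table = _tiny_table(np.arange(1.0, 9.0).reshape(2, 2, 2))
        single_session = RatingTable(
            table.records[table.records.session == 1].copy(), table.meta
        )
        with pytest.raises(NotCrossedError, match="levels per facet"):
            estimate_variance_components(single_session)


class TestEMEstimator:
    def test_agrees_with_closed_form_on_balanced_data(self):
        cfg = SyntheticConfig(
            n_raters=6,
            n_singers=3,
            n_melodies=2,
            styles=("pop",),
            sigma2_item=1.0,
            sigma2_rater=0.5,
            sigma2_rater_item=1.0,
            sigma2_time=0.1,
            sigma2_rater_time=0.2,
            sigma2_res=0.5,
            discretize=False,
            seed=3,
        )
        table, _ = generate_ratings(cfg)
        anova = estimate_variance_components(table, estimator="anova_mom")
        em = estimate_variance_components(
            table, estimator="reml_em", max_iter=5000
        )
        for k, v in anova.as_dict().items():
            assert em.as_dict()[k] == pytest.approx(v, abs=1e-4), k

    def test_unbalanced_falls_back_to_em(self):
        cfg = SyntheticConfig(
            n_raters=5, n_singers=3, n_melodies=2, styles=("pop",),
            discretize=False, seed=9,
        )
        table, _ = generate_ratings(cfg)
        rec = table.records.iloc[:-3].copy()  # drop cells -> unbalanced
        vc = estimate_variance_components(
            RatingTable(rec, table.meta), max_iter=5000
        )
        assert vc.estimator == "reml_em"
        assert vc.total > 0


class TestBeholderIndices:
    def test_direct_ratios(self):
        from sharedtaste.varcomp import VarianceComponents

        vc = VarianceComponents(
            rater=0.5, item=1.0, time=0.0, rater_item=1.0, rater_time=0.0,
            residual=0.3, estimator="anova_mom", n_rater=2, n_item=2, n_time=2,
        )
        bi = beholder_indices(vc)
        assert bi.bi1 == pytest.approx(0.5)
        assert bi.bi2 == pytest.approx(0.6)

    def test_no_private_taste(self):
        from sharedtaste.varcomp import VarianceComponents

        vc = VarianceComponents(
            rater=0.0, item=1.0, time=0.0, rater_item=0.0, rater_time=0.0,
            residual=0.3, estimator="anova_mom", n_rater=2, n_item=2, n_time=2,
        )
        assert beholder_indices(vc).bi1 == 0.0

    def test_bi2_at_least_bi1_with_rater_bias(self, study_table):
        table, _ = study_table
        vc = estimate_variance_components(table.subset_style("pop"))
        bi = beholder_indices(vc)
        assert 0 <= bi.bi1 <= bi.bi2 <= 1

    def test_recovery_of_configured_ratio(self, study_table):
        table, truth = study_table
        for style in ("lullaby", "AD"):
            vc = estimate_variance_components(table.subset_style(style))
            bi = beholder_indices(vc)
            assert bi.bi1 == pytest.approx(truth.implied_bi1[style], abs=0.05)

    def test_shared_taste_complement(self):
        assert shared_taste_complement(BeholderIndices(0.59, 0.80)) == (
            pytest.approx(0.41),
            pytest.approx(0.20),
        )
        assert shared_taste_complement(BeholderIndices(0.0, 0.0)) == (1.0, 1.0)


class TestICCEquivalence:
    def test_icc_identity_on_session_collapsed_matrix(self):
        """ICC(2,1) equals the variance-ratio with suitably pooled residual.

        On balanced data, ICC(2,1) of the session-averaged matrix is
        item / (item + rater + rater_time/n_t + rater_item + residual/n_t)
        with untruncated component estimates — an exact algebraic identity.
        """
        rng = np.random.default_rng(8)
        for seed in rng.integers(0, 2**31, size=5):
            cfg = SyntheticConfig(
                n_raters=7, n_singers=4, n_melodies=2, styles=("pop",),
                discretize=False, seed=int(seed),
            )
            table, _ = generate_ratings(cfg)
            vc = estimate_variance_components(table, truncate=False)
            n_t = vc.n_time
            ratio = vc.item / (
                vc.item
                + vc.rater
                + vc.rater_time / n_t
                + vc.rater_item
                + vc.residual / n_t
            )
            icc = icc_2_1(average_sessions(table)).estimate
            assert icc == pytest.approx(ratio, abs=1e-10)


class TestBiMonotonicity:
    def test_more_private_variance_raises_bi1(self):
        means = []
        for s2_ri in (0.4, 1.6):
            vals = []
            for seed in range(4):
                cfg = SyntheticConfig(
                    n_raters=20, n_singers=8, n_melodies=2, styles=("pop",),
                    sigma2_item=1.0, sigma2_rater_item=s2_ri,
                    discretize=False, seed=100 + seed,
                )
                table, _ = generate_ratings(cfg)
                vc = estimate_variance_components(table)
                vals.append(beholder_indices(vc).bi1)
            means.append(np.mean(vals))
        assert means[0] < means[1]
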