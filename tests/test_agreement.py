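import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sharedtaste import (
    DegenerateDataError,
    SyntheticConfig,
    average_sessions,
    cronbach_alpha,
    fisher_z,
    fisher_z_inv,
    generate_ratings,
    icc_2_1,
    intrarater_reliability,
    kendalls_w,
    krippendorff_alpha,
    krippendorff_bootstrap,
    mm1,
    mm1_ci,
    slice_by_style,
)


class TestFisherTransform:
    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, r):
        assert fisher_z_inv(fisher_z(r)) == pytest.approx(r, abs=1e-9)

    def test_known_value(self):
        assert fisher_z(0.6) == pytest.approx(0.5 * np.log(4), rel=1e-12)
        assert fisher_z(0.0) == 0.0

    def test_perfect_correlation_clamped(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert fisher_z_inv(z) == pytest.approx(1.0, abs=1e-9)


def _mm1_naive(matrix: pd.DataFrame) -> float:
    """Independent double-loop oracle for MM1."""
    zs = []
    for rater in matrix.index:
        others = matrix.drop(index=rater).mean(axis=0)
        r = stats.pearsonr(matrix.loc[rater], others).statistic
        zs.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
    return float(np.tanh(np.mean(zs)))


class TestMM1:
    def test_hand_derived_fixture(self, fixture_matrix):
        res = mm1(fixture_matrix)
        assert res.per_rater["r1"] == pytest.approx(0.8944, abs=1e-4)
        assert res.per_rater["r2"] == pytest.approx(0.8944, abs=1e-4)
        assert res.per_rater["r3"] == pytest.approx(0.6, abs=1e-12)
        assert res.estimate == pytest.approx(0.832, abs=1e-3)

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = pd.DataFrame(rng.normal(size=(5, 8)))
            assert mm1(m).estimate == pytest.approx(_mm1_naive(m), abs=1e-12)

    def test_identical_raters_give_one(self):
        m = pd.DataFrame([[1, 5, 3, 7]] * 4)
        assert mm1(m).estimate == pytest.approx(1.0, abs=1e-6)

    def test_constant_rater_dropped(self, fixture_matrix):
        m = pd.concat(
            [
                fixture_matrix,
                pd.DataFrame(
                    [[5, 5, 5, 5]], index=["flat"], columns=fixture_matrix.columns
                ),
            ]
        )
        with pytest.warns(UserWarning, match="dropped"):
            res = mm1(m)
        assert res.dropped_raters == ["flat"]
        assert len(res.per_rater) == 3

    def test_too_few_usable_raters(self):
        m = pd.DataFrame([[1, 2, 3], [5, 5, 5], [4, 4, 4]])
        with pytest.raises(DegenerateDataError, match="fewer than 2"):
            mm1(m)

    def test_invariant_to_shifting_one_rater(self, fixture_matrix):
        shifted = fixture_matrix.copy()
        shifted.loc["r3"] += 3
        assert mm1(shifted).estimate == pytest.approx(
            mm1(fixture_matrix).estimate, abs=1e-12
        )
        # absolute-agreement measures are *not* shift-invariant
        assert krippendorff_alpha(shifted).estimate < krippendorff_alpha(
            fixture_matrix
        ).estimate
        assert icc_2_1(shifted).estimate < icc_2_1(fixture_matrix).estimate


class TestMM1CI:
    def test_equal_correlations_zero_width(self):
        m = pd.DataFrame(
            [[1.0, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4]]
        )
        noise = np.random.default_rng(0).normal(0, 1e-9, size=m.shape)
        res = mm1(m + noise)  # jitter so correlations defined, all ~equal
        low, high = mm1_ci(res)
        assert high - low == pytest.approx(0.0, abs=1e-4)

    def test_fixture_interval(self, fixture_matrix):
        res = mm1(fixture_matrix)
        low, high = mm1_ci(res)
        zs = np.arctanh([0.894427190999916, 0.894427190999916, 0.6])
        se = zs.std(ddof=1) / np.sqrt(3)
        assert low == pytest.approx(np.tanh(zs.mean() - 1.959964 * se), abs=1e-5)
        assert high == pytest.approx(np.tanh(zs.mean() + 1.959964 * se), abs=1e-5)
        assert low < res.estimate < high

    def test_study_size_ci_width(self, study_table):
        table, _ = study_table
        matrix = slice_by_style(average_sessions(table), "lullaby", table.meta)
        res = mm1(matrix)
        low, high = mm1_ci(res)
        # with 62 raters the CI half-width is around +-0.05
        assert 0.01 < (high - low) / 2 < 0.12


class TestKrippendorff:
    def test_hand_derived_fixture(self, fixture_matrix):
        res = krippendorff_alpha(fixture_matrix)
        assert res.estimate == pytest.approx(1 - (8 / 12) / (360 / 132), abs=1e-12)
        assert res.estimate == pytest.approx(0.7556, abs=1e-4)

    def test_identical_raters_full_agreement(self):
        m = pd.DataFrame([[1, 5, 3, 7]] * 3)
        assert krippendorff_alpha(m).estimate == pytest.approx(1.0)

    def test_no_variation_is_undefined(self):
        with pytest.raises(DegenerateDataError):
            krippendorff_alpha(pd.DataFrame([[5, 5, 5]] * 3))

    def test_shuffled_raters_near_zero(self):
        rng = np.random.default_rng(3)
        base = rng.integers(1, 10, size=(30, 200))
        shuffled = np.vstack([rng.permutation(row) for row in base])
        assert abs(krippendorff_alpha(pd.DataFrame(shuffled)).estimate) < 0.05

    def test_nominal_and_ordinal_levels_run(self, fixture_matrix):
        for level in ("nominal", "ordinal"):
            est = krippendorff_alpha(fixture_matrix, level=level).estimate
            assert -1 <= est <= 1


class TestKrippendorffBootstrap:
    def test_identical_raters_degenerate_ci(self):
        m = pd.DataFrame([[1, 5, 3, 7, 2]] * 3)
        mean, lo, hi = krippendorff_bootstrap(m, iterations=50, seed=0)
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_mean_consistent_with_point_estimate(self, study_table):
        table, _ = study_table
        matrix = slice_by_style(average_sessions(table), "pop", table.meta)
        point = krippendorff_alpha(matrix).estimate
        mean, lo, hi = krippendorff_bootstrap(matrix, iterations=100, seed=1)
        assert lo <= mean <= hi
        assert abs(mean - point) < (hi - lo)

    def test_iteration_count_insensitive(self, study_table):
        table, _ = study_table
        matrix = slice_by_style(average_sessions(table), "pop", table.meta)
        m10, lo, hi = krippendorff_bootstrap(matrix, iterations=10, seed=2)
        m100, _, _ = krippendorff_bootstrap(matrix, iterations=100, seed=2)
        assert abs(m10 - m100) < (hi - lo)

    def test_pair_resampling_variant(self, fixture_matrix):
        mean, lo, hi = krippendorff_bootstrap(
            fixture_matrix, iterations=200, seed=3, unit="pairs"
        )
        assert lo <= mean <= hi
        assert mean == pytest.approx(0.756, abs=0.1)


class TestICC:
    def test_hand_derived_fixture(self, fixture_matrix):
        assert icc_2_1(fixture_matrix).estimate == pytest.approx(
            (4.1111111 - 0.4444444)
            / (4.1111111 + 2 * 0.4444444 + 3 * (0 - 0.4444444) / 4),
            abs=1e-6,
        )

    def test_identical_raters(self):
        m = pd.DataFrame([[1, 5, 3, 7]] * 3)
        assert icc_2_1(m).estimate == pytest.approx(1.0)

    def test_matches_pingouin(self, study_table):
        pingouin = pytest.importorskip("pingouin")
        table, _ = study_table
        matrix = slice_by_style(average_sessions(table), "opera", table.meta)
        long = matrix.iloc[:10, :20].stack().reset_index()
        long.columns = ["rater", "target", "rating"]
        icc = pingouin.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="rating"
        )
        # absolute agreement, single rater: labelled ICC2 or ICC(A,1)
        mask = icc["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = float(icc.loc[mask, "ICC"].iloc[0])
        ours = icc_2_1(matrix.iloc[:10, :20]).estimate
        assert ours == pytest.approx(ref, abs=1e-6)


class TestKendallW:
    def test_hand_derived_fixture(self, fixture_matrix):
        assert kendalls_w(fixture_matrix).estimate == pytest.approx(444 / 540)

    def test_identical_rankings(self):
        m = pd.DataFrame([[1, 5, 3, 7]] * 3)
        assert kendalls_w(m).estimate == pytest.approx(1.0)

    def test_reversed_rankings_cancel(self):
        m = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert kendalls_w(m).estimate == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_undefined(self):
        with pytest.raises(DegenerateDataError):
            kendalls_w(pd.DataFrame([[5, 5, 5]] * 3))


class TestCronbach:
    def test_hand_derived_fixture(self, fixture_matrix):
        assert cronbach_alpha(fixture_matrix).estimate == pytest.approx(33 / 37)

    def test_identical_raters(self):
        m = pd.DataFrame([[1, 5, 3, 7]] * 3)
        assert cronbach_alpha(m).estimate == pytest.approx(1.0)

    def test_consistency_at_least_absolute_agreement(self, fixture_matrix):
        assert (
            cronbach_alpha(fixture_matrix).estimate
            >= icc_2_1(fixture_matrix).estimate
        )


class TestIntraraterReliability:
    def _two_session_table(self, transform):
        cfg = SyntheticConfig(
            n_raters=5, n_singers=3, n_melodies=2, styles=("pop",), seed=4
        )
        table, _ = generate_ratings(cfg)
        rec = table.records.copy()
        s1 = rec[rec.session == 1]
        s2 = s1.copy()
        s2["session"] = 2
        s2["rating"] = transform(s1["rating"].to_numpy())
        from sharedtaste import RatingTable

        return RatingTable(pd.concat([s1, s2]), table.meta)

    def test_identical_sessions(self):
        table = self._two_session_table(lambda r: r)
        rs, summary = intrarater_reliability(table)
        assert np.allclose(rs.dropna(), 1.0)
        assert summary["mean"] == pytest.approx(1.0)

    def test_reversed_sessions(self):
        table = self._two_session_table(lambda r: 10 - r)
        rs, _ = intrarater_reliability(table)
        assert np.allclose(rs.dropna(), -1.0)

    def test_stable_private_taste_is_time_consistent(self):
        cfg = SyntheticConfig(
            sigma2_item=0.5,
            sigma2_rater_item=3.0,
            sigma2_res=0.2,
            discretize=False,
            n_raters=20,
            seed=6,
        )
        table, _ = generate_ratings(cfg)
        _, summary = intrarater_reliability(table)
        assert summary["mean"] > 0.8


class TestCrossMeasureOrdering:
    def test_correlational_above_absolute_with_rater_bias(self, study_table):
        """With rater bias variance > 0, MM1 and W exceed alpha_K and ICC."""
        table, _ = study_table
        matrix = average_sessions(table)
        for style in table.styles:
            sliced = slice_by_style(matrix, style, table.meta)
            correlational = min(mm1(sliced).estimate, kendalls_w(sliced).estimate)
            absolute = max(
                krippendorff_alpha(sliced).estimate, icc_2_1(sliced).estimate
            )
            assert correlational > absolute
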