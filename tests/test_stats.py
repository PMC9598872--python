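import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from phenocycle.stats import (
    DayGroupData,
    balanced_anova_components,
    ci_overlap_significant,
    confidence_band,
    daily_blues,
    divergence_onset,
    maturity_day,
    repeatability,
    response_lag,
    senescence_onset,
    stay_green_score,
    summary_ttest,
    tukey_filter,
    two_sample_ttest,
    variance_components,
)
from phenocycle.synthetic import sample_one_way_table


def groups_from_df(df):
    return {g: p["value"].to_numpy(float) for g, p in df.groupby("genotype")}


def day(groups):
    return DayGroupData(1, "control", "x", groups)


class TestTukeyFilter:
    def test_identical_values_all_kept(self):
        assert tukey_filter([3.0] * 6).all()

    def test_hand_computed_fences(self):
        """{1..9, 100}: Q1 = 3.25, Q3 = 7.75 (linear interpolation),
        IQR = 4.5, fences [-3.5, 14.5] -> only 100 removed."""
        kept = tukey_filter(list(range(1, 10)) + [100])
        assert kept.tolist() == [True] * 9 + [False]

    def test_small_lists_kept_whole(self):
        assert tukey_filter([5.0]).all()
        assert tukey_filter([1.0, 100.0, -50.0]).all()

    @given(hst.lists(hst.floats(-1e6, 1e6), min_size=4, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_never_removes_the_median(self, values):
        kept = tukey_filter(values)
        med = np.median(values)
        closest = int(np.argmin(np.abs(np.asarray(values) - med)))
        assert kept[closest]


class TestDailyBlues:
    def test_blue_is_group_mean(self):
        out = daily_blues(day({"g1": np.array([2.0, 4.0])}))
        assert out.blue.iloc[0] == pytest.approx(3.0)

    def test_unbalanced_blues_match_normal_equations(self, rng):
        """Solve the fixed-effect normal equations directly (cell-means
        design matrix, least squares) and compare."""
        groups = {f"g{i}": rng.normal(i, 1.0, size=n)
                  for i, n in enumerate([4, 7, 5])}
        out = daily_blues(day(groups))
        y = np.concatenate(list(groups.values()))
        X = np.zeros((len(y), 3))
        start = 0
        for j, v in enumerate(groups.values()):
            X[start:start + len(v), j] = 1.0
            start += len(v)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(out.blue.to_numpy(), beta)

    def test_constant_shift_equivariance(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 5) for i in range(3)}
        a = daily_blues(day(groups)).blue.to_numpy()
        shifted = {k: v + 7.5 for k, v in groups.items()}
        b = daily_blues(day(shifted)).blue.to_numpy()
        assert np.allclose(b - a, 7.5)

    def test_pooled_se_scales_with_group_size(self, rng):
        groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(0, 1, 16)}
        out = daily_blues(day(groups)).set_index("genotype")
        assert out.loc["a", "se"] == pytest.approx(2 * out.loc["b", "se"])


class TestVarianceComponents:
    def test_no_between_group_signal(self):
        groups = {"a": np.array([1.0, 3.0]), "b": np.array([1.0, 3.0]),
                  "c": np.array([1.0, 3.0])}
        v_g, v_e = variance_components(day(groups))
        assert v_g == 0.0
        assert v_e > 0.0

    def test_balanced_toy_table_matches_closed_form(self, rng):
        df = sample_one_way_table(2.0, 1.0, 3, 4, rng)
        d = day(groups_from_df(df))
        v_g, v_e = variance_components(d)
        v_g_cf, v_e_cf = balanced_anova_components(d)
        if v_g_cf > 0:
            assert v_g == pytest.approx(v_g_cf, rel=1e-8)
            assert v_e == pytest.approx(v_e_cf, rel=1e-8)

    def test_monte_carlo_parameter_recovery(self, rng):
        """500 simulated days with vG=4, ve=1, 6 genotypes x 10 reps:
        mean estimates land within 10% of the truth."""
        ests = np.array([
            variance_components(day(groups_from_df(
                sample_one_way_table(4.0, 1.0, 6, 10, rng))))
            for _ in range(500)
        ])
        assert ests[:, 0].mean() == pytest.approx(4.0, rel=0.10)
        assert ests[:, 1].mean() == pytest.approx(1.0, rel=0.10)

    def test_unbalanced_agrees_with_mixedlm(self, rng):
        """statsmodels MixedLM (REML random intercept) as an independent
        oracle on an unbalanced layout."""
        sm = pytest.importorskip("statsmodels.api")
        df = sample_one_way_table(2.0, 1.0, 6, 10, rng).drop(
            index=[0, 1, 11, 25]
        )
        v_g, v_e = variance_components(day(groups_from_df(df)))
        fit = sm.MixedLM.from_formula("value ~ 1", groups="genotype",
                                      data=df).fit(reml=True)
        assert v_g == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-4)
        assert v_e == pytest.approx(float(fit.scale), rel=1e-4)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            variance_components(day({"a": np.array([1.0, 2.0])}))


class TestRepeatability:
    @pytest.mark.parametrize("v_g,v_e,n,expected", [
        (1.0, 0.0, 10, 1.0),
        (0.0, 1.0, 10, 0.0),
        (1.0, 1.0, 10, 1.0 / 1.1),
    ])
    def test_formula(self, v_g, v_e, n, expected):
        assert repeatability(v_g, v_e, n) == pytest.approx(expected)

    def test_undefined_when_no_variance(self):
        assert np.isnan(repeatability(0.0, 0.0, 10))

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.1, 5, 12)
        r_vg = [repeatability(v, 1.0, 10) for v in grid]
        r_ve = [repeatability(1.0, v, 10) for v in grid]
        r_n = [repeatability(1.0, 1.0, n) for n in range(1, 30)]
        assert all(a < b for a, b in zip(r_vg, r_vg[1:]))
        assert all(a > b for a, b in zip(r_ve, r_ve[1:]))
        assert all(a < b for a, b in zip(r_n, r_n[1:]))


class TestTTests:
    def test_identical_groups(self):
        t, df, p, sig = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_printed_tiller_contrast_is_significant(self):
        """Summary stats of the durum parent/NIL tiller contrast at DAS 28
        under drought (2.40+/-0.52 vs 3.30+/-0.48, n=10) give p < 0.01."""
        t, df, p, sig = summary_ttest(2.40, 0.52, 10, 3.30, 0.48, 10)
        assert df == 18
        assert p < 0.01 and sig

    def test_printed_seed_length_contrast(self):
        _, _, p, sig = summary_ttest(5.94, 0.10, 10, 6.32, 0.25, 10)
        assert p < 0.01 and sig

    def test_summary_matches_raw_data(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 12)))
            b = rng.normal(0.5, 1.5, int(rng.integers(3, 12)))
            t1, df1, p1, _ = two_sample_ttest(a, b)
            t2, df2, p2, _ = summary_ttest(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            assert t1 == pytest.approx(t2)
            assert df1 == pytest.approx(df2)
            assert p1 == pytest.approx(p2)

    def test_welch_flag_changes_df(self):
        _, df_pooled, _, _ = summary_ttest(0, 1, 10, 0.5, 3, 10)
        _, df_welch, _, _ = summary_ttest(0, 1, 10, 0.5, 3, 10, welch=True)
        assert df_pooled == 18 and df_welch < 18

    def test_summary_of_itself_gives_p_one(self):
        _, _, p, sig = summary_ttest(3.0, 0.0, 10, 3.0, 0.0, 10)
        assert p == 1.0 and not sig


class TestConfidenceBands:
    def test_zero_se_gives_point_band(self):
        assert confidence_band(5.0, 0.0, 9) == (5.0, 5.0)

    def test_width_linear_in_se(self):
        lo1, hi1 = confidence_band(0.0, 1.0, 9)
        lo2, hi2 = confidence_band(0.0, 2.0, 9)
        assert hi2 - lo2 == pytest.approx(2 * (hi1 - lo1))

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            confidence_band(0.0, 1.0, 0)

    def test_monte_carlo_coverage(self, rng):
        """~95% of 1000 simulated group means are covered by their band."""
        hits = 0
        for _ in range(1000):
            x = rng.normal(10.0, 2.0, 10)
            lo, hi = confidence_band(x.mean(), x.std(ddof=1) / np.sqrt(10), 9)
            hits += lo <= 10.0 <= hi
        assert 930 <= hits <= 975

    def test_overlap_rule(self):
        assert not ci_overlap_significant((0.0, 1.0), (0.0, 1.0))
        assert ci_overlap_significant((0.0, 1.0), (2.0, 3.0))
        assert ci_overlap_significant((2.0, 3.0), (0.0, 1.0))
        assert not ci_overlap_significant((0.0, 1.5), (1.0, 2.0))

    def test_disjoint_bands_imply_significant_ttest(self, rng):
        """One-way implication on random two-group draws: disjoint 95%
        bands always come with t-test p < 0.05 (never the converse)."""
        for _ in range(1000):
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(rng.uniform(0, 2.5), 1.0, 10)
            band_a = confidence_band(a.mean(), a.std(ddof=1) / np.sqrt(10), 9)
            band_b = confidence_band(b.mean(), b.std(ddof=1) / np.sqrt(10), 9)
            if ci_overlap_significant(band_a, band_b):
                _, _, p, _ = two_sample_ttest(a, b)
                assert p < 0.05


class TestDivergenceOnset:
    def test_never_significant(self):
        assert divergence_onset({d: 0.5 for d in range(1, 20)}) is None

    def test_always_significant_returns_first_day(self):
        assert divergence_onset({d: 0.01 for d in range(5, 20)}) == 5

    def test_requires_sustained_run(self):
        p = {1: 0.01, 2: 0.5, 3: 0.01, 4: 0.01, 5: 0.01, 6: 0.5}
        assert divergence_onset(p, sustain_k=3) == 3

    def test_invariant_to_trailing_non_significant_days(self):
        p = {d: (0.01 if 10 <= d <= 14 else 0.5) for d in range(1, 15)}
        onset = divergence_onset(p, sustain_k=3)
        p2 = dict(p)
        p2.update({d: 0.9 for d in range(15, 30)})
        assert divergence_onset(p2, sustain_k=3) == onset == 10

    def test_response_lag(self):
        assert response_lag(38, 44) == 6
        assert response_lag(44, 38) == -6
        assert response_lag(38, 38) == 0
        assert response_lag(None, 38) is None


class TestMaturityDay:
    def test_all_removed_same_day(self):
        assert maturity_day([100] * 10) == 100

    def test_staggered_removal_matches_enumeration(self):
        removal = [96, 96, 98, 100, 102, 104, 106, 108, 110, 121]
        # exhaustive oracle: day-by-day presence count
        need = int(np.ceil(0.7 * len(removal)))
        expected = max(d for d in range(1, 122)
                       if sum(r >= d for r in removal) >= need)
        assert maturity_day(removal, 0.7) == expected == 100

    def test_full_quorum_is_earliest_removal(self):
        assert maturity_day([96, 100, 110], quorum=1.0) == 96


class TestSenescence:
    def test_constant_series_has_no_onset(self):
        series = {d: 0.23 for d in range(1, 40)}
        assert senescence_onset(series, baseline_window=5, delta=0.02) is None

    def test_step_drop_detected_at_step(self):
        series = {d: (0.23 if d < 70 else 0.12) for d in range(1, 100)}
        assert senescence_onset(series, baseline_window=10, delta=0.02) == 70

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            senescence_onset({1: 0.2, 2: 0.2}, baseline_window=10)

    def test_logistic_decay_onset_recovery(self, rng):
        """Midpoint recovery across 20 noisy logistic decays: calibrating
        the drop threshold to half the green-to-mature span makes the
        detected day the logistic midpoint, within +/-3 days."""
        from phenocycle.synthetic import true_cva
        from tests_helpers import logistic_params

        p = logistic_params(onset=80.0)
        for _ in range(20):
            series = {d: true_cva(p, d) + rng.normal(0, 0.004)
                      for d in range(1, 122)}
            got = senescence_onset(series, baseline_window=10,
                                   delta=(p.hue_green - p.hue_mature) / 2)
            assert abs(got - 80.0) <= 3

    def test_stay_green_identical_series(self):
        a = {d: np.array([0.2, 0.21, 0.2]) for d in range(80, 100)}
        score, days = stay_green_score(a, a, (85, 95))
        assert score == 0.0 and days == []

    def test_stay_green_constant_offset(self):
        a = {d: np.full(10, 0.15) for d in range(80, 100)}
        b = {d: np.full(10, 0.15 + 0.03) for d in range(80, 100)}
        score, _ = stay_green_score(a, b, (80, 99))
        assert score == pytest.approx(0.03)

    def test_stay_green_later_senescing_genotype(self, rng):
        """A genotype senescing 8 days later scores positive with a
        contiguous late-window run of significant days."""
        from phenocycle.synthetic import true_cva
        from tests_helpers import logistic_params

        early = logistic_params(onset=70.0)
        late = logistic_params(onset=78.0)
        a = {d: true_cva(early, d) + rng.normal(0, 0.004, 10)
             for d in range(40, 100)}
        b = {d: true_cva(late, d) + rng.normal(0, 0.004, 10)
             for d in range(40, 100)}
        score, days = stay_green_score(a, b, (60, 90))
        assert score > 0
        assert len(days) >= 5
        assert days == list(range(min(days), max(days) + 1))

    def test_stay_green_empty_window_rejected(self):
        a = {d: np.full(3, 0.2) for d in range(10, 20)}
        with pytest.raises(ValueError):
            stay_green_score(a, a, (50, 60))
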