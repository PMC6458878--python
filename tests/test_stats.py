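"""Statistical chain: LRT ANOVA, contrasts, effect sizes, Tukey, correlations,
BH adjustment, Morey error bars, median-split control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as spstats

from tinnifeed import stats as st


def make_table(n=24, timepoints=("t1", "t2", "t3", "t4"), outcome="thi",
               shifts=None, sd_between=10.0, sd_within=5.0, seed=0, base=30.0):
    rng = np.random.default_rng(seed)
    shifts = shifts or {}
    rows = []
    for i in range(n):
        b = base + rng.normal(0, sd_between)
        for tp in timepoints:
            rows.append({
                "subject": f"s{i:02d}", "timepoint": tp, "outcome": outcome,
                "value": b + shifts.get(tp, 0.0) + rng.normal(0, sd_within),
            })
    return pd.DataFrame(rows)


class TestAnova:
    def test_constant_outcome_gives_null_result(self):
        tab = make_table(sd_between=0.0, sd_within=0.0)
        tab["value"] = 5.0
        res = st.fit_time_anova(tab, "thi")
        assert res.chi_sq == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_df_bookkeeping(self):
        assert st.fit_time_anova(make_table(), "thi").df == 3
        assert st.fit_time_anova(
            make_table(timepoints=("t1", "t2", "t3")), "thi").df == 2

    def test_matches_iterative_mixed_model_fit(self):
        """Dual route: closed-form profile ML vs statsmodels MixedLM."""
        import warnings

        import statsmodels.formula.api as smf

        tab = make_table(shifts={"t2": -4.0}, seed=3)
        ours = st.fit_time_anova(tab, "thi")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm("value ~ C(timepoint)", tab,
                               groups=tab["subject"]).fit(reml=False)
            null = smf.mixedlm("value ~ 1", tab, groups=tab["subject"]).fit(reml=False)
        assert ours.chi_sq == pytest.approx(2 * (full.llf - null.llf), abs=1e-3)

    def test_unbalanced_table_rejected(self):
        tab = make_table().iloc[:-1]
        with pytest.raises(st.UnbalancedTableError):
            st.fit_time_anova(tab, "thi")


class TestContrasts:
    def test_residual_df_is_69_for_behavioral_design(self):
        cs = st.apriori_contrasts(make_table(), "thi", "decrease")
        assert [c.df for c in cs] == [69, 69, 69]
        assert [c.label for c in cs] == ["t1-t2", "t1-t3", "t1-t4"]

    def test_residual_df_is_46_for_eeg_design(self):
        cs = st.apriori_contrasts(
            make_table(timepoints=("t1", "t2", "t3")), "thi", "increase")
        assert [c.df for c in cs] == [46, 46]

    def test_zero_contrast_gives_capped_bonferroni_p(self):
        tab = make_table(sd_between=3.0, sd_within=2.0, seed=1)
        wide = st.pivot_outcome(tab, "thi")
        # force equal timepoint means -> t exactly 0
        x = wide.to_numpy()
        x -= x.mean(axis=0, keepdims=True) - x.mean()
        rows = [
            {"subject": s, "timepoint": tp, "outcome": "thi", "value": x[i, j]}
            for i, s in enumerate(wide.index)
            for j, tp in enumerate(wide.columns)
        ]
        cs = st.apriori_contrasts(pd.DataFrame(rows), "thi", "decrease")
        for c in cs:
            assert c.t == pytest.approx(0.0, abs=1e-10)
            assert c.p_one_tailed == pytest.approx(0.5, abs=1e-10)
            assert c.p_one_tailed_bonf == 1.0

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            st.apriori_contrasts(make_table(), "thi", None)

    def test_printed_contrast_p_values_reproduce(self):
        """Bonferroni one-tailed p recomputed from published t/df pairs."""
        cases = [  # (t, df, n_contrasts, direction, printed p)
            (-2.76, 69, 3, "decrease", 0.011),
            (-2.30, 69, 3, "decrease", 0.037),
            (-2.34, 69, 3, "decrease", 0.033),
            (-2.21, 69, 3, "decrease", 0.046),
            (-2.74, 69, 3, "decrease", 0.012),
            (2.83, 46, 2, "increase", 0.007),
            (-2.42, 46, 2, "decrease", 0.020),
        ]
        for t, df, m, direction, printed in cases:
            p = st.one_tailed_bonferroni_p(t, df, m, direction)
            assert round(p, 3) == printed


class TestEffectSize:
    @pytest.mark.parametrize(
        "t,df,expected",
        [(-2.76, 69, 0.32), (2.83, 46, 0.39), (0.0, 10, 0.0), (-2.42, 46, 0.34)],
    )
    def test_published_conversions(self, t, df, expected):
        assert round(st.effect_size_r(t, df), 2) == expected

    def test_symmetric_in_sign(self):
        assert st.effect_size_r(2.5, 40) == st.effect_size_r(-2.5, 40)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t=hst.floats(0.1, 50.0), df=hst.integers(2, 500))
    def test_monotone_in_t_and_df(self, t, df):
        r = st.effect_size_r(t, df)
        assert 0 < r < 1
        assert st.effect_size_r(t + 0.5, df) > r
        assert st.effect_size_r(t, df + 10) < r


class TestMeanFollowup:
    def test_equal_timepoints_give_zero_t(self):
        tab = make_table(sd_within=0.0, sd_between=5.0, seed=2)
        res = st.mean_followup_contrast(tab, "thi")
        assert res.t == pytest.approx(0.0, abs=1e-9)
        assert res.df == 69

    def test_sign_tracks_injected_direction(self):
        hits = 0
        for seed in range(20):
            tab = make_table(shifts={"t2": -3, "t3": -3, "t4": -3}, seed=seed)
            hits += st.mean_followup_contrast(tab, "thi").t < 0
        assert hits >= 19


class TestTukey:
    def test_four_timepoints_give_six_comparisons(self):
        tk = st.tukey_posthoc(make_table(), "thi")
        assert len(tk) == 6
        assert (tk.p_tukey >= tk.p_unadjusted - 1e-12).all()

    def test_two_timepoints_reduce_to_plain_t_test(self):
        tab = make_table(timepoints=("t1", "t2"), shifts={"t2": -2.0}, seed=4)
        tk = st.tukey_posthoc(tab, "thi")
        assert len(tk) == 1
        assert tk.p_tukey[0] == pytest.approx(tk.p_unadjusted[0], abs=1e-6)


class TestDiffCorr:
    def test_perfect_negative_relation(self):
        x = np.arange(10.0)
        r, p, df = st.diff_corr(x, -x, alternative="less")
        assert r == pytest.approx(-1.0)
        assert df == 8

    def test_df_for_study_sample_size(self):
        rng = np.random.default_rng(0)
        r, p, df = st.diff_corr(rng.normal(size=24), rng.normal(size=24))
        assert df == 22  # reported as r(22)

    def test_incomplete_cases_rejected(self):
        with pytest.raises(ValueError):
            st.diff_corr([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestBH:
    def test_single_p_unchanged(self):
        assert st.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(st.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(1e-6, 1.0), min_size=4, max_size=4))
    def test_matches_brute_force_step_up(self, ps):
        def oracle(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                k = m - rank_from_top
                prev = min(prev, p[i] * m / k)
                adj[i] = prev
            return adj

        assert np.allclose(st.bh_adjust(ps), oracle(ps), atol=1e-12)


class TestMoreySE:
    def test_correction_factor_for_four_timepoints(self):
        # zero between-subject variance: Morey SE = ordinary SE * sqrt(T/(T-1))
        tab = make_table(sd_between=0.0, sd_within=6.0, seed=5)
        wide = st.pivot_outcome(tab, "thi")
        ordinary = wide.std(ddof=1) / np.sqrt(len(wide))
        morey = st.morey_within_se(tab, "thi")
        # subject-centering removes a df worth of variance; compare the
        # analytic factor on the centered data instead of raw SEs
        x = wide.to_numpy()
        centered = x - x.mean(axis=1, keepdims=True) + x.mean()
        base = centered.std(axis=0, ddof=1) / np.sqrt(len(wide))
        assert np.allclose(morey, base * np.sqrt(4 / 3))
        assert np.sqrt(4 / 3) == pytest.approx(1.1547, abs=1e-4)

    def test_invariant_to_additive_subject_offsets(self):
        tab = make_table(seed=6)
        offset = tab.copy()
        shift = {f"s{i:02d}": 100.0 * i for i in range(24)}
        offset["value"] = offset["value"] + offset["subject"].map(shift)
        assert np.allclose(
            st.morey_within_se(tab, "thi"), st.morey_within_se(offset, "thi")
        )


class TestAgeMedianSplit:
    def test_toy_median_and_grouping(self):
        tab = make_table(n=4, seed=7)
        ages = {"s00": 30, "s01": 40, "s02": 50, "s03": 60}
        res = st.age_median_split_control(tab, "thi", ages)
        assert res.median_age == 45.0
        assert res.n_young == 2 and res.n_old == 2
        assert res.df == 4

    def test_ties_assigned_to_young_group(self):
        tab = make_table(n=3, seed=8)
        res = st.age_median_split_control(tab, "thi", {"s00": 40, "s01": 44, "s02": 50})
        assert res.median_age == 44.0
        assert res.n_young == 2  # the median-aged subject counts as young

    def test_no_interaction_cohorts_rarely_significant(self):
        nonsig = 0
        n_rep = 40
        for seed in range(n_rep):
            tab = make_table(shifts={"t2": -4.0}, seed=seed)
            ages = {f"s{i:02d}": 25 + 2 * i for i in range(24)}
            nonsig += st.age_median_split_control(tab, "thi", ages).p >= 0.05
        assert nonsig >= int(0.9 * n_rep)

    def test_matches_iterative_mixed_model_fit(self):
        import warnings

        import statsmodels.formula.api as smf

        tab = make_table(shifts={"t2": -4.0}, seed=9)
        ages = {f"s{i:02d}": 25 + 2 * i for i in range(24)}
        ours = st.age_median_split_control(tab, "thi", ages)
        long = tab.copy()
        long["group"] = np.where(
            long["subject"].map(ages) <= ours.median_age, "young", "old")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm("value ~ C(timepoint) * C(group)", long,
                               groups=long["subject"]).fit(reml=False)
            null = smf.mixedlm("value ~ C(timepoint)", long,
                               groups=long["subject"]).fit(reml=False)
        assert ours.chi_sq == pytest.approx(2 * (full.llf - null.llf), abs=1e-3)
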