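"""Contrast layer: t-tests, effect sizes, sensitivity power, contrast table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuralign.stats import (
    PairingError,
    SummaryStats,
    build_contrast_table,
    cohens_d_from_t,
    cohens_d_pooled,
    paired_t,
    sensitivity_power,
    two_tailed_p,
    welch_t,
)


def diffs_with(mean, sd, n, seed=0):
    """A difference vector with exactly the requested mean/sd."""
    x = np.random.default_rng(seed).standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestPairedT:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_formula_and_scipy(self, seed):
        d = np.random.default_rng(seed).standard_normal(12)
        t, df, p = paired_t(d)
        assert t == pytest.approx(
            d.mean() / (d.std(ddof=1) / np.sqrt(12)), abs=1e-10
        )
        assert df == 11
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_case(self):
        d = diffs_with(0.0, 1.0, 37)
        t, df, p = paired_t(d)
        assert abs(t) < 1e-10 and p > 0.999

    def test_reported_political_incongruent_conversion(self):
        # a difference vector with t = 2.362 at n = 37 gives p = 0.024
        t_target = 2.362
        d = diffs_with(t_target / np.sqrt(37), 1.0, 37)
        t, df, p = paired_t(d)
        assert t == pytest.approx(t_target, abs=1e-9)
        assert df == 36
        assert round(p, 3) == 0.024

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            paired_t(np.ones(10))
        with pytest.raises(ValueError):
            paired_t(np.array([1.0]))


class TestWelch:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_summary_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = SummaryStats(rng.normal(), rng.uniform(0.5, 3), int(rng.integers(5, 50)))
        b = SummaryStats(rng.normal(), rng.uniform(0.5, 3), int(rng.integers(5, 50)))
        t, df, p = welch_t(a, b)
        ref = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                       equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_equal_means_and_antisymmetry(self):
        a = SummaryStats(5.0, 1.0, 10)
        b = SummaryStats(5.0, 2.0, 12)
        t, _, p = welch_t(a, b)
        assert t == 0.0 and p == pytest.approx(1.0)
        c = SummaryStats(6.0, 2.0, 12)
        assert welch_t(a, c)[0] == pytest.approx(-welch_t(c, a)[0])

    def test_identity_threat_summaries(self):
        # from the printed group summaries (7.34 +/- 2.32 vs 6.03 +/- 3.09)
        t, df, p = welch_t(SummaryStats(7.34, 2.32, 37),
                           SummaryStats(6.03, 3.09, 42))
        assert t == pytest.approx(2.1455, abs=1e-3)
        assert df == pytest.approx(75.19, abs=0.01)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            welch_t(SummaryStats(1.0, 0.0, 5), SummaryStats(2.0, 0.0, 5))


class TestEffectSizes:
    @pytest.mark.parametrize(
        "t, n, expected",
        [(2.362, 37, 0.388), (2.669, 37, 0.439), (-1.035, 37, -0.170),
         (-1.916, 42, -0.296), (0.0, 10, 0.0)],
    )
    def test_paired_d_from_t(self, t, n, expected):
        assert round(cohens_d_from_t(t, n), 3) == expected

    def test_pooled_d(self):
        a = SummaryStats(7.34, 2.32, 37)
        b = SummaryStats(6.03, 3.09, 42)
        assert round(abs(cohens_d_pooled(a, b)), 2) == 0.48
        assert cohens_d_pooled(a, a) == 0.0
        half_a = SummaryStats(7.34, 1.16, 37)
        half_b = SummaryStats(6.03, 1.545, 42)
        assert cohens_d_pooled(half_a, half_b) == pytest.approx(
            2 * cohens_d_pooled(a, b)
        )

    def test_pooled_degenerate(self):
        with pytest.raises(ValueError):
            cohens_d_pooled(SummaryStats(1, 0.0, 5), SummaryStats(1, 0.0, 5))


class TestTwoTailedP:
    @pytest.mark.parametrize(
        "t, df, expected",
        [(2.362, 36, 0.024), (2.669, 36, 0.011), (-0.185, 41, 0.854)],
    )
    def test_reported_conversions(self, t, df, expected):
        assert round(two_tailed_p(t, df), 3) == expected

    def test_zero_statistic(self):
        assert two_tailed_p(0.0, 17) == pytest.approx(1.0)

    def test_consistent_with_paired_t(self):
        d = diffs_with(0.3, 1.0, 20, seed=3)
        t, df, p = paired_t(d)
        assert p == pytest.approx(two_tailed_p(t, df), abs=1e-15)


class TestSensitivityPower:
    def test_preregistered_cohort_sensitivity(self):
        # n=37, two-sided alpha 0.05, 80% power -> minimal detectable d
        assert round(sensitivity_power(37, 0.05, 0.80), 2) == 0.47

    def test_against_grid_search_oracle(self):
        # brute-force sweep of the noncentral-t power curve
        n, alpha, power = 24, 0.05, 0.80
        grid = np.arange(0.01, 2.0, 1e-4)
        crit = sps.t.ppf(1 - alpha / 2, n - 1)
        # scipy's nct underflows to NaN in the far opposite tail; that term
        # is ~1e-25 there, so treat NaN as zero
        pw = (sps.nct.sf(crit, n - 1, grid * np.sqrt(n))
              + np.nan_to_num(sps.nct.cdf(-crit, n - 1, grid * np.sqrt(n))))
        oracle = grid[np.argmin(np.abs(pw - power))]
        assert sensitivity_power(n, alpha, power) == pytest.approx(
            oracle, abs=2e-4
        )

    def test_monotone_in_n_and_power(self):
        ds = [sensitivity_power(n) for n in (10, 20, 40, 80)]
        assert all(b < a for a, b in zip(ds, ds[1:]))
        ps = [sensitivity_power(37, power=p) for p in (0.5, 0.7, 0.9)]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_low_power_limit_and_errors(self):
        assert sensitivity_power(37, 0.05, 0.051) < 0.05
        with pytest.raises(ValueError):
            sensitivity_power(37, 0.05, 0.04)
        with pytest.raises(ValueError):
            sensitivity_power(1)


class TestContrastTable:
    @staticmethod
    def subject_table(effects, n=10, noise_sd=0.1, seed=0):
        """Long-format ISC table; ``effects[(group, condition)]`` is the
        post-minus-pre shift added for that row."""
        rng = np.random.default_rng(seed)
        rows = []
        for group in ("intervention", "control"):
            for condition in ("political", "nonpolitical"):
                for subject in range(n):
                    base = 0.3 + 0.05 * rng.standard_normal()
                    for session in ("pre", "post"):
                        for version in ("v1", "v2"):
                            val = base + noise_sd * rng.standard_normal()
                            if session == "post":
                                val += effects.get((group, condition), 0.0)
                            rows.append(dict(group=group, session=session,
                                             version=version,
                                             condition=condition,
                                             subject=f"{group}-{subject}",
                                             isc=val))
        return pd.DataFrame(rows)

    def test_row_count_and_columns(self):
        tab = build_contrast_table(self.subject_table({}))
        assert len(tab) == 4  # groups x conditions
        assert {"t", "df", "p", "cohens_d", "n", "p_fdr"} <= set(tab.columns)
        assert (tab.df == tab.n - 1).all()

    def test_detects_targeted_effect(self):
        effects = {("intervention", "political"): 1.0}
        tab = build_contrast_table(self.subject_table(effects, seed=1))
        hit = tab[(tab.group == "intervention") & (tab.condition == "political")]
        assert (hit.p_fdr < 0.05).all()
        assert hit.t.iloc[0] > 0
        # the targeted row carries by far the smallest p-value
        assert hit.p.iloc[0] == tab.p.min()

    def test_t_matches_paired_t_on_the_same_diffs(self):
        df = self.subject_table({("control", "political"): 0.2}, seed=2)
        tab = build_contrast_table(df)
        means = df.groupby(
            ["group", "condition", "session", "subject"]
        )["isc"].mean().reset_index()
        wide = means[(means.group == "control")
                     & (means.condition == "political")].pivot(
            index="subject", columns="session", values="isc")
        t, _, _ = paired_t((wide["post"] - wide["pre"]).to_numpy())
        row = tab[(tab.group == "control") & (tab.condition == "political")]
        assert row.t.iloc[0] == pytest.approx(t, abs=1e-12)

    def test_unmatched_subjects_rejected(self):
        df = self.subject_table({})
        df = df[~((df.subject == "control-3") & (df.session == "post"))]
        with pytest.raises(PairingError, match="control-3"):
            build_contrast_table(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            build_contrast_table(pd.DataFrame({"group": [], "isc": []}))
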