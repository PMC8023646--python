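"""Cox regression by score tertile, chi-square machinery, LPS fold changes
and baseline tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microrem import (
    association_score_lps,
    baseline_table,
    chi2_test,
    cox_by_score_tertile,
    lps_fold_change,
    simulate_tertile_survival,
)
from microrem.outcomes import FitError, ContingencyTestError


def chi2_formula_oracle(counts):
    """Textbook Pearson chi-square: sum (O-E)^2 / E with margin-product E."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    stat = ((counts - expected) ** 2 / expected).sum()
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, stats.chi2.sf(stat, df)


class TestChi2:
    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            shape = rng.choice([2, 3]), rng.choice([2, 3])
            counts = rng.integers(1, 60, size=shape)
            res = chi2_test(counts)
            stat, p = chi2_formula_oracle(counts)
            assert res["statistic"] == pytest.approx(stat, abs=1e-10)
            assert res["p_value"] == pytest.approx(p, abs=1e-10)

    def test_identical_row_proportions_give_zero_statistic(self):
        res = chi2_test([[2, 42], [3, 63]])
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ContingencyTestError):
            chi2_test([[0, 0], [3, 5]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ContingencyTestError):
            chi2_test([[1.5, 2], [3, 4]])

    def test_continuity_correction_available_behind_flag(self):
        uncorrected = chi2_test([[10, 20], [30, 15]])
        corrected = chi2_test([[10, 20], [30, 15]], correction=True)
        assert corrected["statistic"] < uncorrected["statistic"]


class TestLpsFoldChange:
    def _lps(self, fasting, post):
        return pd.DataFrame(
            {"fasting_lps": fasting, "postprandial_lps": post},
            index=[f"S{i}" for i in range(len(fasting))],
        )

    def test_ratio_computed_exactly(self):
        fold, _ = lps_fold_change(
            self._lps([2.0, 1.0, 4.0, 2.0], [3.0, 1.0, 5.0, 8.0])
        )
        assert fold.iloc[0] == pytest.approx(1.5)
        assert fold.iloc[1] == pytest.approx(1.0)  # equal fasting/postprandial

    def test_non_positive_values_excluded(self):
        lps = self._lps([2.0, 0.0, 1.0, 2.0, 1.0], [3.0, 1.0, -1.0, 4.0, 2.5])
        fold, tert = lps_fold_change(lps)
        assert list(fold.index) == ["S0", "S3", "S4"]
        assert len(tert) == 3

    def test_tertile_sizes_near_equal_for_110(self):
        rng = np.random.default_rng(1)
        fasting = np.exp(rng.normal(-1, 0.3, 110))
        post = fasting * np.exp(rng.normal(0.4, 0.4, 110))
        _, tert = lps_fold_change(self._lps(fasting, post))
        counts = tert.value_counts()
        assert counts.max() - counts.min() <= 1


class TestAssociationScoreLps:
    def _tertiles(self, codes, index=None):
        index = index or [f"S{i}" for i in range(len(codes))]
        return pd.Series(pd.Categorical([f"T{c}" for c in codes],
                                        categories=["T1", "T2", "T3"], ordered=True),
                         index=index)

    def test_perfect_antidiagonal_gives_rho_minus_one(self):
        score = self._tertiles([1] * 10 + [2] * 10 + [3] * 10)
        lps = self._tertiles([3] * 10 + [2] * 10 + [1] * 10)
        res = association_score_lps(score, lps)
        assert res["spearman_rho"] == pytest.approx(-1.0)
        assert np.fliplr(res["table"].to_numpy()).trace() == 30

    def test_independent_partitions_give_uniform_p(self):
        """chi-square p on independent tertile partitions is U(0,1)
        (KS not rejected at the 1% level, 500 replicates)."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(500):
            a = self._tertiles(rng.integers(1, 4, size=120))
            b = self._tertiles(rng.integers(1, 4, size=120))
            pvals.append(association_score_lps(a, b)["p_value"])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_coupled_synthetic_cohorts_show_inverse_relation(self):
        """lps_coupling=-0.5 cohorts give a negative score-LPS rank
        correlation in >= 90% of 50 replicates."""
        from microrem import build_score_rules, generate_cohort, patient_score
        from microrem.simulate import SimulationConfig

        negative = 0
        for seed in range(50):
            c = generate_cohort(SimulationConfig(seed=seed, lps_coupling=-0.5))
            imp = pd.DataFrame({"mda": [0.04] * 10}, index=list(c.truth))
            rules = build_score_rules(c.abundance, c.cohort.responder, imp)
            res = patient_score(c.abundance, rules)
            _, lps_tert = lps_fold_change(c.cohort.lps)
            assoc = association_score_lps(res.tertiles, lps_tert)
            negative += assoc["spearman_rho"] < 0
        assert negative / 50 >= 0.9

    def test_disjoint_samples_rejected(self):
        a = self._tertiles([1, 2, 3], index=["A", "B", "C"])
        b = self._tertiles([1, 2, 3], index=["X", "Y", "Z"])
        with pytest.raises(ValueError):
            association_score_lps(a, b)


def _cox_frame(df, rng, n):
    """Attach independent adjustment covariates to a survival frame."""
    df = df.copy()
    df["age"] = rng.normal(60, 8, n)
    df["bmi"] = rng.normal(31, 4, n)
    df["gender_male"] = rng.integers(0, 2, n)
    df["diet_mediterranean"] = rng.integers(0, 2, n)
    df["hdl"] = rng.normal(1.1, 0.3, n)
    df["triglycerides"] = rng.normal(1.6, 0.6, n)
    df["statin_intensity"] = rng.integers(0, 3, n)
    return df


class TestCoxByScoreTertile:
    def test_null_tertiles_cover_hr_one(self):
        """Tertile labels independent of hazard: the 95% CI contains 1 in
        >= 93% of 100 simulated cohorts (n=300)."""
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = simulate_tertile_survival(n=300, rate_ratio=1.0, seed=seed)
            df = _cox_frame(df, rng, 300)
            tert = df.pop("tertile").astype(str)
            res = cox_by_score_tertile(df, tert, "primary")
            s = res.summary.loc["T2"]
            covered += s["hr_lower"] <= 1.0 <= s["hr_upper"]
        assert covered / 100 >= 0.93

    def test_recovers_known_rate_ratio(self):
        """True per-tertile hazard ratio 2.0 (n=1000) is recovered within
        [1.8, 2.2] on average over replicates."""
        hrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = simulate_tertile_survival(n=1000, rate_ratio=2.0, seed=seed)
            df = _cox_frame(df, rng, 1000)
            tert = df.pop("tertile").astype(str)
            res = cox_by_score_tertile(df, tert, "primary")
            hrs.append(res.summary.loc["T2", "hr"])
            hrs.append(np.sqrt(res.summary.loc["T3", "hr"]))
        assert 1.8 <= np.mean(hrs) <= 2.2

    def test_all_censored_raises_fit_error(self):
        rng = np.random.default_rng(0)
        df = simulate_tertile_survival(n=90, rate_ratio=1.0, seed=0)
        df = _cox_frame(df, rng, 90)
        df["event"] = 0
        tert = df.pop("tertile").astype(str)
        with pytest.raises(FitError):
            cox_by_score_tertile(df, tert, "primary")

    def test_curves_are_cumulative_remission_probabilities(self):
        rng = np.random.default_rng(3)
        df = simulate_tertile_survival(n=300, rate_ratio=2.0, seed=3)
        df = _cox_frame(df, rng, 300)
        tert = df.pop("tertile").astype(str)
        res = cox_by_score_tertile(df, tert, "primary")
        curves = res.curves
        assert set(curves.columns) == {"T1", "T2", "T3"}
        for col in curves:
            assert curves[col].between(0, 1).all()
            assert curves[col].is_monotonic_increasing
        # higher-hazard tertile remits faster
        assert curves["T3"].iloc[-1] >= curves["T1"].iloc[-1]

    def test_unknown_adjustment_set_rejected(self):
        rng = np.random.default_rng(0)
        df = simulate_tertile_survival(n=90, seed=0)
        df = _cox_frame(df, rng, 90)
        tert = df.pop("tertile").astype(str)
        with pytest.raises(ValueError, match="adjustment"):
            cox_by_score_tertile(df, tert, "bogus")


class TestBaselineTable:
    def test_identical_groups_give_p_one(self):
        clinical = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=clinical.index)
        out = baseline_table(clinical, labels, continuous=["x"], categorical=[])
        assert out.loc["x", "p_value"] == pytest.approx(1.0)

    def test_anova_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 55)
        clinical = pd.DataFrame({"x": np.concatenate([a, b])})
        labels = pd.Series([0] * 40 + [1] * 55, index=clinical.index)
        out = baseline_table(clinical, labels, continuous=["x"], categorical=[])
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        f, p_f = stats.f_oneway(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert out.loc["x", "p_value"] == pytest.approx(p_t, rel=1e-10)

    def test_weight_magnitude_difference_is_significant(self):
        """Groups simulated to match a mean gap of 80.2 vs 88.4 kg with
        SEMs 1.3 / 1.4 (n=73 / 110) give ANOVA p < 0.001, agreeing with the
        summary-statistic oracle."""
        n1, n2 = 73, 110
        m1, m2, sem1, sem2 = 80.2, 88.4, 1.3, 1.4
        sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
        rng = np.random.default_rng(5)

        def standardize(x, m, sd):
            return (x - x.mean()) / x.std(ddof=1) * sd + m

        a = standardize(rng.normal(size=n1), m1, sd1)
        b = standardize(rng.normal(size=n2), m2, sd2)
        clinical = pd.DataFrame({"weight": np.concatenate([a, b])})
        labels = pd.Series([1] * n1 + [0] * n2, index=clinical.index)
        out = baseline_table(clinical, labels, continuous=["weight"], categorical=[])
        # summary-statistic ANOVA oracle
        gm = (n1 * m1 + n2 * m2) / (n1 + n2)
        ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
        ssw = (n1 - 1) * sd1**2 + (n2 - 1) * sd2**2
        f_oracle = ssb / (ssw / (n1 + n2 - 2))
        p_oracle = stats.f.sf(f_oracle, 1, n1 + n2 - 2)
        assert out.loc["weight", "p_value"] == pytest.approx(p_oracle, rel=1e-9)
        assert out.loc["weight", "p_value"] < 0.001

    def test_zero_variance_flagged(self):
        clinical = pd.DataFrame({"x": [2.0] * 6})
        labels = pd.Series([0] * 3 + [1] * 3, index=clinical.index)
        out = baseline_table(clinical, labels, continuous=["x"], categorical=[])
        assert out.loc["x", "p_value"] == 1.0 and bool(out.loc["x", "degenerate"])

    def test_categorical_uses_chi_square(self, default_cohort):
        out = baseline_table(
            default_cohort.cohort.clinical,
            default_cohort.cohort.responder,
            continuous=["age"],
            categorical=["gender_male"],
        )
        tab = pd.crosstab(
            default_cohort.cohort.responder,
            default_cohort.cohort.clinical["gender_male"],
        )
        assert out.loc["gender_male", "p_value"] == pytest.approx(
            chi2_test(tab)["p_value"], rel=1e-12
        )
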