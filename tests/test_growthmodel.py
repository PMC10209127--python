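"""Cross-sectional age fits and the random-slope growth model."""

import math

import numpy as np
import pandas as pd
import pytest

from clonedyn import (
    CohortConfig,
    call_table,
    fit_carrier_vs_age,
    fit_logvaf_vs_age,
    fit_mixed_growth,
    generate_longitudinal_cohort,
    generate_single_timepoint_cohort,
    rate_from_slope,
    run_single_timepoint,
    slope_from_rate,
)
from clonedyn.errors import InputError, InsufficientDataError, SeparationError


class TestRateConversion:
    def test_reported_coefficient_conversion(self):
        """A reported-scale log-VAF age coefficient of 0.059 is a ~6% larger clone per year."""
        assert rate_from_slope(0.059) == pytest.approx(6.0775, abs=1e-3)
        assert round(rate_from_slope(0.059)) == 6

    @pytest.mark.parametrize("slope", [-0.05, 0.0, 0.02, 0.0677, 0.25])
    def test_round_trip(self, slope):
        assert slope_from_rate(rate_from_slope(slope)) == pytest.approx(
            slope, abs=1e-12)

    def test_monotone_and_bounded_below(self):
        slopes = np.linspace(-3, 1, 101)
        rates = [rate_from_slope(s) for s in slopes]
        assert all(b > a for a, b in zip(rates, rates[1:]))
        assert all(r > -100 for r in rates)


class TestLogVafVsAge:
    def test_exact_noiseless_coefficient(self):
        age = np.linspace(40, 70, 50)
        df = pd.DataFrame({"age_years": age,
                           "vaf_pct": np.exp(0.059 * age - 3.0)})
        fit = fit_logvaf_vs_age(df)
        assert fit.logvaf_age_coef == pytest.approx(0.059, abs=1e-12)
        assert fit.pct_per_year == pytest.approx(100 * (math.e ** 0.059 - 1),
                                                 abs=1e-9)

    def test_null_under_permutation(self):
        rng = np.random.default_rng(31)
        age = rng.uniform(40, 70, 1000)
        vaf = np.exp(0.059 * age + rng.normal(0, 1, 1000) - 3)
        df = pd.DataFrame({"age_years": age, "vaf_pct": rng.permutation(vaf)})
        fit = fit_logvaf_vs_age(df)
        assert abs(fit.logvaf_age_coef) < 3 * fit.std_err

    def test_recovery_from_synthetic_cohort(self):
        """Planted log-age effect 0.059 at n = 1050 recovered within 2 SE."""
        cfg = CohortConfig(seed=3, n_individuals=1050, timepoints=(0.0,),
                           dropout_pattern=(1.0,), coverage_mean=2840.0,
                           baseline_age_range=(37.0, 70.0),
                           vaf_age_log_slope=0.059)
        obs, clin = generate_single_timepoint_cohort(cfg)
        rep = run_single_timepoint(obs, clin)
        fit = rep.logvaf_fit
        assert abs(fit.logvaf_age_coef - 0.059) < 2 * fit.std_err

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_logvaf_vs_age(pd.DataFrame({"age_years": [50, 60],
                                            "vaf_pct": [1.0, 2.0]}))


class TestCarrierVsAge:
    @staticmethod
    def _cohort(rng, n, slope):
        from scipy.special import expit

        age = rng.uniform(37, 70, n)
        p = expit(math.log(0.206 / 0.794) + slope * (age - age.mean()))
        return pd.DataFrame({"age_years": age,
                             "carrier": rng.random(n) < p})

    def test_null_slope(self):
        rng = np.random.default_rng(41)
        fit = fit_carrier_vs_age(self._cohort(rng, 10_000, 0.0))
        assert abs(fit.logistic_age_coef) < 3 * fit.std_err

    def test_recovery(self):
        rng = np.random.default_rng(42)
        fit = fit_carrier_vs_age(self._cohort(rng, 10_000, 0.05))
        assert abs(fit.logistic_age_coef - 0.05) < 2 * fit.std_err

    def test_perfect_separation(self):
        df = pd.DataFrame({"age_years": [40, 41, 42, 60, 61, 62],
                           "carrier": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(SeparationError):
            fit_carrier_vs_age(df)

    def test_single_class(self):
        df = pd.DataFrame({"age_years": [40, 50, 60], "carrier": [1, 1, 1]})
        with pytest.raises(SeparationError):
            fit_carrier_vs_age(df)


def _ols_slope(age, y):
    A = np.column_stack([np.ones(len(age)), age])
    return float(np.linalg.lstsq(A, y, rcond=None)[0][1])


class TestMixedGrowth:
    def test_single_individual_noiseless_exact(self):
        b = 0.08
        age = np.array([50.0, 52.0, 60.0, 65.0, 70.0])
        df = pd.DataFrame({"individual_id": "A", "age_years": age,
                           "vaf_pct": 2.0 * np.exp(b * (age - 50.0))})
        fit = fit_mixed_growth(df)
        assert fit.estimates[0].slope_log_per_year == pytest.approx(b, abs=1e-8)
        assert fit.fixed_slope_log_per_year == pytest.approx(b, abs=1e-8)

    def test_dense_noiseless_matches_per_individual_ols(self):
        """With wide between-individual slope spread and dense noiseless
        sampling, the mixed-model BLUP slopes coincide with per-individual
        OLS slopes (residual variance -> 0, shrinkage -> none)."""
        rng = np.random.default_rng(0)
        rows, slopes = [], {}
        for i in range(8):
            b = 0.02 + 0.05 * i
            a0 = rng.uniform(-2, 2)
            for a in np.linspace(45, 65, 20):
                rows.append({"individual_id": f"I{i}", "age_years": a,
                             "vaf_pct": math.exp(a0 + b * (a - 45))})
            slopes[f"I{i}"] = b
        fit = fit_mixed_growth(pd.DataFrame(rows))
        for e in fit.estimates:
            assert e.slope_log_per_year == pytest.approx(slopes[e.individual_id],
                                                         abs=1e-6)

    def test_mean_rate_recovery(self, growth_cohort_config):
        """35-individual synthetic cohort planted at 7%/yr mean growth:
        recovered cohort mean rate within 1.5 pp of 7."""
        from clonedyn import run_longitudinal

        obs, clin, _ = generate_longitudinal_cohort(growth_cohort_config)
        rep = run_longitudinal(obs, clin, run_sensitivity=False)
        assert rep.growth.mean_rate_pct_per_year == pytest.approx(7.0, abs=1.5)

    def test_shrinkage_partial_pooling(self, growth_cohort_config):
        """BLUP slopes lie (to numerical slack) between the fixed-effect
        slope and each individual's own OLS slope; a correlated 2-D BLUP may
        overshoot the interval by O(1e-4), hence the tolerance."""
        from clonedyn import run_longitudinal
        from clonedyn.pipeline import dominant_long_table

        obs, clin, _ = generate_longitudinal_cohort(growth_cohort_config)
        rep = run_longitudinal(obs, clin, run_sensitivity=False)
        long = dominant_long_table(rep.dominant)
        fixed = rep.growth.fixed_slope_log_per_year
        for e in rep.growth.estimates:
            sub = long[long["individual_id"] == e.individual_id]
            ols = _ols_slope(sub["age_years"].to_numpy(),
                             np.log(sub["vaf_pct"].to_numpy()))
            lo, hi = sorted([fixed, ols])
            assert lo - 1e-3 <= e.slope_log_per_year <= hi + 1e-3

    def test_strict_betweenness_balanced_design(self):
        """On a balanced design with uncorrelated random effects the slope
        BLUP is a scalar shrinkage of the OLS slope toward the fixed slope,
        so it sits strictly inside the fixed-to-OLS interval."""
        rng = np.random.default_rng(3)
        rows = []
        ages = np.array([50.0, 55.0, 60.0, 65.0, 70.0])
        for i in range(20):
            b = rng.normal(0.07, 0.05)
            a0 = rng.normal(0.0, 1.0)
            for a in ages:
                rows.append({"individual_id": f"I{i:02d}", "age_years": a,
                             "vaf_pct": math.exp(a0 + b * (a - 50)
                                                 + rng.normal(0, 0.3))})
        fit = fit_mixed_growth(pd.DataFrame(rows), force_diagonal=True)
        long = pd.DataFrame(rows)
        fixed = fit.fixed_slope_log_per_year
        for e in fit.estimates:
            sub = long[long["individual_id"] == e.individual_id]
            ols = _ols_slope(sub["age_years"].to_numpy(),
                             np.log(sub["vaf_pct"].to_numpy()))
            lo, hi = sorted([fixed, ols])
            assert lo - 1e-9 <= e.slope_log_per_year <= hi + 1e-9

    def test_mean_individual_slope_near_fixed_slope(self, growth_cohort_config):
        from clonedyn import run_longitudinal

        obs, clin, _ = generate_longitudinal_cohort(growth_cohort_config)
        rep = run_longitudinal(obs, clin, run_sensitivity=False)
        mean_slope = np.mean([e.slope_log_per_year for e in rep.growth.estimates])
        assert mean_slope == pytest.approx(rep.growth.fixed_slope_log_per_year,
                                           abs=0.01)

    def test_fixed_slope_recovery_and_coverage(self):
        """Over 200 simulated cohorts (no dominant-selection filtering, one
        clone each) the mean recovered fixed slope sits within Monte-Carlo
        error of the planted ln(1.07), and 95% Wald intervals cover the truth
        90-99% of the time."""
        true = math.log(1.07)
        ests, ses = [], []
        for seed in range(200):
            cfg = CohortConfig(seed=seed + 100, n_individuals=35,
                               multi_clone_prob=0.0,
                               dropout_pattern=(1.0, 0.95, 1.0, 0.95, 0.6))
            obs, _clin, _truth = generate_longitudinal_cohort(cfg)
            det = call_table(obs).query("detected")
            counts = det.groupby("individual_id").size()
            keep = counts[counts >= 2].index
            long = det[det["individual_id"].isin(keep)][
                ["individual_id", "age_years", "vaf_pct"]]
            fit = fit_mixed_growth(long)
            ests.append(fit.fixed_slope_log_per_year)
            ses.append(fit.fixed_slope_se)
        ests, ses = np.array(ests), np.array(ses)
        mc_err = ests.std(ddof=1) / math.sqrt(len(ests))
        # 3x MC error also absorbs the small detection-truncation bias
        assert abs(ests.mean() - true) < 3 * mc_err
        coverage = np.mean(np.abs(ests - true) <= 1.96 * ses)
        assert 0.90 <= coverage <= 0.99

    def test_raw_response_scale(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(6):
            b = rng.normal(0.1, 0.03)
            for a in np.linspace(50, 70, 6):
                rows.append({"individual_id": f"I{i}", "age_years": a,
                             "vaf_pct": 1.0 + b * (a - 50)
                             + rng.normal(0, 0.02)})
        fit = fit_mixed_growth(pd.DataFrame(rows), response_scale="raw")
        # raw-scale rates are the slopes themselves
        for e in fit.estimates:
            assert e.rate_pct_per_year == pytest.approx(e.slope_log_per_year)

    def test_too_few_points_per_individual(self):
        df = pd.DataFrame({"individual_id": ["A", "A", "B"],
                           "age_years": [50, 60, 55], "vaf_pct": [1, 2, 1]})
        with pytest.raises(InsufficientDataError):
            fit_mixed_growth(df)

    def test_nonpositive_vaf_rejected_on_log_scale(self):
        df = pd.DataFrame({"individual_id": ["A", "A"],
                           "age_years": [50, 60], "vaf_pct": [0.0, 2.0]})
        with pytest.raises(InputError):
            fit_mixed_growth(df)
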