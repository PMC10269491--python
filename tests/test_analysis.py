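"""Gated comparisons, floor rule, quadratic and linear trend fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ironclock import (
    BandLabel,
    CohortSpec,
    SubjectRecord,
    bioage_fits,
    bioage_table,
    compare_groups,
    generate_cohort,
    normality_gate,
    polyfit2,
    pvl_floor,
    relation_scan,
)
from ironclock.analysis import Normality, StatTest
from ironclock.bioage import NO_ADJUSTMENT, AdjustmentPolicy
from ironclock.calibration import fit_normalized_slope

from conftest import mean_subject


def _exact_moment_sample(n, mean, sd, rng):
    """A draw rescaled to have exactly the requested mean and SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestPvlFloor:
    @pytest.mark.parametrize("value,expected", [
        (0.0, 10.0), (19.0, 10.0), (20.0, 20.0), (3_940_000.0, 3_940_000.0),
    ])
    def test_detection_limit_rule(self, value, expected):
        assert pvl_floor(value) == expected

    @given(st.floats(0, 1e7, allow_nan=False))
    @settings(deadline=None, max_examples=100)
    def test_idempotent(self, value):
        assert pvl_floor(pvl_floor(value)) == pvl_floor(value)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pvl_floor(-1.0)

    def test_vectorized(self):
        out = pvl_floor(np.array([0.0, 19.9, 20.0, 100.0]))
        assert np.array_equal(out, [10.0, 10.0, 20.0, 100.0])


class TestNormalityGate:
    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        assert normality_gate(rng.normal(size=10_000)) is Normality.normal

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(0)
        assert normality_gate(rng.exponential(size=10_000)) is Normality.non_normal

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0, 3.0])

    def test_constant_sample_is_non_normal_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate([2.0] * 10) is Normality.non_normal


class TestCompareGroups:
    def test_identical_samples_give_null_result(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        result = compare_groups(x, x)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)
        assert result.test is StatTest.t_test
        assert result.df == 198

    def test_pooled_t_on_exact_moment_fixture(self):
        """Telomere-style fixture: n = 50/50 with means 0.83/0.69 and
        SDs 0.36/0.24 gives the closed-form pooled |t| = 2.288."""
        rng = np.random.default_rng(2)
        a = _exact_moment_sample(50, 0.83, 0.36, rng)
        b = _exact_moment_sample(50, 0.69, 0.24, rng)
        result = compare_groups(a, b, gate=(Normality.normal, Normality.normal))
        pooled = np.sqrt((49 * 0.36**2 + 49 * 0.24**2) / 98)
        expected = 0.14 / (pooled * np.sqrt(2 / 50))
        assert result.statistic == pytest.approx(expected, abs=1e-9)
        assert abs(result.statistic) == pytest.approx(2.288, abs=5e-4)
        assert result.df == 98
        assert result.summary[0] == (pytest.approx(0.83), pytest.approx(0.36))

    def test_huge_shift_is_overwhelmingly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 60)
        result = compare_groups(a, a + 10.0)
        assert result.p_value < 1e-6

    def test_mann_whitney_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a, b = rng.exponential(2, 40), rng.exponential(1, 35)
        gate = (Normality.non_normal, Normality.non_normal)
        raw = compare_groups(a, b, gate=gate)
        transformed = compare_groups(np.log(a), np.log(b), gate=gate)
        assert raw.test is StatTest.mann_whitney
        assert raw.statistic == transformed.statistic
        assert raw.p_value == pytest.approx(transformed.p_value, rel=1e-12)

    def test_gate_routes_skewed_data_to_mann_whitney(self):
        rng = np.random.default_rng(5)
        result = compare_groups(rng.lognormal(0, 1, 500), rng.lognormal(0.2, 1, 500))
        assert result.test is StatTest.mann_whitney

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_groups([3.0, 3.0, 3.0, 3.0], [3.0, 3.0, 3.0, 3.0])

    def test_rejection_rate_matches_noncentral_t_power(self):
        """With the telomere-fixture effect (d ~ 0.46, n = 50/50) the
        simulated two-sided t rejection rate over 2 000 replicates sits
        within 3 points of the closed-form noncentral-t power."""
        n, reps = 50, 2000
        rng = np.random.default_rng(6)
        a = rng.normal(0.83, 0.36, size=(reps, n))
        b = rng.normal(0.69, 0.24, size=(reps, n))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        simulated = float((p < 0.05).mean())
        pooled_sd = np.sqrt((0.36**2 + 0.24**2) / 2)
        ncp = (0.83 - 0.69) / pooled_sd * np.sqrt(n / 2)
        crit = stats.t.ppf(0.975, 2 * n - 2)
        power = (1 - stats.nct.cdf(crit, 2 * n - 2, ncp)
                 + stats.nct.cdf(-crit, 2 * n - 2, ncp))
        assert simulated == pytest.approx(power, abs=0.03)


class TestPolyfit2:
    def test_exact_quadratic_recovered(self):
        ages = np.linspace(20, 70, 30)
        values = 2.0 + 0.0 * ages + 0.5 * ages**2
        fit = polyfit2(ages, values)
        assert fit.c0 == pytest.approx(2.0, abs=1e-7)
        assert fit.c1 == pytest.approx(0.0, abs=1e-8)
        assert fit.c2 == pytest.approx(0.5, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_constant_data_gives_flat_curve(self):
        fit = polyfit2([20, 30, 40, 50], [7.0, 7.0, 7.0, 7.0])
        assert (fit.c0, fit.c1, fit.c2) == (
            pytest.approx(7.0), pytest.approx(0.0, abs=1e-12),
            pytest.approx(0.0, abs=1e-12))

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError):
            polyfit2([20, 20, 30], [1.0, 1.1, 2.0])

    def test_noisy_quadratic_recovery_within_three_se(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(20, 77, 1000)
        truth = (5.0, -0.3, 0.01)
        values = truth[0] + truth[1] * ages + truth[2] * ages**2 + rng.normal(0, 2, 1000)
        fit = polyfit2(ages, values)
        X = np.column_stack([np.ones_like(ages), ages, ages**2])
        cov = np.linalg.inv(X.T @ X) * fit.residual_sd**2
        se = np.sqrt(np.diag(cov))
        for est, true, s in zip((fit.c0, fit.c1, fit.c2), truth, se):
            assert abs(est - true) < 3 * s

    def test_linear_data_reduces_to_shared_linear_oracle(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(20, 35, 200)
        values = 3.0 + 0.2 * ages + rng.normal(0, 0.5, 200)
        quad = polyfit2(ages, values)
        line = fit_normalized_slope(ages, values)
        assert quad.c2 == pytest.approx(0.0, abs=3 * 0.002)
        # refit forcing c2 = 0 must agree with the calibration-module line
        c1, c0 = np.polyfit(ages, values, 1)
        assert (c1, c0) == (pytest.approx(line.k_x), pytest.approx(line.n_x))


class TestBioageFits:
    def test_referent_sample_recovers_identity_line(self, younger_referent,
                                                    younger_calibration):
        records = younger_referent.records
        subjects = [
            SubjectRecord(str(i), age=r.age, hiv_status="negative", rtl=r.RTL,
                          serum_iron=r.Fe, tibc=r.TIBC, ferritin=r.F)
            for i, r in records.iterrows()
        ]
        table = bioage_table(
            subjects,
            {b: younger_calibration for b in BandLabel},
            NO_ADJUSTMENT,
        )
        table["hiv_status"] = "negative"
        (identity, fitted) = bioage_fits(table)
        assert abs(fitted.slope - 1.0) < 1e-6
        assert abs(fitted.intercept) < 1e-4
        assert (identity.slope, identity.intercept) == (1.0, 0.0)

    def test_identical_biomarkers_differ_by_exactly_the_hiv_adjustment(
            self, younger_constants):
        ages = np.linspace(21, 34, 14)
        subjects = [mean_subject(younger_constants, subject_id=f"n{i}", age=a)
                    for i, a in enumerate(ages)]
        subjects += [mean_subject(younger_constants, subject_id=f"p{i}", age=a,
                                  hiv_status="positive") for i, a in enumerate(ages)]
        table = bioage_table(subjects, policy=AdjustmentPolicy())
        fits = {f.group: f for f in bioage_fits(table, subjects, include_identity=False)}
        assert fits["positive"].slope - fits["negative"].slope == pytest.approx(
            0.194, abs=1e-9)
        assert fits["positive"].intercept - fits["negative"].intercept == pytest.approx(
            -20 * 0.194, abs=1e-9)

    def test_single_group_yields_one_fit(self, younger_constants):
        subjects = [mean_subject(younger_constants, subject_id=f"s{i}", age=a)
                    for i, a in enumerate([25.0, 30.0])]
        table = bioage_table(subjects, policy=NO_ADJUSTMENT)
        fits = bioage_fits(table, subjects, include_identity=False)
        assert len(fits) == 1 and fits[0].group == "negative"

    def test_group_without_age_spread_skipped_with_warning(self, younger_constants):
        subjects = [
            mean_subject(younger_constants, subject_id="a", age=30.0),
            mean_subject(younger_constants, subject_id="b", age=30.0),
        ]
        table = bioage_table(subjects, policy=NO_ADJUSTMENT)
        with pytest.warns(UserWarning, match="distinct ages"):
            fits = bioage_fits(table, subjects, include_identity=False)
        assert fits == []


class TestRelationScan:
    def test_empty_cohort_gives_empty_report(self):
        assert relation_scan([]) == []

    def test_null_cohort_shows_no_rtl_iron_relations(self):
        # generator builds in no biomarker-biomarker correlation
        cohort = generate_cohort(CohortSpec(seed=12))
        fits = {(f.x, f.y): f for f in relation_scan(cohort)}
        for pair in (("rtl", "serum_iron"), ("rtl", "tibc"), ("rtl", "ferritin")):
            assert abs(fits[pair].r_value) < 3 / np.sqrt(fits[pair].n - 2)

    def test_injected_duration_effect_recovers_negative_sign(self):
        cohort = generate_cohort(CohortSpec(seed=13))
        # telomere attrition with time on therapy, imposed deterministically
        shifted = []
        for record in cohort:
            if record.therapy_duration is not None:
                import dataclasses

                shifted.append(dataclasses.replace(
                    record,
                    rtl=max(0.0, record.rtl - 0.004 * record.therapy_duration)))
            else:
                shifted.append(record)
        fits = {(f.x, f.y): f for f in relation_scan(shifted)}
        assert fits[("therapy_duration", "rtl")].slope < 0

    def test_pvl_floor_applied_before_fitting(self):
        cohort = generate_cohort(CohortSpec(seed=14))
        fits = {(f.x, f.y): f for f in relation_scan(cohort)}
        pvl_fit = fits[("pvl", "rtl")]
        n_positive = sum(1 for r in cohort if r.pvl is not None)
        assert pvl_fit.n == n_positive
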