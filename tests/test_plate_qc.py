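"""Assay-quality statistics: Z-factor, SW, CV, outliers, normality, power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spheroscreen as ss
from spheroscreen.plate_qc import SummaryStats, qc_stats


def stats_of(mean, sd, n=6):
    return SummaryStats(mean=mean, sd=sd, n=n)


class TestZFactor:
    def test_perfect_assay_bound(self):
        assert ss.z_factor(stats_of(100, 0), stats_of(0, 0)) == 1.0

    @pytest.mark.parametrize("ss_, sc, expect", [
        (5.0, 5.0, 0.7),    # 1 - 30/100
        (10.0, 10.0, 0.4),  # exactly the acceptance boundary
    ])
    def test_worked_examples(self, ss_, sc, expect):
        z = ss.z_factor(stats_of(100, ss_), stats_of(0, sc))
        assert z == pytest.approx(expect, abs=1e-12)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError):
            ss.z_factor(stats_of(50, 1), stats_of(50, 2))

    @given(mu_s=st.floats(-1e3, 1e3), mu_c=st.floats(-1e3, 1e3),
           sd_s=st.floats(0, 100), sd_c=st.floats(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_never_exceeds_one(self, mu_s, mu_c, sd_s, sd_c):
        if mu_s == mu_c:
            return
        z = ss.z_factor(stats_of(mu_s, sd_s), stats_of(mu_c, sd_c))
        assert z <= 1.0
        if sd_s == sd_c == 0:
            assert z == 1.0

    @given(gain=st.floats(0.1, 50), offset=st.floats(-500, 500))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, gain, offset):
        """Shared gain/offset on raw readings leaves Z and SW unchanged."""
        s, c = stats_of(100, 5), stats_of(0, 5)
        s2 = stats_of(gain * s.mean + offset, gain * s.sd)
        c2 = stats_of(gain * c.mean + offset, gain * c.sd)
        assert ss.z_factor(s2, c2) == pytest.approx(ss.z_factor(s, c), rel=1e-9)
        assert ss.signal_window(s2, c2) == pytest.approx(
            ss.signal_window(s, c), rel=1e-9)


class TestSignalWindow:
    @pytest.mark.parametrize("sd, expect", [(5.0, 14.0), (10.0, 4.0)])
    def test_worked_examples(self, sd, expect):
        assert ss.signal_window(stats_of(100, sd), stats_of(0, sd)) == \
            pytest.approx(expect, abs=1e-12)

    def test_zero_window(self):
        # separation exactly 3*(sd_h+sd_l)
        assert ss.signal_window(stats_of(60, 5), stats_of(0, 15)) == 0.0

    def test_zero_high_sd_rejected(self):
        with pytest.raises(ValueError):
            ss.signal_window(stats_of(100, 0), stats_of(0, 5))


class TestCV:
    def test_zero_sd(self):
        assert ss.cv_percent(stats_of(100, 0)) == 0.0

    def test_plate_range_example(self):
        assert ss.cv_percent(stats_of(422, 21.1)) == pytest.approx(5.0)

    def test_boundary_fails_criterion(self):
        q = qc_stats(stats_of(100, 20), stats_of(0, 1))
        assert q.cv_percent == 20.0
        assert not q.passes  # CV must be strictly below 20%

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            ss.cv_percent(stats_of(0, 5))


class TestGrowthAndDilution:
    def test_growth_increase(self):
        assert ss.growth_increase(10.0, 10.0) == 0.0
        assert ss.growth_increase(1.0, 7.0) == pytest.approx(600.0)
        assert ss.growth_increase(1.0, 2.7) == pytest.approx(170.0)
        with pytest.raises(ValueError):
            ss.growth_increase(0.0, 5.0)

    def test_residual_fraction(self):
        assert ss.residual_fraction(200, 150, 1) == 0.25
        assert ss.residual_fraction(200, 150, 2) == 0.0625
        assert ss.residual_fraction(200, 150, 0) == 1.0
        with pytest.raises(ValueError):
            ss.residual_fraction(200, 250, 1)


class TestOutliers:
    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(6)
        values = list(rng.normal(size=59)) + [10.0]
        assert ss.detect_outliers_robust(values, 1.0) == [59]

    def test_constant_data_flags_nothing(self):
        assert ss.detect_outliers_robust([5.0] * 10, 1.0) == []

    def test_clean_sample_rarely_flags(self):
        rng = np.random.default_rng(7)
        flagged = sum(len(ss.detect_outliers_robust(rng.normal(size=60), 1.0))
                      for _ in range(100))
        assert flagged / (100 * 60) <= 0.01

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ss.detect_outliers_robust([1.0, 2.0, 3.0, 4.0], 1.0)


class TestK2:
    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ss.dagostino_k2(np.arange(19.0))

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(8)
        _, p = ss.dagostino_k2(np.exp(rng.normal(size=66) * 1.5))
        assert p < 0.01

    def test_symmetric_sample_has_no_skew_contribution(self):
        from scipy import stats as sps

        # near-perfect symmetry (an exact zero trips a guard branch in
        # scipy's skewness transformation, so perturb by an epsilon)
        v = np.concatenate([np.linspace(0.2, 1, 30), -np.linspace(0.2, 1, 30)])
        v[0] += 1e-6
        k2, _ = ss.dagostino_k2(v)
        z_skew, _ = sps.skewtest(v)
        z_kurt, _ = sps.kurtosistest(v)
        assert z_skew ** 2 < 1e-3
        assert k2 == pytest.approx(z_skew ** 2 + z_kurt ** 2, abs=1e-10)


class TestDetectionPower:
    def test_null_limit_equals_alpha(self):
        p = ss.detection_power(1e-9, 15.0, 6, alpha=0.05)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_monotonicity(self):
        grid = [ss.detection_power(d, 15.0, 6) for d in (10, 20, 30)]
        assert grid == sorted(grid)
        grid = [ss.detection_power(20.0, cv, 6) for cv in (5, 10, 20)]
        assert grid == sorted(grid, reverse=True)
        grid = [ss.detection_power(20.0, 15.0, n) for n in (3, 6, 12)]
        assert grid == sorted(grid)

    def test_one_sample_design_exceeds_two_sample(self):
        two = ss.detection_power(20.0, 15.0, 6, design="two-sample")
        one = ss.detection_power(20.0, 15.0, 6, design="one-sample")
        assert one > two  # fixed reference mean removes control variance

    @pytest.mark.parametrize("kwargs", [
        {"drop_percent": 0.0}, {"drop_percent": 100.0},
        {"cv_percent": 0.0}, {"n_per_group": 1},
        {"alpha": 0.7}, {"tails": "three"},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(drop_percent=20.0, cv_percent=15.0, n_per_group=6,
                    alpha=0.05, tails="one")
        base.update(kwargs)
        with pytest.raises(ValueError):
            ss.detection_power(**base)


class TestNormalisation:
    def test_anchor_mapping(self):
        assert ss.anchor_normalize(500.0, 500.0, 5000.0) == 0.0
        assert ss.anchor_normalize(5000.0, 500.0, 5000.0) == 100.0
        assert ss.anchor_normalize(2750.0, 500.0, 5000.0) == 50.0

    def test_not_clipped(self):
        assert ss.anchor_normalize(6000.0, 500.0, 5000.0) > 100.0

    def test_idempotent_on_normalised_anchors(self):
        v = ss.anchor_normalize(np.array([0.0, 37.0, 100.0]), 0.0, 100.0)
        assert np.allclose(v, [0.0, 37.0, 100.0])

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError):
            ss.anchor_normalize(1.0, 10.0, 10.0)

    def test_schemes_on_simulated_plate(self, mono_readings):
        cyto = ss.normalize_readings(mono_readings, "cytotoxicity")
        assert set(cyto.columns) >= {"concentration_uM", "viability_pct"}
        assert len(cyto) == 54
        val = ss.normalize_readings(mono_readings, "validation")
        assert val["viability_pct"].max() <= 100.0 + 1e-9

    def test_missing_anchor_rejected(self, mono_readings):
        samples_only = [r for r in mono_readings if r.role.value == "sample"]
        with pytest.raises(ValueError, match="wells present"):
            ss.normalize_readings(samples_only, "cytotoxicity")


class TestUniformityReport:
    def test_outlier_removed_and_reported(self):
        rng = np.random.default_rng(9)
        d = list(rng.normal(422, 20, size=65)) + [800.0]
        rep = ss.uniformity_report(d)
        assert rep.outlier_ids == [65]
        assert rep.n_wells == 66
        assert rep.mean_diameter == pytest.approx(422, rel=0.02)
        assert 0 <= rep.k2_p <= 1
        assert 0 <= rep.power_1_minus_beta <= 1


def test_qc_table_on_simulated_plate(mono_readings):
    table = ss.qc_table(mono_readings)
    assert {"z_factor", "signal_window", "cv_percent", "passes"} <= set(table.columns)
    neg = table[table["condition"] == "negative_control"].iloc[0]
    # vehicle controls vs kill controls: a clean simulated plate passes
    assert neg["z_factor"] > 0.4 and neg["passes"]
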