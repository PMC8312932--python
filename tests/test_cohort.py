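"""Synthetic-cohort generator: growth-curve arithmetic, design replication,
measurement model and determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phvalid.cohort import (
    CohortConfig,
    DegenerateCurveError,
    GrowthParams,
    InvalidParameterError,
    calibrate_theta,
    pb1_height,
    pb1_velocity,
    sample_cohort,
    true_aphv,
)

P = GrowthParams(h_adult=178.0, h_theta=162.0, s0=0.12, s1=1.2, theta=14.0)


class TestGrowthCurve:
    def test_closed_form_value(self):
        # independent arithmetic oracle: term-by-term evaluation with math.exp
        d = 12.0 - 14.0
        expected = 178.0 - 2.0 * (178.0 - 162.0) / (math.exp(0.12 * d) + math.exp(1.2 * d))
        assert pb1_height(P, 12.0) == pytest.approx(expected, abs=1e-12)
        assert pb1_height(P, 12.0) == pytest.approx(141.52635474360784, abs=1e-9)

    def test_height_at_theta_is_h_theta(self):
        # denominators sum to 2 at age == theta
        assert pb1_height(P, P.theta) == pytest.approx(P.h_theta, abs=1e-12)

    def test_adult_limit(self):
        assert pb1_height(P, 60.0) == pytest.approx(P.h_adult, abs=1e-6)

    @given(st.floats(5.0, 24.9))
    def test_strictly_increasing(self, age):
        assert pb1_height(P, age + 0.1) > pb1_height(P, age)

    def test_velocity_matches_finite_difference(self):
        for age in (10.0, 12.5, 13.5, 15.0):
            fd = (pb1_height(P, age + 5e-6) - pb1_height(P, age - 5e-6)) / 1e-5
            assert pb1_velocity(P, age) == pytest.approx(fd, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            GrowthParams(178.0, 162.0, 1.2, 0.12, 14.0)  # s1 < s0
        with pytest.raises(InvalidParameterError):
            GrowthParams(150.0, 162.0, 0.12, 1.2, 14.0)  # h_theta > h_adult
        with pytest.raises(InvalidParameterError):
            GrowthParams(np.nan, 162.0, 0.12, 1.2, 14.0)


class TestTrueAphv:
    def test_against_dense_grid_oracle(self):
        grid = np.arange(8.0, 20.0, 1e-4)
        oracle = grid[np.argmax(pb1_velocity(P, grid))]
        assert true_aphv(P) == pytest.approx(oracle, abs=1e-3)

    def test_near_symmetric_rates_have_no_spurt(self):
        # with s1 -> s0 the curve degenerates to an exponential approach
        # (h_adult - delta * exp(-s (t - theta))) whose velocity is monotone:
        # the adolescent peak vanishes rather than sitting at theta
        p = GrowthParams(178.0, 162.0, 0.5, 0.5 * (1 + 1e-9), 14.0)
        with pytest.raises(DegenerateCurveError):
            true_aphv(p)

    def test_translation_equivariance(self):
        shifted = GrowthParams(P.h_adult, P.h_theta, P.s0, P.s1, P.theta + 1.0)
        assert true_aphv(shifted) - true_aphv(P) == pytest.approx(1.0, abs=1e-5)

    def test_peak_precedes_theta(self):
        assert true_aphv(P) < P.theta

    def test_calibration_hits_target(self):
        for target in (11.9, 13.6, 15.4):
            p = calibrate_theta(177.0, 163.0, 0.11, 1.25, target)
            assert true_aphv(p) == pytest.approx(target, abs=0.01)

    def test_degenerate_curve_raises(self):
        # spurt far outside the window leaves only the monotone childhood tail
        p = GrowthParams(178.0, 162.0, 0.12, 1.2, theta=40.0)
        with pytest.raises(DegenerateCurveError):
            true_aphv(p)


class TestSampleCohort:
    def test_zero_noise_heights_on_truth_curve(self):
        cfg = CohortConfig(n_subjects=3, seed=9, error_sd_height=0.0)
        for s in sample_cohort(cfg):
            for v in s.visits:
                assert abs(v.height - pb1_height(s.truth, v.age)) < 1e-9

    def test_default_retention_design(self, default_cohort):
        assert default_cohort.retention_counts() == (58, 58, 58, 55, 40)
        assert len(default_cohort.to_frame()) == 269

    def test_visit_spacing_and_monotone_ages(self, default_cohort):
        for s in default_cohort:
            ages = [v.age for v in s.visits]
            assert all(b > a for a, b in zip(ages, ages[1:]))
            gaps = np.diff(ages)
            assert np.all((gaps > 0.9) & (gaps < 1.1))

    def test_sitting_height_ratio_physiological(self, default_cohort):
        df = default_cohort.to_frame()
        ratio = df["sitting_height"] / df["height"]
        assert (df["sitting_height"] < df["height"]).all()
        assert ratio.between(0.48, 0.56, inclusive="neither").all()
        assert (df["weight"] > 0).all()

    def test_true_aphv_matches_curve_peak(self, default_cohort):
        for s in list(default_cohort)[:5]:
            assert s.true_aphv == pytest.approx(true_aphv(s.truth), abs=1e-6)

    def test_aphv_population_moments(self):
        t = sample_cohort(CohortConfig(n_subjects=200, seed=7)).truth_frame()
        se_mean = 0.85 / math.sqrt(200)
        assert t["true_aphv"].mean() == pytest.approx(13.60, abs=2 * se_mean)
        se_sd = 0.85 / math.sqrt(2 * 199)  # approximate SE of a normal SD
        assert t["true_aphv"].std(ddof=1) == pytest.approx(0.85, abs=3 * se_sd)

    def test_seed_reproducibility(self):
        a = sample_cohort(CohortConfig(n_subjects=20, seed=3)).to_frame()
        b = sample_cohort(CohortConfig(n_subjects=20, seed=3)).to_frame()
        c = sample_cohort(CohortConfig(n_subjects=20, seed=4)).to_frame()
        assert a.equals(b)
        assert not a["height"].equals(c["height"])

    def test_first_visit_height_sd_stable_across_seeds(self):
        sds = []
        for seed in (11, 22):
            df = sample_cohort(CohortConfig(n_subjects=500, seed=seed)).to_frame()
            sds.append(df.loc[df["visit"] == 1, "height"].std(ddof=1))
        assert sds[0] > 0
        assert abs(sds[0] - sds[1]) / sds[0] < 0.10

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=58, retention=(58, 58, 58, 55, 60))

    def test_csv_round_trip(self, default_cohort, tmp_path):
        p, q = tmp_path / "c.csv", tmp_path / "t.csv"
        default_cohort.write_csv(p, q)
        back = type(default_cohort).read_csv(p, q)
        assert len(back) == len(default_cohort)
        assert back.to_frame()["height"].to_numpy() == pytest.approx(
            default_cohort.to_frame()["height"].to_numpy(), abs=1e-5
        )
        assert back.subjects[0].true_aphv == pytest.approx(
            default_cohort.subjects[0].true_aphv, abs=1e-5
        )
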