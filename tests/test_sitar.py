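"""Shape-invariant growth model: identifiability on model-generated data,
velocity/APHV extraction, and fit invariances."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phvalid.sitar import FitConfig, extract_aphv, fit_sitar, individual_velocity
from phvalid._splines import NaturalCubicSpline

from conftest import make_shape_invariant_dataset


class TestSplineBasis:
    def test_interpolates_smooth_target(self):
        x = np.linspace(0, 10, 200)
        y = np.sin(x / 3.0) * 5 + x
        sp = NaturalCubicSpline.from_quantiles(x, 8).fit(x, y)
        assert np.max(np.abs(sp(x) - y)) < 0.01

    def test_derivative_matches_finite_difference(self):
        x = np.linspace(0, 10, 50)
        sp = NaturalCubicSpline.from_quantiles(x, 5).fit(x, np.cos(x / 2.0))
        pts = np.array([1.3, 4.7, 8.2])
        fd = (sp(pts + 5e-7) - sp(pts - 5e-7)) / 1e-6
        assert sp.deriv(pts) == pytest.approx(fd, abs=1e-5)

    def test_linear_extrapolation_beyond_boundaries(self):
        x = np.linspace(2, 8, 60)
        sp = NaturalCubicSpline.from_quantiles(x, 5).fit(x, x**1.5)
        # second differences vanish outside the boundary knots
        for x0 in (0.5, 9.5):
            sec = sp(x0 + 0.1) - 2 * sp(x0) + sp(x0 - 0.1)
            assert abs(sec) < 1e-9


class TestModelGeneratedRecovery:
    def test_random_effects_recovered_exactly(self, shape_invariant_recovery):
        fit, effects, _ = shape_invariant_recovery
        est = fit.subjects.loc[effects.index]
        assert np.corrcoef(est["alpha"], effects["alpha"])[0, 1] > 0.999
        assert np.corrcoef(est["beta"], effects["beta"])[0, 1] > 0.999
        assert fit.sigma < 0.01

    def test_random_effect_means_centred(self, shape_invariant_recovery):
        fit, _, _ = shape_invariant_recovery
        m = fit.subjects[["alpha", "beta", "gamma"]].mean()
        assert np.all(np.abs(m.to_numpy()) < 0.05)

    def test_aphv_identity_and_flags(self, shape_invariant_recovery):
        fit, _, _ = shape_invariant_recovery
        s = fit.subjects
        expect = s["beta"] + fit.x_star * np.exp(-s["gamma"])
        assert s["aphv"].to_numpy() == pytest.approx(expect.to_numpy(), abs=1e-12)
        assert (s["flag"] == "").all()


class TestFitProperties:
    def test_loglik_trace_monotone(self, default_fit):
        t = default_fit.loglik_trace
        assert len(t) >= 3
        assert all(b >= a - 1e-6 for a, b in zip(t, t[1:]))

    def test_random_effect_means_near_zero(self, default_fit):
        m = default_fit.subjects[["alpha", "beta", "gamma"]].mean()
        assert np.all(np.abs(m.to_numpy()) < 0.05)

    def test_x_star_interior(self, default_fit):
        lo, hi = default_fit.age_range
        assert lo < default_fit.x_star < hi

    def test_residual_sd_positive(self, default_fit):
        assert default_fit.sigma > 0

    def test_relabelling_subjects_is_invariant(self):
        data, _, _ = make_shape_invariant_dataset(n=25, seed=8)
        renamed = data.copy()
        renamed["subject_id"] = renamed["subject_id"].map(
            lambda s: f"Q{99 - int(s[1:]):02d}"  # reversed order
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_sitar(data)
            f2 = fit_sitar(renamed)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-5)
        assert f2.x_star == pytest.approx(f1.x_star, abs=1e-6)
        grid = np.linspace(12, 15, 7)
        assert f2.spline(grid) == pytest.approx(f1.spline(grid), abs=1e-6)

    def test_shifting_all_heights_shifts_only_size(self):
        # on noise-free model data the optimum is sharp, so the shift
        # equivariance of the model is visible down to solver precision
        data, _, _ = make_shape_invariant_dataset(n=22, sigma=0.0, seed=13)
        shifted = data.assign(height=data["height"] + 100.0)
        cfg = FitConfig(freeze_knots_after=40, max_iter=120, tol=1e-7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_sitar(data, cfg)
            f2 = fit_sitar(shifted, cfg)
        a1 = f1.subjects.sort_index()["aphv"].to_numpy()
        a2 = f2.subjects.sort_index()["aphv"].to_numpy()
        assert a2 == pytest.approx(a1, abs=1e-6)
        alpha_shift = (f2.subjects.sort_index()["alpha"] - f1.subjects.sort_index()["alpha"])
        grid = np.linspace(12.5, 15.5, 5)
        curve_shift = f2.spline(grid) - f1.spline(grid)
        assert curve_shift + alpha_shift.mean() == pytest.approx(100.0, abs=1e-4)

    def test_measurement_noise_perturbs_aphv_mildly(self):
        # adding technical error (0.27 cm) to exact curves moves APHV < 0.15 yr RMSE
        from phvalid.cohort import CohortConfig, sample_cohort

        cfg = CohortConfig(seed=1, error_sd_height=0.0)
        clean = sample_cohort(cfg).to_frame()
        rng = np.random.default_rng(99)
        noisy = clean.assign(height=clean["height"] + rng.normal(0, 0.27, len(clean)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_clean = fit_sitar(clean)
            f_noisy = fit_sitar(noisy)
        a = f_clean.subjects.sort_index()["aphv"]
        b = f_noisy.subjects.sort_index()["aphv"]
        rmse = float(np.sqrt(((a - b) ** 2).mean()))
        assert rmse < 0.15

    def test_input_validation(self):
        bad = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b", "b"],
            "age": [11, 12, 11, 12, 13],
            "height": [140, 146, 141, 147, 152.0],
        })
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_sitar(bad)
        data, _, _ = make_shape_invariant_dataset(n=10)
        with pytest.raises(ValueError, match="20 subjects"):
            fit_sitar(data)
        with pytest.raises(ValueError):
            FitConfig(df=3)


class TestVelocityAndAphv:
    def test_velocity_matches_finite_difference(self, default_fit):
        sid = default_fit.subjects.index[0]
        for age in (12.0, 13.5, 15.0):
            v1 = individual_velocity(default_fit, sid, age)
            num = (
                default_fit.spline(
                    (age + 5e-5 - default_fit.subjects.loc[sid, "beta"])
                    * np.exp(default_fit.subjects.loc[sid, "gamma"])
                )
                - default_fit.spline(
                    (age - 5e-5 - default_fit.subjects.loc[sid, "beta"])
                    * np.exp(default_fit.subjects.loc[sid, "gamma"])
                )
            ) / 1e-4
            assert v1 == pytest.approx(num, abs=1e-4)

    def test_velocity_is_maximal_at_aphv(self, default_fit):
        for sid in default_fit.subjects.index[:10]:
            aphv, _ = extract_aphv(default_fit, sid)
            v0 = individual_velocity(default_fit, sid, aphv)
            assert v0 >= individual_velocity(default_fit, sid, aphv - 0.5) - 1e-9
            assert v0 >= individual_velocity(default_fit, sid, aphv + 0.5) - 1e-9

    def test_identity_transform_subject_velocity_is_curve_slope(self, default_fit):
        fit = default_fit
        fit.subjects.loc["__probe__"] = {
            "alpha": 0.0, "beta": 0.0, "gamma": 0.0, "n_visits": 5,
            "aphv": fit.x_star, "flag": "",
        }
        try:
            for age in (13.0, 14.0):
                assert individual_velocity(fit, "__probe__", age) == pytest.approx(
                    fit.spline.deriv(age), abs=1e-12
                )
            aphv, _ = extract_aphv(fit, "__probe__")
            assert aphv == pytest.approx(fit.x_star, abs=1e-12)
        finally:
            fit.subjects.drop(index="__probe__", inplace=True)

    def test_aphv_increases_with_tempo(self, default_fit):
        s = default_fit.subjects
        aphv_plus = (s["beta"] + 0.5) + default_fit.x_star * np.exp(-s["gamma"])
        assert np.all(aphv_plus > s["aphv"])

    def test_unknown_subject_raises(self, default_fit):
        with pytest.raises(KeyError):
            individual_velocity(default_fit, "nope", 13.0)
        with pytest.raises(KeyError):
            extract_aphv(default_fit, "nope")

    def test_zero_noise_default_cohort_has_no_flags(self):
        from phvalid.cohort import CohortConfig, sample_cohort

        clean = sample_cohort(CohortConfig(seed=2, error_sd_height=0.0)).to_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_sitar(clean)
        assert (fit.subjects["flag"] == "").all()
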