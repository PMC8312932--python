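"""Shared fixtures: one default synthetic cohort and its growth-model fit,
reused session-wide because the SITAR fit dominates test runtime."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phvalid.classify import label_records
from phvalid.cohort import CohortConfig, Cohort, sample_cohort
from phvalid.equations import build_prediction_records
from phvalid.sitar import FitConfig, SitarFit, fit_sitar, simulate_heights
from phvalid._splines import NaturalCubicSpline

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return sample_cohort(CohortConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_fit(default_cohort) -> SitarFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_sitar(default_cohort.to_frame())


@pytest.fixture(scope="session")
def default_records(default_cohort, default_fit) -> pd.DataFrame:
    """Timing-labelled prediction records for the default cohort."""
    usable = default_fit.subjects[default_fit.subjects["flag"] == ""]
    pred = build_prediction_records(default_cohort.to_frame(), usable["aphv"].rename("aphv"))
    records, _ = label_records(pred.records)
    return records


def make_shape_invariant_dataset(n: int = 30, sigma: float = 0.0, seed: int = 5):
    """Model-generated heights: one spline curve shifted by known (alpha, beta).

    The truth curve is built on the same quantile-knot rule the fitter uses
    (knots at even quantiles of the pooled tempo-aligned ages), so at the true
    effects the model can represent the data exactly — an identifiability
    check, not an approximation benchmark.
    """
    rng = np.random.default_rng(seed)
    alphas = rng.normal(0, 5, n)
    alphas -= alphas.mean()
    betas = rng.normal(0, 0.7, n)
    betas -= betas.mean()
    ids = [f"Z{i:02d}" for i in range(n)]
    ages = {sid: 11.5 + np.arange(5) * 1.0 + rng.uniform(-0.05, 0.05, 5) for sid in ids}
    pooled = np.concatenate([ages[sid] - b for sid, b in zip(ids, betas)])
    curve = NaturalCubicSpline.from_quantiles(pooled, 5)
    grid = np.linspace(pooled.min() - 0.2, pooled.max() + 0.2, 60)
    sigmoid = 175 - 2 * (175 - 160) / (np.exp(0.11 * (grid - 14)) + np.exp(1.2 * (grid - 14)))
    curve.fit(grid, sigmoid)
    effects = pd.DataFrame(
        {"alpha": alphas, "beta": betas, "gamma": np.zeros(n)}, index=ids
    )
    data = simulate_heights(curve, effects, ages, sigma=sigma, seed=seed)
    return data, effects, curve


@pytest.fixture(scope="session")
def shape_invariant_recovery():
    """Fit of the zero-noise model-generated dataset (shared: ~2 s)."""
    data, effects, curve = make_shape_invariant_dataset()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_sitar(data, FitConfig(freeze_knots_after=40, max_iter=120, tol=1e-7))
    return fit, effects, curve
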