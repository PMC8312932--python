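"""Nested linear mixed-effects models for prediction-error trajectories.

The response is the per-record difference (predicted minus observed APHV,
yr).  A ladder of nested models, all fit by maximum likelihood (so that
likelihood-ratio tests on fixed effects are valid), mirrors the standard
longitudinal workflow:

1. unconditional means: intercept only, random intercept;
2. unconditional growth: + linear time (visit - 1), random intercept and slope;
3. + maturity-timing group (fixed factor);
4. + group x time interaction.

Time is centred at visit 1 so the intercept is the visit-1 mean
difference.  Estimation is delegated to statsmodels' MixedLM (ML,
``reml=False``); model comparison, degrees-of-freedom accounting and the
ladder logic live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["LmmSpec", "LmmResult", "fit_lmm", "lrt", "run_model_ladder", "LADDER"]


@dataclass(frozen=True)
class LmmSpec:
    """One rung of the nested sequence.

    ``fixed``: one of "1", "1+time", "1+time+group", "1+time+group+group:time".
    ``random``: "intercept" or "intercept+slope".
    """

    fixed: str = "1"
    random: str = "intercept"

    _FIXED = ("1", "1+time", "1+time+group", "1+time+group+group:time")

    def __post_init__(self) -> None:
        if self.fixed not in self._FIXED:
            raise ValueError(f"unknown fixed part {self.fixed!r}")
        if self.random not in ("intercept", "intercept+slope"):
            raise ValueError(f"unknown random part {self.random!r}")

    def formula(self, response: str = "diff") -> str:
        terms = {
            "1": "1",
            "1+time": "1 + time",
            "1+time+group": "1 + time + C(timing)",
            "1+time+group+group:time": "1 + time + C(timing) + C(timing):time",
        }[self.fixed]
        return f"{response} ~ {terms}"

    def is_nested_in(self, other: "LmmSpec") -> bool:
        """True when this spec's terms are a (possibly equal) subset of other's."""
        fi, fo = self._FIXED.index(self.fixed), self._FIXED.index(other.fixed)
        ri = ("intercept", "intercept+slope").index(self.random)
        ro = ("intercept", "intercept+slope").index(other.random)
        return fi <= fo and ri <= ro


@dataclass
class LmmResult:
    spec: LmmSpec
    fixed_effects: pd.DataFrame     # estimate, se, ci_low, ci_high, wald_z, p per term
    re_cov: np.ndarray              # random-effect covariance (1x1 or 2x2)
    resid_var: float
    loglik: float
    n_params: int                   # fixed + free variance components
    n_obs: int
    n_subjects: int
    converged: bool
    lrt_vs_previous: tuple | None = None   # (statistic, df, p)
    label: str = ""


def _n_vc(random: str) -> int:
    # free (co)variance parameters including the residual variance
    return 2 if random == "intercept" else 4


def fit_lmm(records: pd.DataFrame, spec: LmmSpec, response: str = "diff") -> LmmResult:
    """ML fit of one mixed model to per-record differences.

    ``records`` needs columns subject_id, visit, ``response`` and (for the
    group rungs) timing.  Requires >= 2 visits for >= 80% of subjects.
    """
    df = records.copy()
    df["time"] = df["visit"].astype(float) - 1.0
    if not np.all(np.isfinite(df[response].to_numpy(float))):
        raise ValueError("response contains non-finite values")
    per = df.groupby("subject_id")["visit"].nunique()
    if (per >= 2).mean() < 0.8:
        raise ValueError("need >= 2 visits for >= 80% of subjects")
    if "group" in spec.fixed and "timing" not in df.columns:
        raise ValueError("group models need a 'timing' column")

    re_formula = "~1" if spec.random == "intercept" else "~1 + time"
    model = MixedLM.from_formula(
        spec.formula(response), groups="subject_id", re_formula=re_formula, data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
            converged = bool(res.converged)
        except np.linalg.LinAlgError:
            # non-positive-definite covariance: refit with independent effects
            free = MixedLM.from_formula(
                spec.formula(response), groups="subject_id", re_formula=re_formula, data=df
            )
            res = free.fit(reml=False, method="powell", maxiter=500)
            converged = False
            warnings.warn("random-effect covariance refit with diagonal structure", RuntimeWarning)

    fe = pd.DataFrame({
        "estimate": res.fe_params,
        "se": res.bse_fe,
    })
    fe["ci_low"] = fe["estimate"] - 1.959963984540054 * fe["se"]
    fe["ci_high"] = fe["estimate"] + 1.959963984540054 * fe["se"]
    fe["wald_z"] = fe["estimate"] / fe["se"]
    fe["p"] = 2.0 * stats.norm.sf(np.abs(fe["wald_z"]))

    re_cov = np.atleast_2d(np.asarray(res.cov_re, float))
    return LmmResult(
        spec=spec,
        fixed_effects=fe,
        re_cov=re_cov,
        resid_var=float(res.scale),
        loglik=float(res.llf),
        n_params=len(res.fe_params) + _n_vc(spec.random),
        n_obs=int(res.nobs),
        n_subjects=int(per.size),
        converged=converged,
    )


def lrt(nested: LmmResult, extended: LmmResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of two ML fits on the same records.

    Returns (statistic, df, p); the statistic is clipped at 0.
    """
    if not nested.spec.is_nested_in(extended.spec):
        raise ValueError(f"{nested.spec} is not nested in {extended.spec}")
    if nested.n_obs != extended.n_obs:
        raise ValueError("models were fit to different record sets")
    stat = max(0.0, 2.0 * (extended.loglik - nested.loglik))
    df = extended.n_params - nested.n_params
    if df < 0:
        raise ValueError("extended model has fewer parameters than the nested one")
    if df == 0:
        return stat, 0, 1.0  # identical specifications
    return stat, df, float(stats.chi2.sf(stat, df))


LADDER = (
    ("unconditional_means", LmmSpec("1", "intercept")),
    ("unconditional_growth", LmmSpec("1+time", "intercept+slope")),
    ("maturity_group", LmmSpec("1+time+group", "intercept+slope")),
    ("group_by_time", LmmSpec("1+time+group+group:time", "intercept+slope")),
)


def run_model_ladder(records: pd.DataFrame, equation: str) -> list[LmmResult]:
    """Fit the nested model sequence to one equation's APHV differences.

    ``records`` must carry timing labels (see classify.label_records).
    Non-convergence of a rung flags that rung; the ladder continues.
    """
    if equation not in ("mirwald", "moore"):
        raise ValueError("equation must be 'mirwald' or 'moore'")
    response = f"{equation}_diff"
    out: list[LmmResult] = []
    prev: LmmResult | None = None
    for label, spec in LADDER:
        res = fit_lmm(records, spec, response=response)
        res.label = label
        if prev is not None:
            res.lrt_vs_previous = lrt(prev, res)
        out.append(res)
        prev = res
    return out


def ladder_table(ladder: list[LmmResult]) -> pd.DataFrame:
    """One row per model: log-likelihood, parameter count, LRT vs previous."""
    rows = []
    for r in ladder:
        stat, df, p = r.lrt_vs_previous if r.lrt_vs_previous else (np.nan, np.nan, np.nan)
        rows.append({
            "model": r.label,
            "fixed": r.spec.fixed,
            "random": r.spec.random,
            "n_params": r.n_params,
            "loglik": r.loglik,
            "lrt_stat": stat,
            "lrt_df": df,
            "lrt_p": p,
            "converged": r.converged,
        })
    return pd.DataFrame(rows)
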