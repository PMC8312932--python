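"""Somatic maturity-offset prediction equations and the offset/APHV algebra.

Two published boys' equations predict maturity offset — the signed time in
years from the measurement occasion to peak height velocity (negative
before the spurt peak):

Mirwald (original; CA, sitting height, estimated leg length, height, weight):

    offset = -9.236 + 0.0002708 (LL . SH) - 0.001663 (CA . LL)
             + 0.007216 (CA . SH) + 0.02292 ((weight/height) . 100)

with leg length LL = standing height - sitting height, heights in cm,
weight in kg, CA in decimal years.  NOTE the weight-by-height ratio is in
kg/cm and must be multiplied by 100 — omitting that factor is a known
misuse of the equation.

Moore (modified; CA and height only):

    offset = -7.999994 + 0.0036124 (CA . height)

Predicted age at PHV is CA minus predicted offset; observed offset is CA
minus the observed (growth-model) APHV.  Inputs are used at stored
precision; chronological age outside [8, 18] yr is a domain error rather
than a silent extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
import pandas as pd

__all__ = [
    "MIRWALD_COEF",
    "MOORE_COEF",
    "PUBLISHED_SEE",
    "mirwald_offset",
    "moore_offset",
    "build_prediction_records",
]

#: Mirwald boys' equation coefficients (intercept, LL*SH, CA*LL, CA*SH, 100*wt/ht)
MIRWALD_COEF = MappingProxyType({
    "intercept": -9.236,
    "ll_sh": 0.0002708,
    "ca_ll": -0.001663,
    "ca_sh": 0.007216,
    "wt_ht": 0.02292,
})

#: Moore boys' age-by-height equation coefficients
MOORE_COEF = MappingProxyType({"intercept": -7.999994, "ca_ht": 0.0036124})

#: published standard errors of estimate (yr), metadata only
PUBLISHED_SEE = MappingProxyType({"mirwald": 0.592, "moore": 0.542})

_CA_RANGE = (8.0, 18.0)


def _check_finite(**kwargs) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {name}: {v}")


def mirwald_offset(ca, height, sitting_height, weight):
    """Mirwald predicted maturity offset (yr) for boys.

    Heights in cm, weight in kg, ``ca`` in decimal years within [8, 18].
    Accepts scalars or aligned arrays.
    """
    ca = np.asarray(ca, float)
    height = np.asarray(height, float)
    sitting_height = np.asarray(sitting_height, float)
    weight = np.asarray(weight, float)
    _check_finite(ca=ca, height=height, sitting_height=sitting_height, weight=weight)
    if np.any(sitting_height >= height) or np.any(sitting_height <= 0):
        raise ValueError("require 0 < sitting_height < height")
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    if np.any((ca < _CA_RANGE[0]) | (ca > _CA_RANGE[1])):
        raise ValueError(f"chronological age outside {_CA_RANGE}")
    ll = height - sitting_height
    c = MIRWALD_COEF
    out = (
        c["intercept"]
        + c["ll_sh"] * (ll * sitting_height)
        + c["ca_ll"] * (ca * ll)
        + c["ca_sh"] * (ca * sitting_height)
        + c["wt_ht"] * ((weight / height) * 100.0)
    )
    return float(out) if out.ndim == 0 else out


def moore_offset(ca, height):
    """Moore (age-by-height) predicted maturity offset (yr) for boys."""
    ca = np.asarray(ca, float)
    height = np.asarray(height, float)
    _check_finite(ca=ca, height=height)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    if np.any((ca < _CA_RANGE[0]) | (ca > _CA_RANGE[1])):
        raise ValueError(f"chronological age outside {_CA_RANGE}")
    out = MOORE_COEF["intercept"] + MOORE_COEF["ca_ht"] * (ca * height)
    return float(out) if out.ndim == 0 else out


RECORD_COLUMNS = [
    "subject_id", "visit", "ca", "observed_aphv", "observed_offset",
    "mirwald_offset", "moore_offset", "mirwald_aphv", "moore_aphv",
    "mirwald_diff", "moore_diff",
]


@dataclass
class PredictionSet:
    """Per-visit prediction records plus subjects excluded for missing APHV."""

    records: pd.DataFrame
    excluded: list[str]


def build_prediction_records(cohort_df: pd.DataFrame, aphv: pd.DataFrame | pd.Series) -> PredictionSet:
    """One record per subject x visit with the full offset/APHV algebra.

    Parameters
    ----------
    cohort_df : DataFrame
        Long format with columns subject_id, visit, age, height,
        sitting_height, weight.
    aphv : Series or DataFrame
        Observed APHV per subject (Series indexed by subject_id, or a
        DataFrame with subject_id and aphv columns).  Subjects without an
        APHV are listed in the exclusion report, never silently dropped.

    The identities  ca - offset = aphv  and  diff = predicted - observed
    APHV hold exactly by construction.
    """
    if isinstance(aphv, pd.DataFrame):
        aphv = aphv.set_index("subject_id")["aphv"]
    have = set(aphv.index)
    excluded = sorted(set(cohort_df["subject_id"]) - have)
    df = cohort_df[cohort_df["subject_id"].isin(have)].copy()

    obs_aphv = df["subject_id"].map(aphv).to_numpy(float)
    ca = df["age"].to_numpy(float)
    mir = mirwald_offset(ca, df["height"].to_numpy(float),
                         df["sitting_height"].to_numpy(float),
                         df["weight"].to_numpy(float))
    moo = moore_offset(ca, df["height"].to_numpy(float))
    rec = pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy(),
        "visit": df["visit"].to_numpy(int),
        "ca": ca,
        "observed_aphv": obs_aphv,
        "observed_offset": ca - obs_aphv,
        "mirwald_offset": mir,
        "moore_offset": moo,
        "mirwald_aphv": ca - mir,
        "moore_aphv": ca - moo,
    })
    rec["mirwald_diff"] = rec["mirwald_aphv"] - rec["observed_aphv"]
    rec["moore_diff"] = rec["moore_aphv"] - rec["observed_aphv"]
    rec = rec[RECORD_COLUMNS].sort_values(["subject_id", "visit"]).reset_index(drop=True)
    return PredictionSet(records=rec, excluded=excluded)
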