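"""Maturity-timing classification and predicted/observed agreement tables.

Timing (early / average / late) is defined from the observed APHV
distribution of the analysed sample itself: "average" is an APHV within
one SD of the sample mean, "early" strictly below the lower cutoff and
"late" strictly above the upper — with the printed reference values
(mean 13.60, SD 0.85 yr) the cutoffs are 12.75 and 14.45 yr.  Status at a
single observation (pre / circa / post PHV) uses a symmetric offset band,
conventionally +/-0.5 yr, inclusive at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimingRule",
    "classify_timing",
    "classify_status",
    "agreement_within",
    "build_agreement_table",
    "percent_int",
]

GROUPS = ("early", "average", "late")


@dataclass(frozen=True)
class TimingRule:
    """Early/average/late cutoffs at reference mean +/- one SD (yr)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and np.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"invalid timing rule ({self.mean}, {self.sd})")

    @property
    def lower(self) -> float:
        return self.mean - self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.sd

    @classmethod
    def from_sample(cls, aphv) -> "TimingRule":
        """Cutoffs recomputed from the analysed sample (ddof=1 SD)."""
        a = np.asarray(aphv, float)
        return cls(float(a.mean()), float(a.std(ddof=1)))


def classify_timing(aphv: float, rule: TimingRule) -> str:
    """'early' below the lower cutoff, 'late' above the upper, else 'average'.

    Boundary values are 'average', matching strict-inequality outer groups.
    """
    if not np.isfinite(aphv):
        raise ValueError("aphv must be finite")
    if aphv < rule.lower:
        return "early"
    if aphv > rule.upper:
        return "late"
    return "average"


def classify_status(offset: float, half_width: float = 0.5) -> str:
    """'pre' / 'circa' / 'post' PHV from a maturity offset and a band (yr)."""
    if not (np.isfinite(half_width) and half_width > 0):
        raise ValueError("half_width must be positive")
    if abs(offset) <= half_width:
        return "circa"
    return "pre" if offset < 0 else "post"


def agreement_within(predicted_aphv, observed_aphv, half_width: float = 0.5):
    """|predicted - observed| <= half_width (inclusive at the boundary)."""
    d = np.abs(np.asarray(predicted_aphv, float) - np.asarray(observed_aphv, float))
    out = d <= half_width
    return bool(out) if out.ndim == 0 else out


def percent_int(n: int, total: int):
    """Integer percentage with round-half-up display rounding; None if total=0."""
    if total == 0:
        return None
    return int(math.floor(100.0 * n / total + 0.5))


def label_records(records: pd.DataFrame, rule: TimingRule | None = None) -> tuple[pd.DataFrame, TimingRule]:
    """Append a per-subject timing label column to prediction records."""
    per_subject = records.drop_duplicates("subject_id").set_index("subject_id")["observed_aphv"]
    if rule is None:
        rule = TimingRule.from_sample(per_subject.to_numpy())
    labels = per_subject.map(lambda a: classify_timing(a, rule))
    out = records.copy()
    out["timing"] = out["subject_id"].map(labels)
    return out, rule


def build_agreement_table(records: pd.DataFrame, rule: TimingRule | None = None,
                          half_width: float = 0.5) -> pd.DataFrame:
    """Counts of predictions within +/-half_width yr of observed APHV.

    One row per equation x visit (plus per-equation totals), with columns
    N/n per timing group and overall, and integer percentages on the total
    rows.  Empty cells (N=0) leave the percentage blank, not zero.
    """
    rec, rule = label_records(records, rule)
    rows = []
    for eq in ("mirwald", "moore"):
        ok = agreement_within(rec[f"{eq}_aphv"], rec["observed_aphv"], half_width)
        rec_ok = rec.assign(_ok=ok)
        tot = {g: [0, 0] for g in GROUPS + ("all",)}
        for visit, g in rec_ok.groupby("visit"):
            row = {"equation": eq, "visit": int(visit)}
            for grp in GROUPS:
                sub = g[g["timing"] == grp]
                row[f"N_{grp}"] = len(sub)
                row[f"n_{grp}"] = int(sub["_ok"].sum())
                tot[grp][0] += len(sub)
                tot[grp][1] += int(sub["_ok"].sum())
            row["N_total"] = len(g)
            row["n_total"] = int(g["_ok"].sum())
            tot["all"][0] += len(g)
            tot["all"][1] += int(g["_ok"].sum())
            rows.append(row)
        trow = {"equation": eq, "visit": "total"}
        for grp in GROUPS:
            trow[f"N_{grp}"], trow[f"n_{grp}"] = tot[grp]
            trow[f"pct_{grp}"] = percent_int(tot[grp][1], tot[grp][0])
        trow["N_total"], trow["n_total"] = tot["all"]
        trow["pct_total"] = percent_int(tot["all"][1], tot["all"][0])
        rows.append(trow)
    table = pd.DataFrame(rows)
    table.attrs["rule"] = rule
    table.attrs["half_width"] = half_width
    return table
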