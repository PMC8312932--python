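"""End-to-end validation pipeline and paper-style report tables.

Orchestrates: synthetic cohort (or an external long-format CSV) -> SITAR
fit and observed APHV -> Mirwald/Moore predictions -> maturity-timing
classification -> per-visit descriptives, weighted Deming comparison,
agreement tables, predictor correlations and the mixed-model ladder.
Every emitted table is a pure function of the prediction-record table, so
each number can be recomputed independently from records.csv.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cohort import Cohort, CohortConfig, sample_cohort
from .sitar import FitConfig, SitarFit, fit_sitar
from .equations import build_prediction_records
from .classify import TimingRule, build_agreement_table, label_records, GROUPS
from .deming import jackknife_se
from .lmm import ladder_table, run_model_ladder

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "correlation_table"]


@dataclass
class RunConfig:
    """A fully serialisable pipeline run: config + seed reproduce everything."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_csv: str | None = None       # external cohort instead of synthetic
    fit: FitConfig = field(default_factory=FitConfig)
    band_half_widths: tuple[float, ...] = (0.5, 1.0)
    deming_lambda: float = 1.0
    deming_weighted: bool = True
    run_lmm: bool = True
    out_dir: str | None = None
    force: bool = False                 # proceed on SITAR non-convergence

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        if "cohort" in kw and isinstance(kw["cohort"], dict):
            kw["cohort"] = CohortConfig(**kw["cohort"])
        if "fit" in kw and isinstance(kw["fit"], dict):
            kw["fit"] = FitConfig(**kw["fit"])
        if "band_half_widths" in kw:
            kw["band_half_widths"] = tuple(kw["band_half_widths"])
        return cls(**kw)


@dataclass
class ReportBundle:
    records: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    s1: pd.DataFrame | None
    rule: TimingRule
    fit: SitarFit
    cohort: Cohort | None
    excluded: list[str]
    manifest: dict


def _mean_sd(x) -> str:
    x = np.asarray(x, float)
    return f"{x.mean():.2f}±{x.std(ddof=1):.2f}" if len(x) > 1 else f"{x.mean():.2f}"


_T1_COLS = [
    ("ca", "ca"),
    ("observed_offset", "observed_offset"),
    ("mirwald_offset", "mirwald_offset"),
    ("moore_offset", "moore_offset"),
    ("mirwald_aphv", "mirwald_aphv"),
    ("moore_aphv", "moore_aphv"),
    ("mirwald_diff", "mirwald_diff"),
    ("moore_diff", "moore_diff"),
]


def descriptives_table(records: pd.DataFrame, by_group: bool = False) -> pd.DataFrame:
    """Per-visit (optionally per timing group) mean +/- SD of the key columns."""
    keys = (["timing"] if by_group else []) + ["visit"]
    rows = []
    for key, g in records.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row["n"] = len(g)
        for name, col in _T1_COLS:
            row[f"{name}_mean"] = g[col].mean()
            row[f"{name}_sd"] = g[col].std(ddof=1)
        rows.append(row)
    df = pd.DataFrame(rows)
    if by_group:
        df["timing"] = pd.Categorical(df["timing"], categories=list(GROUPS), ordered=True)
        df = df.sort_values(["timing", "visit"]).reset_index(drop=True)
    return df


def deming_table(records: pd.DataFrame, lam: float = 1.0, weighted: bool = True) -> pd.DataFrame:
    """Weighted Deming fit of predicted (y) on observed (x) APHV per equation x visit."""
    rows = []
    for eq in ("mirwald", "moore"):
        for visit, g in records.groupby("visit"):
            r = jackknife_se(
                g["observed_aphv"].to_numpy(), g[f"{eq}_aphv"].to_numpy(),
                lam=lam, weighted=weighted,
            )
            rows.append({
                "equation": eq, "visit": int(visit), "n": r.n,
                "intercept": r.intercept, "se_intercept": r.se_intercept,
                "cl95_intercept_low": r.cl95_intercept[0],
                "cl95_intercept_high": r.cl95_intercept[1],
                "slope": r.slope, "se_slope": r.se_slope,
                "cl95_slope_low": r.cl95_slope[0], "cl95_slope_high": r.cl95_slope[1],
                "lambda": r.lam, "systematic": r.systematic, "proportional": r.proportional,
            })
    return pd.DataFrame(rows)


_MIRWALD_VARS = ["ca", "height", "sitting_height", "leg_length", "weight"]
_MOORE_VARS = ["ca", "height"]


def correlation_table(records: pd.DataFrame, anthropometry: pd.DataFrame) -> pd.DataFrame:
    """Per-visit Pearson correlations of predicted offset/APHV with predictors.

    Mirwald quantities are correlated with CA, height, sitting height,
    estimated leg length and weight; Moore quantities with CA and height.
    Two-sided p < 0.05 is flagged; cells with fewer than 4 pairs are NaN.
    """
    anth = anthropometry.copy()
    anth["leg_length"] = anth["height"] - anth["sitting_height"]
    merged = records.merge(
        anth[["subject_id", "visit", "height", "sitting_height", "weight", "leg_length"]],
        on=["subject_id", "visit"],
    )
    merged["ca"] = merged["ca"].astype(float)
    rows = []
    for visit, g in merged.groupby("visit"):
        for eq, variables in (("mirwald", _MIRWALD_VARS), ("moore", _MOORE_VARS)):
            for target in ("offset", "aphv"):
                col = f"{eq}_{target}"
                for var in variables:
                    if len(g) < 4:
                        r_val, p = np.nan, np.nan
                    else:
                        r_val, p = stats.pearsonr(g[col], g[var])
                    rows.append({
                        "visit": int(visit), "equation": eq, "quantity": target,
                        "variable": var, "n": len(g), "r": r_val, "p": p,
                        "significant": bool(p < 0.05) if np.isfinite(p) else False,
                    })
    return pd.DataFrame(rows)


def _identity_scatter(records: pd.DataFrame, eq: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"early": "tab:red", "average": "tab:gray", "late": "tab:blue"}
    for grp, g in records.groupby("timing", observed=False):
        ax.scatter(g["observed_aphv"], g[f"{eq}_aphv"], s=12, alpha=0.6,
                   label=str(grp), color=colors.get(str(grp), "k"))
    lims = (records["observed_aphv"].min() - 0.3, records["observed_aphv"].max() + 0.3)
    ax.plot(lims, lims, "k--", lw=1, label="identity")
    ax.set_xlabel("observed APHV (yr)")
    ax.set_ylabel(f"{eq} predicted APHV (yr)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig | None = None) -> ReportBundle:
    """Run the full validation chain and (optionally) write the report bundle.

    Subjects whose SITAR APHV is flagged (outside the plausibility window
    or the empirical age range) are excluded from the analysis and listed
    in the exclusion report, mirroring the reference design in which one
    of 59 modelled players was dropped.
    """
    cfg = config or RunConfig()
    if cfg.cohort_csv:
        cohort = Cohort.read_csv(cfg.cohort_csv)
    else:
        cohort = sample_cohort(cfg.cohort)
    cohort_df = cohort.to_frame()

    fit = fit_sitar(cohort_df, cfg.fit)
    if not fit.converged and not cfg.force:
        raise RuntimeError(
            "growth-model fit did not converge "
            f"(log-likelihood trace tail: {fit.loglik_trace[-3:]}); "
            "pass force=True to proceed"
        )
    usable = fit.subjects[fit.subjects["flag"] == ""]
    flagged = sorted(set(fit.subjects.index) - set(usable.index))
    if flagged:
        log.warning("excluding %d flagged subjects: %s", len(flagged), flagged)

    aphv = usable["aphv"].rename("aphv")
    pred = build_prediction_records(cohort_df, aphv)
    excluded = sorted(set(flagged) | set(pred.excluded))
    records, rule = label_records(pred.records)

    table1 = descriptives_table(records, by_group=False)
    table3 = descriptives_table(records, by_group=True)
    table2 = deming_table(records, lam=cfg.deming_lambda, weighted=cfg.deming_weighted)
    table4 = build_agreement_table(records, rule, half_width=cfg.band_half_widths[0])
    table5 = correlation_table(records, cohort_df)
    s1 = None
    if cfg.run_lmm:
        parts = []
        for eq in ("mirwald", "moore"):
            t = ladder_table(run_model_ladder(records, eq))
            t.insert(0, "equation", eq)
            parts.append(t)
        s1 = pd.concat(parts, ignore_index=True)

    manifest = {
        "phvalid_version": __version__,
        "seed": cfg.cohort.seed,
        "n_subjects_generated": len(cohort),
        "n_subjects_analyzed": int(records["subject_id"].nunique()),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "n_records": int(len(records)),
        "timing_rule": {"mean": rule.mean, "sd": rule.sd,
                        "lower": rule.lower, "upper": rule.upper},
        "band_half_widths": list(cfg.band_half_widths),
        "deming": {"lambda": cfg.deming_lambda, "weighted": cfg.deming_weighted},
        "sitar": {"df": cfg.fit.df, "tol": cfg.fit.tol, "converged": fit.converged,
                  "x_star": fit.x_star, "sigma": fit.sigma, "loglik": fit.loglik,
                  "gamma_fixed": fit.gamma_fixed},
    }

    bundle = ReportBundle(records, table1, table2, table3, table4, table5, s1,
                          rule, fit, cohort, excluded, manifest)
    if cfg.out_dir:
        _write_bundle(bundle, Path(cfg.out_dir))
    return bundle


def _round_display(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: 1 decimal for CA, 2 for offsets/APHVs/diffs."""
    out = df.copy()
    for c in out.columns:
        if c.startswith("ca_"):
            out[c] = out[c].round(1)
        elif out[c].dtype.kind == "f":
            out[c] = out[c].round(2)
    return out


def _write_bundle(b: ReportBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    b.records.to_csv(out / "records.csv", index=False, float_format="%.6f")
    for name, df in [("table1", b.table1), ("table3", b.table3)]:
        df.to_csv(out / f"{name}_raw.csv", index=False, float_format="%.6f")
        _round_display(df).to_csv(out / f"{name}.csv", index=False)
    b.table2.to_csv(out / "table2.csv", index=False, float_format="%.4f")
    b.table4.to_csv(out / "table4.csv", index=False)
    b.table5.to_csv(out / "table5.csv", index=False, float_format="%.4f")
    if b.s1 is not None:
        b.s1.to_csv(out / "s1.csv", index=False, float_format="%.4f")
    b.fit.subjects.reset_index().to_csv(out / "sitar_subjects.csv", index=False,
                                        float_format="%.6f")
    if b.cohort is not None:
        b.cohort.write_csv(out / "cohort.csv", out / "truth.csv")
    for eq in ("mirwald", "moore"):
        _identity_scatter(b.records, eq, out / f"identity_{eq}.png")
    (out / "manifest.json").write_text(json.dumps(b.manifest, indent=2, sort_keys=True))
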