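"""Per-patient time-to-initiation outcome and regional comparison.

The outcome is the number of whole days from the index date (death minus 182
days) to the first in-window visit with effective end-of-life intent; 0 means
initiation a full six months before death, 182 means initiation on the death
date. A shorter mean indicates earlier access.

Regions are compared with a chi-square test of homogeneity on the region x
{initiated at or before the pooled median, after it} contingency table —
the dichotomize-at-median construction makes a mean-type outcome testable
with a chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import age_at_death, reclassify_intents
from .synthetic import OUTCOME_MAX_DAY

#: age-at-death bands for (age x sex) strata; chosen to keep cells populated
#: at realistic region sizes
AGE_BANDS: list[tuple[int, int]] = [(19, 59), (60, 69), (70, 79), (80, 200)]


def age_band_labels(ages: pd.Series) -> pd.Series:
    bins = [b[0] for b in AGE_BANDS] + [AGE_BANDS[-1][1] + 1]
    labels = [f"{lo}-{hi}" if hi < 200 else f"{lo}+" for lo, hi in AGE_BANDS]
    return pd.cut(ages, bins=bins, labels=labels, right=False, include_lowest=True)


def compute_outcomes(
    membership: pd.DataFrame,
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    window_days: int = OUTCOME_MAX_DAY,
) -> pd.DataFrame:
    """Days to first effective-EOL in-window visit, per EOL sub-cohort member.

    Returns a DataFrame with patient_id, region_id, days_to_first_eol.

    Raises
    ------
    RuntimeError
        If an EOL sub-cohort member has no in-window effective-EOL visit, or
        a computed value falls outside [0, window_days] — both indicate an
        inconsistent membership/visit pair.
    """
    v = reclassify_intents(visits) if "effective_intent" not in visits else visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"])
    members = membership.loc[membership["in_eol_subcohort"]]
    p = patients.copy()
    p["diagnosis_date"] = pd.to_datetime(p["diagnosis_date"])

    v = v.loc[v["effective_intent"] == "eol"].merge(
        members[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    v = v.merge(p[["patient_id", "diagnosis_date"]], on="patient_id", how="left")
    death = v["index_date"] + pd.Timedelta(days=window_days)
    in_window = (
        (v["visit_date"] >= v["index_date"])
        & (v["visit_date"] <= death)
        & (v["visit_date"] >= v["diagnosis_date"])
    )
    first = (
        v.loc[in_window]
        .groupby("patient_id")
        .agg(first_eol=("visit_date", "min"), index_date=("index_date", "first"))
    )
    missing = set(members["patient_id"]) - set(first.index)
    if missing:
        raise RuntimeError(
            f"{len(missing)} EOL sub-cohort member(s) have no in-window "
            "effective-EOL visit; membership and visits are inconsistent"
        )
    days = (first["first_eol"] - first["index_date"]).dt.days
    if (days < 0).any() or (days > window_days).any():
        raise RuntimeError("computed outcome outside [0, window] — aborting")
    out = days.rename("days_to_first_eol").reset_index()
    out = out.merge(p[["patient_id", "region_id"]], on="patient_id", how="left")
    return out[["patient_id", "region_id", "days_to_first_eol"]]


def summarize_regions(
    outcomes: pd.DataFrame,
    membership: pd.DataFrame,
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-level summary and (age band x sex) stratum means.

    Returns
    -------
    region_summary : DataFrame
        region_id, province, n_any, n_eol, mean_days, sd_days. Regions with
        no EOL members appear with null mean/sd.
    strata : DataFrame
        region_id, age_band, sex, n, mean_days — one row per populated
        stratum cell, for indirect standardization.
    """
    p = patients.copy()
    p["age"] = age_at_death(p)
    p["age_band"] = age_band_labels(p["age"])
    m = membership.merge(p[["patient_id", "region_id"]], on="patient_id")

    n_any = (
        m.loc[m["in_any_nursing_cohort"]].groupby("region_id").size().rename("n_any")
    )
    regions = (
        p[["region_id", "province"]].drop_duplicates().set_index("region_id").sort_index()
    )

    o = outcomes.merge(p[["patient_id", "age_band", "sex"]], on="patient_id")
    grp = o.groupby("region_id")["days_to_first_eol"]
    summary = pd.DataFrame(
        {
            "n_eol": grp.size(),
            "mean_days": grp.mean(),
            "sd_days": grp.std(ddof=1),
        }
    )
    region_summary = (
        regions.join(n_any).join(summary).fillna({"n_any": 0, "n_eol": 0}).reset_index()
    )
    region_summary["n_any"] = region_summary["n_any"].astype(int)
    region_summary["n_eol"] = region_summary["n_eol"].astype(int)

    strata = (
        o.groupby(["region_id", "age_band", "sex"], observed=True)["days_to_first_eol"]
        .agg(n="size", mean_days="mean")
        .reset_index()
    )
    strata = strata.loc[strata["n"] > 0].reset_index(drop=True)
    return region_summary, strata


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    cutpoint: float  # pooled median used to dichotomize
    table: pd.DataFrame

    def __repr__(self) -> str:  # keep the big table out of reprs
        return (
            f"Chi2Result(statistic={self.statistic:.4g}, df={self.df}, "
            f"pvalue={self.pvalue:.4g}, cutpoint={self.cutpoint})"
        )


def compare_regions_chi2(outcomes: pd.DataFrame) -> Chi2Result:
    """Chi-square homogeneity test of early vs late initiation across regions.

    Outcomes are dichotomized at the pooled median (<= median = early); the
    test is Pearson's chi-square without continuity correction on the
    region x {early, late} table, df = (#regions - 1).
    """
    counts = outcomes.groupby("region_id").size()
    counts = counts[counts > 0]
    if len(counts) < 2:
        raise ValueError("need >= 2 regions with EOL members for the chi-square test")
    o = outcomes.loc[outcomes["region_id"].isin(counts.index)]
    med = float(o["days_to_first_eol"].median())
    table = pd.crosstab(o["region_id"], o["days_to_first_eol"] <= med)
    if table.shape[1] < 2:
        raise ValueError(
            "outcomes are constant across the cohort; the median split is degenerate"
        )
    table.columns = ["late", "early"]
    stat, p, df, _ = chi2_contingency(table.values, correction=False)
    return Chi2Result(float(stat), int(df), float(p), med, table)


def plot_region_means(region_summary: pd.DataFrame, out_path) -> None:
    """Bar chart of unadjusted region means, sorted by province then mean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = region_summary.dropna(subset=["mean_days"]).sort_values(
        ["province", "mean_days"]
    )
    if df.empty:
        raise ValueError("no regions with computed means to plot")
    colors = {"BC": "#1b9e77", "NS": "#7570b3", "ON": "#d95f02"}
    fig, ax = plt.subplots(figsize=(10, 4.5))
    ax.bar(
        df["region_id"], df["mean_days"],
        color=[colors.get(p, "grey") for p in df["province"]],
    )
    ax.set_ylabel("Mean days to first EOL nursing visit\n(from 6 months before death)")
    ax.set_xlabel("Health region")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in colors.values()]
    ax.legend(handles, colors.keys(), frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
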