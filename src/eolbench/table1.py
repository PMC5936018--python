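"""Published region-level cohort demographics for the three-province study.

The study spans 28 health regions in British Columbia (BC), Nova Scotia (NS)
and Ontario (ON): cancer decedents (fiscal years 2004/05-2008/09) with at
least one homecare nursing record in the last 182 days of life, and the
sub-cohort whose nursing carried end-of-life (EOL) intent.

Per-region outcome means and within-region SDs were never published, so the
default first-EOL-visit timing parameters used by the synthetic generator are
package choices (see docs/methods.md): they echo the reported ordering — BC
shortest, NS second, ON longest, extremes 55 and 97 days — without claiming
the confidential per-region values.
"""

from __future__ import annotations

import datetime as dt
import math

import pandas as pd

from .synthetic import GeneratorConfig, RegionSpec

# (province, region number, any-nursing n, EOL n, median age, age Q1, age Q3,
#  female %, wealthiest income quintile %, Charlson-Deyo >= 1 %)
TABLE1_ROWS: list[tuple[str, int, int, int, int, int, int, int, int, int]] = [
    ("BC", 2, 7104, 6447, 71, 61, 79, 48, 17, 14),
    ("BC", 4, 5902, 5328, 73, 63, 81, 47, 21, 13),
    ("BC", 3, 4225, 3663, 72, 62, 80, 49, 24, 14),
    ("BC", 5, 1242, 1061, 68, 59, 76, 44, 20, 20),
    ("BC", 1, 1021, 878, 72, 64, 80, 44, 12, 16),
    ("NS", 9, 1891, 1633, 71, 61, 80, 45, 20, 14),
    ("NS", 8, 824, 701, 71, 62, 80, 48, 14, 28),
    ("NS", 3, 478, 406, 73, 64, 81, 47, 15, 16),
    ("NS", 4, 450, 375, 72, 62, 80, 48, 18, 16),
    ("NS", 2, 412, 372, 71, 62, 81, 43, 12, 19),
    ("NS", 1, 377, 315, 73, 62, 81, 47, 29, 11),
    ("NS", 6, 337, 321, 73, 63, 81, 42, 17, 22),
    ("NS", 7, 246, 193, 76, 62, 84, 45, 19, 23),
    ("NS", 5, 238, 179, 71, 62, 79, 48, 13, 21),
    ("ON", 4, 8256, 5742, 71, 60, 79, 48, 17, 18),
    ("ON", 9, 6883, 4696, 70, 60, 80, 49, 15, 18),
    ("ON", 11, 6048, 4487, 70, 62, 78, 49, 22, 16),
    ("ON", 8, 5811, 3885, 71, 60, 80, 48, 21, 18),
    ("ON", 7, 4557, 3307, 71, 59, 79, 51, 30, 18),
    ("ON", 2, 5382, 2710, 70, 60, 78, 48, 18, 16),
    ("ON", 3, 3227, 2565, 71, 60, 78, 48, 21, 16),
    ("ON", 1, 3969, 2552, 70, 64, 79, 48, 18, 19),
    ("ON", 6, 3762, 2459, 70, 59, 77, 49, 29, 16),
    ("ON", 13, 3534, 2121, 70, 62, 79, 46, 13, 22),
    ("ON", 10, 3184, 1846, 71, 60, 78, 45, 15, 16),
    ("ON", 12, 2692, 1752, 72, 60, 78, 46, 24, 19),
    ("ON", 5, 2287, 1302, 69, 61, 79, 48, 12, 17),
    ("ON", 14, 1000, 607, 70, 61, 77, 46, 17, 23),
]

STUDY_START = dt.date(2004, 4, 1)
STUDY_END = dt.date(2009, 3, 31)

# Default generating mean (days on the 0-182 scale, 0 = six months before
# death) of the first EOL-intent visit per region. Chosen once to match the
# published narrative: BC and NS regions initiate earliest, ON latest; the
# two best regions (55 days) are a large BC region (n=3663) and a small NS
# region (n=372); the worst (97 days) is a mid-size ON region.
DEFAULT_TIMING_MEANS: dict[str, float] = {
    "BC-1": 64, "BC-2": 60, "BC-3": 55, "BC-4": 63, "BC-5": 66,
    "NS-1": 73, "NS-2": 55, "NS-3": 71, "NS-4": 72, "NS-5": 77,
    "NS-6": 65, "NS-7": 75, "NS-8": 70, "NS-9": 68,
    "ON-1": 85, "ON-2": 86, "ON-3": 79, "ON-4": 80, "ON-5": 92,
    "ON-6": 83, "ON-7": 97, "ON-8": 84, "ON-9": 82, "ON-10": 90,
    "ON-11": 78, "ON-12": 87, "ON-13": 88, "ON-14": 89,
}

# Within-region SD of first-EOL-visit day (days). Not published; one value
# shared by all regions.
DEFAULT_TIMING_SD = 35.0


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (presentation rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def table1_frame() -> pd.DataFrame:
    """The published region table as a DataFrame, one row per region."""
    df = pd.DataFrame(
        TABLE1_ROWS,
        columns=[
            "province", "region_num", "n_any", "n_eol", "median_age",
            "age_q1", "age_q3", "female_pct", "income_q5_pct", "charlson_pct",
        ],
    )
    df.insert(0, "region_id", df["province"] + "-" + df["region_num"].astype(str))
    return df


def table1_totals() -> dict:
    """Cohort bookkeeping recomputed from the region table.

    Returns the any-nursing and EOL sub-cohort totals, the EOL share (%),
    per-province EOL shares (%), and the EOL-n-weighted female share (%),
    all rounded the way the source table prints them (half-up to integer).
    """
    df = table1_frame()
    n_any = int(df["n_any"].sum())
    n_eol = int(df["n_eol"].sum())
    prov = df.groupby("province")["n_eol"].sum()
    return {
        "n_any_total": n_any,
        "n_eol_total": n_eol,
        "eol_share_pct": round_half_up(100 * n_eol / n_any),
        "province_eol_share_pct": {
            p: round_half_up(100 * prov[p] / n_eol) for p in ("BC", "ON", "NS")
        },
        "weighted_female_pct": round_half_up(
            float((df["n_eol"] * df["female_pct"]).sum() / n_eol)
        ),
    }


def region_eol_percentages() -> pd.Series:
    """Per-region EOL share of the any-nursing cohort, rounded half-up."""
    df = table1_frame()
    pct = (100 * df["n_eol"] / df["n_any"]).map(round_half_up)
    pct.index = df["region_id"]
    return pct


def default_table1_config(
    seed: int = 0,
    timing_means: dict[str, float] | None = None,
    timing_sd: float = DEFAULT_TIMING_SD,
) -> GeneratorConfig:
    """Generator configuration calibrated row-for-row to the published table.

    EOL sub-cohort sizes are specified as exact counts (not sampled), so a
    generated cohort reproduces the printed totals exactly: 85,339 decedents
    with any nursing and 61,903 in the EOL sub-cohort.
    """
    means = dict(DEFAULT_TIMING_MEANS)
    if timing_means:
        means.update(timing_means)
    regions = []
    for prov, num, n_any, n_eol, med, q1, q3, fem, q5, cci in TABLE1_ROWS:
        rid = f"{prov}-{num}"
        regions.append(
            RegionSpec(
                region_id=rid,
                province=prov,
                n_any_nursing=n_any,
                p_eol=n_eol / n_any,
                n_eol=n_eol,
                timing_mean=means[rid],
                timing_sd=timing_sd,
                median_age=med,
                iqr_age=(q1, q3),
                p_female=fem / 100,
                p_comorbid=cci / 100,
                p_income_q5=q5 / 100,
            )
        )
    return GeneratorConfig(
        regions=regions, study_start=STUDY_START, study_end=STUDY_END, seed=seed
    )
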