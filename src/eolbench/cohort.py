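"""Cohort construction: inclusion criteria, intent reclassification, weekly counts.

Inclusion (any-nursing cohort): adult decedents (age >= 19 at death, whole
years) with at least one nursing visit on or after the diagnosis date, on or
before the death date, and within the outcome window (default 182 days
before death, both ends closed). The EOL sub-cohort additionally requires an
in-window visit with effective end-of-life intent.

Reclassification: once a patient has an EOL-intent visit, every visit on the
same or a later date is treated as end-of-life, regardless of its recorded
intent. The rule is monotone and idempotent.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .synthetic import OUTCOME_MAX_DAY

logger = logging.getLogger(__name__)


def reclassify_intents(visits: pd.DataFrame) -> pd.DataFrame:
    """Fill ``effective_intent``: eol from the first eol-intent visit onward.

    Same-day standard visits alongside an eol visit are reclassified to eol
    (the eol visit dominates). Visits strictly before a patient's first
    eol-intent visit keep effective_intent = 'standard'.
    """
    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"])
    first_eol = (
        v.loc[v["intent"] == "eol"].groupby("patient_id")["visit_date"].min()
    )
    fe = v["patient_id"].map(first_eol)
    v["effective_intent"] = np.where(
        fe.notna() & (v["visit_date"] >= fe), "eol", "standard"
    )
    return v


def age_at_death(patients: pd.DataFrame) -> pd.Series:
    """Age in whole years between birth_date and death_date."""
    b = pd.to_datetime(patients["birth_date"])
    d = pd.to_datetime(patients["death_date"])
    before_birthday = (d.dt.month < b.dt.month) | (
        (d.dt.month == b.dt.month) & (d.dt.day < b.dt.day)
    )
    return (d.dt.year - b.dt.year - before_birthday.astype(int)).rename("age")


def build_cohort(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    window_days: int = OUTCOME_MAX_DAY,
    study_start: dt.date | None = None,
    study_end: dt.date | None = None,
    min_age: int = 19,
) -> pd.DataFrame:
    """Apply inclusion criteria; return one membership row per patient.

    Returns a DataFrame with patient_id, in_any_nursing_cohort,
    in_eol_subcohort and index_date (death_date - window_days). Patients with
    a missing death date are flagged False with a null index_date and logged.

    Raises
    ------
    ValueError
        If window_days < 1 or any visit references an unknown patient_id.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    p = patients.copy()
    for col in ("birth_date", "death_date", "diagnosis_date"):
        p[col] = pd.to_datetime(p[col])

    unknown = ~visits["patient_id"].isin(p["patient_id"])
    if unknown.any():
        raise ValueError(
            f"{int(unknown.sum())} visit(s) reference unknown patient_id"
        )

    no_death = p["death_date"].isna()
    if no_death.any():
        logger.warning(
            "excluding %d patient(s) with missing death_date", int(no_death.sum())
        )

    p["age"] = age_at_death(p)
    p["index_date"] = p["death_date"] - pd.Timedelta(days=window_days)

    v = reclassify_intents(visits)
    v = v.merge(
        p[["patient_id", "death_date", "diagnosis_date", "index_date"]],
        on="patient_id",
        how="left",
    )
    in_window = (
        (v["visit_date"] >= v["index_date"])
        & (v["visit_date"] <= v["death_date"])
        & (v["visit_date"] >= v["diagnosis_date"])
    )
    has_any = v.loc[in_window, "patient_id"].unique()
    has_eol = v.loc[
        in_window & (v["effective_intent"] == "eol"), "patient_id"
    ].unique()

    eligible = (p["age"] >= min_age) & ~no_death
    if study_start is not None:
        eligible &= p["death_date"] >= pd.Timestamp(study_start)
    if study_end is not None:
        eligible &= p["death_date"] <= pd.Timestamp(study_end)

    membership = pd.DataFrame(
        {
            "patient_id": p["patient_id"],
            "in_any_nursing_cohort": eligible & p["patient_id"].isin(has_any),
            "index_date": p["index_date"].where(~no_death),
        }
    )
    membership["in_eol_subcohort"] = (
        membership["in_any_nursing_cohort"] & p["patient_id"].isin(has_eol).values
    )
    n_excl = int((~membership["in_any_nursing_cohort"]).sum())
    logger.info(
        "cohort built: %d any-nursing, %d EOL sub-cohort, %d excluded",
        int(membership["in_any_nursing_cohort"].sum()),
        int(membership["in_eol_subcohort"].sum()),
        n_excl,
    )
    return membership[
        ["patient_id", "in_any_nursing_cohort", "in_eol_subcohort", "index_date"]
    ]


def weekly_service_counts(
    visits: pd.DataFrame,
    membership: pd.DataFrame,
    window_days: int = OUTCOME_MAX_DAY,
) -> pd.DataFrame:
    """Distinct patients on standard vs EOL nursing per pre-death week.

    Weeks are anchored at death: week 26 covers days 0-6 before death,
    week 25 days 7-13, ..., week 1 the earliest days of the window (a visit
    on the index date itself folds into week 1). Within one week a patient
    counts in exactly one category — EOL wins if both intents occur — but may
    switch categories across weeks.
    """
    v = reclassify_intents(visits) if "effective_intent" not in visits else visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"])
    m = membership.loc[membership["in_any_nursing_cohort"]]
    v = v.merge(m[["patient_id", "index_date"]], on="patient_id", how="inner")
    death = v["index_date"] + pd.Timedelta(days=window_days)
    days_before = (death - v["visit_date"]).dt.days
    v = v.loc[(days_before >= 0) & (days_before <= window_days)].copy()
    days_before = days_before.loc[v.index]

    n_weeks = window_days // 7
    v["week"] = np.clip(n_weeks - days_before // 7, 1, n_weeks)
    per = (
        v.assign(is_eol=v["effective_intent"] == "eol")
        .groupby(["patient_id", "week"])["is_eol"]
        .any()
        .reset_index()
    )
    counts = (
        per.groupby(["week", "is_eol"])["patient_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(range(1, n_weeks + 1), fill_value=0)
    )
    return pd.DataFrame(
        {
            "week": range(1, n_weeks + 1),
            "n_standard": counts.get(False, pd.Series(0, index=counts.index)).values,
            "n_eol": counts.get(True, pd.Series(0, index=counts.index)).values,
        }
    )
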