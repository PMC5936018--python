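"""Seeded synthetic generator for linked decedent patient/visit tables.

Emulates the linkage output of provincial administrative databases: one
table of cancer decedents (demographics, region, diagnosis and death dates)
and one table of dated homecare nursing visits labelled with standard or
end-of-life (EOL) intent. The statistical structure matches what the
downstream analysis assumes:

* every patient dies inside the study window, is an adult (>= 19 at death),
  and has at least one nursing visit after diagnosis and within the last 182
  days of life;
* a configurable fraction (or exact count) of each region's patients starts
  EOL-intent nursing, with the first EOL visit day drawn from a normal
  distribution truncated to the 0-182 day outcome scale (0 = six months
  before death, 182 = death day) and rounded to whole days;
* standard-intent visits occur before EOL initiation (and are the only
  visits for non-EOL patients); a sparse set of pre-window visits exercises
  the downstream window filter without affecting the outcome.

The same config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

OUTCOME_MAX_DAY = 182  # death day on the outcome scale; day 0 = index date

# quartile z-spread of a standard normal, used to match a log-normal IQR
_IQR_Z = 1.3489795003921634


class RegionSpec(BaseModel):
    """Generating parameters for one health region."""

    region_id: str
    province: Literal["BC", "NS", "ON"]
    n_any_nursing: int = Field(ge=1)
    p_eol: float = Field(ge=0.0, le=1.0)
    n_eol: Optional[int] = Field(
        default=None, ge=0,
        description="Exact EOL sub-cohort size; overrides binomial sampling of p_eol.",
    )
    timing_mean: float = Field(ge=0.0, le=OUTCOME_MAX_DAY)
    timing_sd: float = Field(ge=0.0)  # 0 => point mass at round(timing_mean)
    median_age: float = Field(gt=19.0)
    iqr_age: tuple[float, float]
    p_female: float = Field(ge=0.0, le=1.0)
    p_comorbid: float = Field(ge=0.0, le=1.0)
    p_income_q5: float = Field(default=0.2, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "RegionSpec":
        q1, q3 = self.iqr_age
        if q1 > q3:
            raise ValueError(f"{self.region_id}: iqr_age must be (q1, q3) with q1 <= q3")
        if self.n_eol is not None and self.n_eol > self.n_any_nursing:
            raise ValueError(f"{self.region_id}: n_eol exceeds n_any_nursing")
        return self


class GeneratorConfig(BaseModel):
    """Full generator configuration: regions, study window, rates, seed."""

    regions: list[RegionSpec] = Field(min_length=1)
    study_start: dt.date
    study_end: dt.date
    seed: int = 0
    visit_rate_std: float = Field(default=1.5, ge=0.0)  # mean standard visits pre-EOL
    visit_rate_eol: float = Field(default=3.0, ge=0.0)  # mean EOL visits post-initiation

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        return self


def _region_eol_count(spec: RegionSpec, rng: np.random.Generator) -> int:
    if spec.n_eol is not None:
        return spec.n_eol
    expected = spec.p_eol * spec.n_any_nursing
    if 0 < expected < 1:
        warnings.warn(
            f"region {spec.region_id}: p_eol*n = {expected:.2f} < 1; "
            "emitting zero EOL patients",
            stacklevel=3,
        )
        return 0
    return int(rng.binomial(spec.n_any_nursing, spec.p_eol))


def _draw_first_eol_days(
    spec: RegionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """First-EOL-visit day on [0, 182]: truncated normal, whole days."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if spec.timing_sd == 0:
        return np.full(n, int(round(spec.timing_mean)), dtype=np.int64)
    a = (0 - spec.timing_mean) / spec.timing_sd
    b = (OUTCOME_MAX_DAY - spec.timing_mean) / spec.timing_sd
    draws = truncnorm.rvs(
        a, b, loc=spec.timing_mean, scale=spec.timing_sd, size=n, random_state=rng
    )
    return np.clip(np.round(draws), 0, OUTCOME_MAX_DAY).astype(np.int64)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate synthetic (patients, visits) tables.

    Returns
    -------
    patients : DataFrame
        Columns patient_id, region_id, province, sex, birth_date, death_date,
        diagnosis_date, income_quintile, charlson_ge1 (dates as datetime64).
    visits : DataFrame
        Columns patient_id, visit_date, intent ('standard' | 'eol'), sorted
        by patient then date.
    """
    ids = [r.region_id for r in config.regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"overlapping region_ids: {dupes}")

    rng = np.random.default_rng(config.seed)
    horizon = (config.study_end - config.study_start).days

    pat_cols: dict[str, list[np.ndarray]] = {
        k: [] for k in (
            "region_id", "province", "sex", "death_day", "birth_lag",
            "diag_lag", "income_quintile", "charlson_ge1",
        )
    }
    vis_pat_idx: list[np.ndarray] = []
    vis_day: list[np.ndarray] = []  # day on outcome scale relative to index date
    vis_intent: list[np.ndarray] = []
    offset = 0

    for spec in config.regions:
        n = spec.n_any_nursing
        n_eol = _region_eol_count(spec, rng)

        death_day = rng.integers(0, horizon + 1, n)
        # diagnosis precedes the 182-day window so every window day is
        # post-diagnosis (inclusion requires >= 1 post-diagnosis visit)
        diag_lag = OUTCOME_MAX_DAY + 1 + rng.integers(0, 913, n)

        q1, q3 = spec.iqr_age
        sigma = (math.log(q3) - math.log(q1)) / _IQR_Z if q3 > q1 else 0.0
        age = np.exp(rng.normal(math.log(spec.median_age), sigma, n))
        age = np.clip(np.round(age), 19, 105).astype(np.int64)
        # birth offset keeps whole-year age at death >= 19 and ~= drawn age
        birth_lag = np.round(age * 365.25).astype(np.int64) + rng.integers(20, 345, n)

        sex = np.where(rng.random(n) < spec.p_female, "F", "M")
        charlson = rng.random(n) < spec.p_comorbid
        quintile = np.where(
            rng.random(n) < spec.p_income_q5, 5, rng.integers(1, 5, n)
        ).astype(np.int64)

        is_eol = np.zeros(n, dtype=bool)
        if n_eol:
            is_eol[rng.permutation(n)[:n_eol]] = True
        eol_idx = np.flatnonzero(is_eol) + offset
        std_idx = np.flatnonzero(~is_eol) + offset

        first_day = _draw_first_eol_days(spec, n_eol, rng)
        vis_pat_idx.append(eol_idx)
        vis_day.append(first_day)
        vis_intent.append(np.ones(n_eol, dtype=np.int8))

        # follow-up EOL visits after initiation
        if config.visit_rate_eol > 0 and n_eol:
            k = rng.poisson(config.visit_rate_eol, n_eol)
            rep = np.repeat(np.arange(n_eol), k)
            if rep.size:
                lo = first_day[rep]
                days = rng.integers(lo, OUTCOME_MAX_DAY + 1)
                vis_pat_idx.append(eol_idx[rep])
                vis_day.append(days)
                vis_intent.append(np.ones(rep.size, dtype=np.int8))

        # standard visits before initiation (EOL patients with first_day >= 1)
        if config.visit_rate_std > 0 and n_eol:
            can_pre = first_day >= 1
            k = np.where(can_pre, rng.poisson(config.visit_rate_std, n_eol), 0)
            rep = np.repeat(np.arange(n_eol), k)
            if rep.size:
                days = rng.integers(0, first_day[rep])
                vis_pat_idx.append(eol_idx[rep])
                vis_day.append(days)
                vis_intent.append(np.zeros(rep.size, dtype=np.int8))

        # standard-only patients: guaranteed one in-window visit plus extras
        n_std = n - n_eol
        if n_std:
            k = 1 + rng.poisson(config.visit_rate_std, n_std)
            rep = np.repeat(np.arange(n_std), k)
            days = rng.integers(0, OUTCOME_MAX_DAY + 1, rep.size)
            vis_pat_idx.append(std_idx[rep])
            vis_day.append(days)
            vis_intent.append(np.zeros(rep.size, dtype=np.int8))

        # sparse pre-window standard visits (outside the outcome window,
        # still post-diagnosis); exercise the downstream window filter
        pre = rng.random(n) < 0.15
        if pre.any():
            idx = np.flatnonzero(pre)
            k = rng.integers(1, 91, idx.size)
            k = np.minimum(k, diag_lag[idx] - OUTCOME_MAX_DAY - 1)
            keep = k >= 1
            if keep.any():
                vis_pat_idx.append(idx[keep] + offset)
                vis_day.append(-k[keep])
                vis_intent.append(np.zeros(int(keep.sum()), dtype=np.int8))

        pat_cols["region_id"].append(np.full(n, spec.region_id, dtype=object))
        pat_cols["province"].append(np.full(n, spec.province, dtype=object))
        pat_cols["sex"].append(sex)
        pat_cols["death_day"].append(death_day)
        pat_cols["birth_lag"].append(birth_lag)
        pat_cols["diag_lag"].append(diag_lag)
        pat_cols["income_quintile"].append(quintile)
        pat_cols["charlson_ge1"].append(charlson)
        offset += n

    death_day = np.concatenate(pat_cols["death_day"])
    start = pd.Timestamp(config.study_start)
    death_date = start + pd.to_timedelta(death_day, unit="D")
    n_total = offset
    patient_id = np.array([f"P{i:07d}" for i in range(n_total)], dtype=object)

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "region_id": np.concatenate(pat_cols["region_id"]),
            "province": np.concatenate(pat_cols["province"]),
            "sex": np.concatenate(pat_cols["sex"]),
            "birth_date": death_date
            - pd.to_timedelta(np.concatenate(pat_cols["birth_lag"]), unit="D"),
            "death_date": death_date,
            "diagnosis_date": death_date
            - pd.to_timedelta(np.concatenate(pat_cols["diag_lag"]), unit="D"),
            "income_quintile": np.concatenate(pat_cols["income_quintile"]),
            "charlson_ge1": np.concatenate(pat_cols["charlson_ge1"]),
        }
    )

    v_idx = np.concatenate(vis_pat_idx) if vis_pat_idx else np.empty(0, np.int64)
    v_day = np.concatenate(vis_day) if vis_day else np.empty(0, np.int64)
    v_int = np.concatenate(vis_intent) if vis_intent else np.empty(0, np.int8)
    visit_date = (
        start
        + pd.to_timedelta(death_day[v_idx] - OUTCOME_MAX_DAY + v_day, unit="D")
    )
    visits = pd.DataFrame(
        {
            "patient_id": patient_id[v_idx],
            "visit_date": visit_date,
            "intent": np.where(v_int == 1, "eol", "standard"),
        }
    ).sort_values(["patient_id", "visit_date", "intent"], kind="mergesort")
    visits = visits.reset_index(drop=True)
    return patients, visits


def write_cohort(
    patients: pd.DataFrame, visits: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write patients.csv and visits.csv with ISO-8601 dates; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_path, v_path = out / "patients.csv", out / "visits.csv"
    patients.to_csv(p_path, index=False, date_format="%Y-%m-%d")
    visits.to_csv(v_path, index=False, date_format="%Y-%m-%d")
    return p_path, v_path


def read_cohort(
    patients_csv: str | Path, visits_csv: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read patient/visit CSVs, parsing date columns."""
    patients = pd.read_csv(
        patients_csv, parse_dates=["birth_date", "death_date", "diagnosis_date"]
    )
    visits = pd.read_csv(visits_csv, parse_dates=["visit_date"])
    return patients, visits
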