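import datetime as dt

import pandas as pd
import pytest

import eolbench as eb


def make_region(
    region_id="R1",
    province="BC",
    n=200,
    p_eol=0.8,
    n_eol=None,
    timing_mean=70.0,
    timing_sd=30.0,
    **kw,
):
    defaults = dict(
        median_age=71, iqr_age=(61, 80), p_female=0.48, p_comorbid=0.2
    )
    defaults.update(kw)
    return eb.RegionSpec(
        region_id=region_id,
        province=province,
        n_any_nursing=n,
        p_eol=p_eol,
        n_eol=n_eol,
        timing_mean=timing_mean,
        timing_sd=timing_sd,
        **defaults,
    )


def make_config(regions, seed=0, **kw):
    return eb.GeneratorConfig(
        regions=regions,
        study_start=dt.date(2004, 4, 1),
        study_end=dt.date(2009, 3, 31),
        seed=seed,
        **kw,
    )


def make_patient(pid, death, region="R1", province="BC", sex="F",
                 birth=None, diagnosis=None):
    death = pd.Timestamp(death)
    return {
        "patient_id": pid,
        "region_id": region,
        "province": province,
        "sex": sex,
        "birth_date": pd.Timestamp(birth) if birth else death - pd.Timedelta(days=70 * 365),
        "death_date": death,
        "diagnosis_date": pd.Timestamp(diagnosis) if diagnosis else death - pd.Timedelta(days=400),
        "income_quintile": 3,
        "charlson_ge1": False,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Three mid-size regions with distinct timing means; shared read-only."""
    cfg = make_config(
        [
            make_region("A-1", "BC", n=600, p_eol=0.9, timing_mean=55, timing_sd=30),
            make_region("A-2", "NS", n=500, p_eol=0.8, timing_mean=70, timing_sd=30),
            make_region("A-3", "ON", n=700, p_eol=0.7, timing_mean=90, timing_sd=30),
        ],
        seed=42,
    )
    patients, visits = eb.generate_cohort(cfg)
    membership = eb.build_cohort(
        patients, visits, study_start=cfg.study_start, study_end=cfg.study_end
    )
    outcomes = eb.compute_outcomes(membership, visits, patients)
    summary, strata = eb.summarize_regions(outcomes, membership, patients)
    return {
        "config": cfg,
        "patients": patients,
        "visits": visits,
        "membership": membership,
        "outcomes": outcomes,
        "summary": summary,
        "strata": strata,
    }


@pytest.fixture(scope="session")
def table1_analysis():
    """Full published-table-calibrated synthetic run (default timing means)."""
    cfg = eb.default_table1_config(seed=1234)
    patients, visits = eb.generate_cohort(cfg)
    membership = eb.build_cohort(
        patients, visits, study_start=cfg.study_start, study_end=cfg.study_end
    )
    outcomes = eb.compute_outcomes(membership, visits, patients)
    summary, strata = eb.summarize_regions(outcomes, membership, patients)
    return {
        "config": cfg,
        "patients": patients,
        "visits": visits,
        "membership": membership,
        "outcomes": outcomes,
        "summary": summary,
        "strata": strata,
    }
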