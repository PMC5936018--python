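"""Inclusion criteria, intent reclassification, weekly service tabulation."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eolbench as eb
from conftest import make_patient
from oracles import brute_force_weekly_counts


def _visits(pid, dated_intents):
    return pd.DataFrame(
        [
            {"patient_id": pid, "visit_date": pd.Timestamp(d), "intent": i}
            for d, i in dated_intents
        ]
    )


class TestReclassification:
    def test_quoted_rule_sequence(self):
        v = _visits(
            "p1",
            [
                ("2008-01-01", "standard"),
                ("2008-01-10", "standard"),
                ("2008-01-20", "eol"),
                ("2008-02-01", "standard"),
                ("2008-02-10", "standard"),
            ],
        )
        out = eb.reclassify_intents(v)
        assert list(out["effective_intent"]) == [
            "standard", "standard", "eol", "eol", "eol",
        ]

    def test_all_standard_unchanged(self):
        v = _visits("p1", [("2008-01-01", "standard"), ("2008-02-01", "standard")])
        assert (eb.reclassify_intents(v)["effective_intent"] == "standard").all()

    def test_eol_first_visit_makes_all_eol(self):
        v = _visits("p1", [("2008-01-01", "eol"), ("2008-02-01", "standard")])
        assert (eb.reclassify_intents(v)["effective_intent"] == "eol").all()

    def test_same_day_standard_dominated_by_eol(self):
        v = _visits("p1", [("2008-01-05", "standard"), ("2008-01-05", "eol")])
        assert (eb.reclassify_intents(v)["effective_intent"] == "eol").all()

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=20))
    def test_monotone_and_idempotent(self, eol_flags):
        dates = pd.date_range("2008-01-01", periods=len(eol_flags), freq="3D")
        v = pd.DataFrame(
            {
                "patient_id": "p",
                "visit_date": dates,
                "intent": ["eol" if f else "standard" for f in eol_flags],
            }
        )
        once = eb.reclassify_intents(v)
        eff = (once["effective_intent"] == "eol").tolist()
        # monotone: once eol, never reverts
        assert eff == sorted(eff)
        # standard strictly before first recorded eol stays standard
        if True in eol_flags:
            first = eol_flags.index(True)
            assert not any(eff[:first])
            assert all(eff[first:])
        else:
            assert not any(eff)
        # idempotent on its own output
        twice = eb.reclassify_intents(once)
        assert list(twice["effective_intent"]) == list(once["effective_intent"])


class TestInclusionCriteria:
    def test_age_18_excluded_19_included(self):
        patients = pd.DataFrame(
            [
                make_patient("kid", "2008-06-30", birth="1990-07-01"),   # 17
                make_patient("adult", "2008-06-30", birth="1989-06-30"),  # 19
                make_patient("almost", "2008-06-30", birth="1989-07-01"),  # 18
            ]
        )
        visits = pd.concat(
            [_visits(p, [("2008-06-01", "standard")]) for p in ("kid", "adult", "almost")]
        )
        m = eb.build_cohort(patients, visits).set_index("patient_id")
        assert not m.loc["kid", "in_any_nursing_cohort"]
        assert not m.loc["almost", "in_any_nursing_cohort"]
        assert m.loc["adult", "in_any_nursing_cohort"]

    def test_visit_outside_window_excluded(self):
        patients = pd.DataFrame([make_patient("p", "2008-06-30")])
        far = eb.build_cohort(
            patients, _visits("p", [("2007-12-13", "standard")])  # 200 days before
        )
        assert not far["in_any_nursing_cohort"].iloc[0]
        edge = eb.build_cohort(
            patients, _visits("p", [("2007-12-31", "standard")])  # exactly 182 days
        )
        assert edge["in_any_nursing_cohort"].iloc[0]

    def test_visit_before_diagnosis_does_not_qualify(self):
        patients = pd.DataFrame(
            [make_patient("p", "2008-06-30", diagnosis="2008-05-01")]
        )
        m = eb.build_cohort(patients, _visits("p", [("2008-04-01", "standard")]))
        assert not m["in_any_nursing_cohort"].iloc[0]
        m2 = eb.build_cohort(patients, _visits("p", [("2008-05-01", "standard")]))
        assert m2["in_any_nursing_cohort"].iloc[0]

    def test_death_outside_study_period_excluded(self):
        patients = pd.DataFrame([make_patient("p", "2010-06-30")])
        m = eb.build_cohort(
            patients,
            _visits("p", [("2010-06-01", "standard")]),
            study_start=pd.Timestamp("2004-04-01").date(),
            study_end=pd.Timestamp("2009-03-31").date(),
        )
        assert not m["in_any_nursing_cohort"].iloc[0]

    def test_unknown_patient_id_rejected_with_count(self):
        patients = pd.DataFrame([make_patient("p", "2008-06-30")])
        visits = pd.concat(
            [_visits("p", [("2008-06-01", "standard")]),
             _visits("ghost", [("2008-06-01", "standard")])]
        )
        with pytest.raises(ValueError, match="1 visit"):
            eb.build_cohort(patients, visits)

    def test_missing_death_date_excluded_not_fatal(self):
        rows = [make_patient("p", "2008-06-30"), make_patient("q", "2008-06-30")]
        patients = pd.DataFrame(rows)
        patients.loc[patients["patient_id"] == "q", "death_date"] = pd.NaT
        visits = pd.concat(
            [_visits("p", [("2008-06-01", "standard")]),
             _visits("q", [("2008-06-01", "standard")])]
        )
        m = eb.build_cohort(patients, visits).set_index("patient_id")
        assert m.loc["p", "in_any_nursing_cohort"]
        assert not m.loc["q", "in_any_nursing_cohort"]

    def test_eol_subcohort_contained_in_any_nursing(self, small_cohort):
        m = small_cohort["membership"]
        assert (m["in_eol_subcohort"] <= m["in_any_nursing_cohort"]).all()


class TestWeeklyCounts:
    def test_single_eol_visit_near_death(self):
        patients = pd.DataFrame([make_patient("p", "2008-06-30")])
        visits = _visits("p", [("2008-06-27", "eol")])  # 3 days before death
        m = eb.build_cohort(patients, visits)
        weekly = eb.weekly_service_counts(visits, m)
        assert len(weekly) == 26
        assert weekly.loc[weekly["week"] == 26, "n_eol"].iloc[0] == 1
        assert weekly["n_eol"].sum() == 1
        assert weekly["n_standard"].sum() == 0

    def test_no_in_window_visits_gives_zero_counts(self):
        patients = pd.DataFrame([make_patient("p", "2008-06-30")])
        visits = _visits("p", [("2008-06-01", "standard")])
        m = eb.build_cohort(patients, visits)
        m["in_any_nursing_cohort"] = True  # member, but probe a no-visit week table
        weekly = eb.weekly_service_counts(
            _visits("p", [("2006-01-01", "standard")]), m
        )
        assert weekly["n_eol"].sum() == 0 and weekly["n_standard"].sum() == 0

    def test_eol_wins_within_week_but_not_across(self):
        patients = pd.DataFrame([make_patient("p", "2008-06-30")])
        visits = _visits(
            "p",
            [("2008-06-25", "standard"), ("2008-06-27", "eol"),  # same final week
             ("2008-06-10", "standard")],                          # earlier week
        )
        m = eb.build_cohort(patients, visits)
        weekly = eb.weekly_service_counts(visits, m).set_index("week")
        assert weekly.loc[26, "n_eol"] == 1 and weekly.loc[26, "n_standard"] == 0
        assert weekly.loc[24, "n_standard"] == 1  # days 14-20 before death

    def test_matches_brute_force_recount(self, small_cohort):
        visits = eb.reclassify_intents(small_cohort["visits"])
        m = small_cohort["membership"]
        weekly = eb.weekly_service_counts(visits, m)

        merged = visits.merge(
            small_cohort["patients"][["patient_id", "death_date"]], on="patient_id"
        ).merge(
            m.loc[m["in_any_nursing_cohort"], ["patient_id"]], on="patient_id"
        )
        rows = [
            (r.patient_id, (r.death_date - r.visit_date).days, r.effective_intent)
            for r in merged.itertuples()
        ]
        expected = brute_force_weekly_counts(rows)
        for r in weekly.itertuples():
            assert (r.n_standard, r.n_eol) == expected[r.week]
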