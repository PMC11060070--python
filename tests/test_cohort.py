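"""Phenotyping rules: T2DM entry, depression qualification, censoring."""

import numpy as np
import pandas as pd
import pytest

import nestedcc as ncc
from nestedcc.cohort import CohortParams, ReferentialIntegrityError, censor
from nestedcc.tables import as_days

from conftest import _death, _event, _patient, _rx, make_tables, qualifying_patient_rows


def _entries(tables, threshold=11.1):
    return ncc.identify_t2dm_entry(
        tables["patients"], tables["prescriptions"], tables["clinical_events"], threshold
    )


def _base_rows(pid="P1", entry="2005-01-01", **kw):
    return qualifying_patient_rows(pid, entry, **kw)


class TestT2dmEntry:
    def test_qualifying_patient_gets_entry_at_first_oral_antidiabetic(self):
        r = _base_rows()
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        entries = _entries(t)
        assert list(entries.index) == ["P1"]
        assert entries.iloc[0] == np.datetime64("2005-01-01")

    def test_first_prescription_too_soon_after_registration_is_excluded(self):
        r = _base_rows()
        r["prescriptions"] = [_rx("P1", "2000-04-10")]  # day 100 of registration
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 0

    def test_lead_time_boundary_183_days_is_inclusive(self):
        r = _base_rows()
        r["prescriptions"] = [_rx("P1", np.datetime64("2000-01-01") + 183)]
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 1

    def test_insulin_200_days_after_first_oral_agent_is_included(self):
        r = _base_rows()
        r["prescriptions"].append(
            _rx("P1", np.datetime64("2005-01-01") + 200, drug_class="insulin",
                agent="insulin")
        )
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 1

    def test_insulin_within_183_days_flags_possible_type1(self):
        r = _base_rows()
        r["prescriptions"].append(
            _rx("P1", np.datetime64("2005-01-01") + 100, drug_class="insulin",
                agent="insulin")
        )
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 0

    def test_single_high_glucose_test_is_not_enough(self):
        r = _base_rows()
        r["events"] = [e for e in r["events"] if e["value"] != "14.000"]
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 0

    def test_antidiabetics_only_during_pregnancy_are_excluded(self):
        r = _base_rows()
        r["events"] += [
            _event("P1", "2004-11-01", "pregnancy_start"),
            _event("P1", "2005-08-01", "pregnancy_end"),
        ]
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 0
        # a second prescription outside pregnancy restores eligibility
        r["prescriptions"].append(_rx("P1", "2006-01-01"))
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        assert len(_entries(t)) == 1

    def test_prescription_for_unknown_patient_raises(self):
        r = _base_rows()
        r["prescriptions"].append(_rx("GHOST", "2005-01-01"))
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        with pytest.raises(ReferentialIntegrityError):
            _entries(t)


class TestDepressionFlag:
    def _events_to_frame(self, events):
        return make_tables([], events=events)["clinical_events"]

    def test_only_dementia_context_codes_do_not_qualify(self):
        ev = self._events_to_frame(
            [_event("P1", "2006-01-01", "depression_dementia_context")]
        )
        entry = pd.Series([np.datetime64("2005-01-01")], index=["P1"])
        assert ncc.flag_depression(ev, entry) == {}

    def test_code_before_entry_only_is_excluded_by_default(self):
        ev = self._events_to_frame([_event("P1", "2004-01-01", "depression")])
        entry = pd.Series([np.datetime64("2005-01-01")], index=["P1"])
        assert ncc.flag_depression(ev, entry) == {}
        anytime = ncc.flag_depression(ev, entry, rule="any_time")
        assert list(anytime) == ["P1"]

    def test_post_entry_codes_are_returned_sorted(self):
        ev = self._events_to_frame(
            [
                _event("P1", np.datetime64("2005-01-01") + 400, "depression"),
                _event("P1", np.datetime64("2005-01-01") + 1, "depression"),
            ]
        )
        entry = pd.Series([np.datetime64("2005-01-01")], index=["P1"])
        dates = ncc.flag_depression(ev, entry)["P1"]
        assert list(dates) == sorted(dates)
        assert len(dates) == 2


class TestCensor:
    def _pat_frame(self, reg_end):
        return make_tables([_patient("P1", reg_end=reg_end)])["patients"]

    def test_death_before_deregistration_wins(self):
        deaths = make_tables([], deaths=[_death("P1", "2010-05-01")])["deaths"]
        out = censor(self._pat_frame("2012-01-01"), deaths, "2018-12-31")
        assert out.loc[0, "censor_date"] == np.datetime64("2010-05-01")
        assert out.loc[0, "censor_reason"] == "death"

    def test_study_end_caps_open_registration(self):
        deaths = make_tables([], deaths=[])["deaths"]
        out = censor(self._pat_frame("2020-03-01"), deaths, "2018-12-31")
        assert out.loc[0, "censor_date"] == np.datetime64("2018-12-31")
        assert out.loc[0, "censor_reason"] == "study_end"

    def test_tie_between_death_and_deregistration_reports_death(self):
        deaths = make_tables([], deaths=[_death("P1", "2012-01-01")])["deaths"]
        out = censor(self._pat_frame("2012-01-01"), deaths, "2018-12-31")
        assert out.loc[0, "censor_reason"] == "death"


class TestBuildCohort:
    def test_seventeen_year_old_at_entry_is_excluded(self):
        r = _base_rows(yob=1988)  # age 17 in 2005
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        cohort, tally = ncc.build_cohort(
            t["patients"], t["prescriptions"], t["clinical_events"], t["deaths"]
        )
        assert len(cohort) == 0
        assert tally["under_age_minimum"] == 1

    def test_default_run_satisfies_member_invariants(self, default_cohort):
        cohort, _ = default_cohort
        entry = as_days(cohort["entry_date"])
        assert (entry <= as_days(cohort["censor_date"])).all()
        assert (cohort["age_at_entry"] >= 18).all()
        assert (as_days(cohort["first_depression_date"]) > entry).all()
        assert cohort["patient_id"].is_unique

    def test_exclusion_tally_accounts_for_every_patient(self, default_tables, default_cohort):
        _, t = default_tables
        _, tally = default_cohort
        assert sum(tally.values()) == len(t["patients"])

    def test_membership_matches_independent_rule_reapplication(self, default_tables, default_cohort):
        """Brute-force per-patient oracle re-applies every inclusion rule."""
        cfg, t = default_tables
        cohort, _ = default_cohort
        rx_by = dict(tuple(t["prescriptions"].groupby("patient_id")))
        ev_by = dict(tuple(t["clinical_events"].groupby("patient_id")))
        death_by = t["deaths"].set_index("patient_id")["death_date"]
        study_end = np.datetime64("2018-12-31")
        expected = set()
        for p in t["patients"].itertuples(index=False):
            rx = rx_by.get(p.patient_id)
            if rx is None:
                continue
            oad = rx[rx["drug_class"] == "oral_antidiabetic"]
            if not len(oad):
                continue
            entry = oad["date"].min()
            if (entry - p.registration_start).days < 183:
                continue
            ev = ev_by.get(p.patient_id)
            gl = ev[ev["code_category"] == "glucose_test"] if ev is not None else None
            if gl is None or (pd.to_numeric(gl["value"]) > cfg.glucose_threshold).sum() < 2:
                continue
            ins = rx[rx["drug_class"] == "insulin"]
            if len(ins) and (ins["date"].min() - entry).days < 183:
                continue
            starts = sorted(ev.loc[ev["code_category"] == "pregnancy_start", "date"])
            ends = sorted(ev.loc[ev["code_category"] == "pregnancy_end", "date"])
            antidiab = rx[rx["drug_class"].isin(["oral_antidiabetic", "insulin"])]
            if starts and all(
                any(s <= d <= e for s, e in zip(starts, ends))
                for d in antidiab["date"]
            ):
                continue
            dep = ev[(ev["code_category"] == "depression") & (ev["date"] > entry)]
            if not len(dep):
                continue
            if entry.year - p.year_of_birth < 18:
                continue
            cens = min(
                death_by.get(p.patient_id, pd.Timestamp("9999-01-01")),
                pd.Timestamp(p.registration_end),
                pd.Timestamp(study_end),
            )
            if pd.Timestamp(entry) > cens:
                continue
            expected.add(p.patient_id)
        assert expected == set(cohort["patient_id"])

    def test_phenotyping_is_idempotent_on_its_own_members(self, default_tables, default_cohort):
        _, t = default_tables
        cohort, _ = default_cohort
        ids = set(cohort["patient_id"])
        sub = {
            "patients": t["patients"][t["patients"]["patient_id"].isin(ids)],
            "prescriptions": t["prescriptions"][t["prescriptions"]["patient_id"].isin(ids)],
            "clinical_events": t["clinical_events"][t["clinical_events"]["patient_id"].isin(ids)],
            "deaths": t["deaths"][t["deaths"]["patient_id"].isin(ids)],
        }
        cohort2, _ = ncc.build_cohort(
            sub["patients"], sub["prescriptions"], sub["clinical_events"], sub["deaths"]
        )
        pd.testing.assert_frame_equal(
            cohort.sort_values("patient_id").reset_index(drop=True),
            cohort2.sort_values("patient_id").reset_index(drop=True),
        )

    def test_missing_ethnicity_imputed_as_white_and_flagged(self):
        r = _base_rows()
        r["patients"][0]["ethnicity"] = ""
        t = make_tables(r["patients"], r["prescriptions"], r["events"])
        cohort, _ = ncc.build_cohort(
            t["patients"], t["prescriptions"], t["clinical_events"], t["deaths"]
        )
        assert cohort.loc[0, "ethnicity"] == "white"
        assert cohort.loc[0, "ethnicity_missing"] == 1
        assert cohort.loc[0, "ethnicity_nonwhite"] == 0

    def test_bmi_imputation_is_seeded_and_flagged(self, default_tables):
        _, t = default_tables
        a, _ = ncc.build_cohort(
            t["patients"], t["prescriptions"], t["clinical_events"], t["deaths"],
            CohortParams(seed=5),
        )
        b, _ = ncc.build_cohort(
            t["patients"], t["prescriptions"], t["clinical_events"], t["deaths"],
            CohortParams(seed=5),
        )
        pd.testing.assert_series_equal(a["bmi"], b["bmi"])
        assert a["bmi_missing"].sum() > 0
        assert a["bmi"].notna().all()
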