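"""Case extraction, risk-set eligibility and matched-control sampling."""

import numpy as np
import pandas as pd
import pytest

import nestedcc as ncc


def _cohort_row(pid, entry="2005-01-01", censor="2018-12-31", reason="study_end",
                dep="2005-02-01", age=65, gender="female", practice="G000"):
    return dict(
        patient_id=pid,
        entry_date=np.datetime64(entry, "D"),
        censor_date=np.datetime64(censor, "D"),
        censor_reason=reason,
        first_depression_date=np.datetime64(dep, "D"),
        age_at_entry=age,
        gender=gender,
        practice_id=practice,
    )


def _cohort(rows):
    return pd.DataFrame(rows)


def _deaths(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "death_date", "cause_category"]
    )


class TestExtractCases:
    def test_observation_days_is_a_calendar_day_count(self):
        cohort = _cohort([_cohort_row("A", entry="2005-01-01", censor="2012-01-19",
                                      reason="death")])
        deaths = _deaths([("A", np.datetime64("2012-01-19"), "cancer")])
        cases = ncc.extract_cases(cohort, deaths)
        # 7 years (one leap day, 2008) + 18 days
        assert cases.loc[0, "observation_days"] == 2574

    def test_member_without_death_is_absent(self):
        cohort = _cohort([_cohort_row("A"), _cohort_row("B")])
        deaths = _deaths([("A", np.datetime64("2010-01-01"), "cancer")])
        cases = ncc.extract_cases(cohort, deaths)
        assert list(cases["patient_id"]) == ["A"]

    def test_death_on_entry_date_is_skipped_with_warning(self):
        cohort = _cohort([_cohort_row("A", entry="2005-01-01")])
        deaths = _deaths([("A", np.datetime64("2005-01-01"), "cancer")])
        with pytest.warns(UserWarning):
            cases = ncc.extract_cases(cohort, deaths)
        assert len(cases) == 0


class TestEligibility:
    def _base(self):
        # case A dies after 100 days; B, C, D are potential controls
        cohort = _cohort([
            _cohort_row("A", entry="2005-01-01", censor="2005-04-11", reason="death"),
            _cohort_row("B", entry="2006-01-01"),
            _cohort_row("C", entry="2006-01-01", age=70),
            _cohort_row("D", entry="2006-01-01", practice="G001"),
        ])
        deaths = _deaths([("A", np.datetime64("2005-04-11"), "cancer")])
        case = ncc.extract_cases(cohort, deaths).iloc[0]
        return cohort, deaths, case

    def test_age_difference_of_exactly_five_years_is_eligible(self):
        cohort, deaths, case = self._base()
        assert "C" in ncc.eligible_controls(case, cohort, deaths)  # |70-65| = 5
        cohort.loc[cohort["patient_id"] == "C", "age_at_entry"] = 71
        assert "C" not in ncc.eligible_controls(case, cohort, deaths)

    def test_other_practice_is_ineligible(self):
        cohort, deaths, case = self._base()
        assert "D" not in ncc.eligible_controls(case, cohort, deaths)

    def test_control_dying_after_pseudo_outcome_date_is_eligible(self):
        cohort, deaths, case = self._base()
        # B's pseudo-outcome date is 2006-04-11; B dies 10 days later
        deaths2 = pd.concat(
            [deaths, _deaths([("B", np.datetime64("2006-04-21"), "cancer")])],
            ignore_index=True,
        )
        assert "B" in ncc.eligible_controls(case, cohort, deaths2)
        # dying on the pseudo-outcome date makes B ineligible
        deaths3 = pd.concat(
            [deaths, _deaths([("B", np.datetime64("2006-04-11"), "cancer")])],
            ignore_index=True,
        )
        assert "B" not in ncc.eligible_controls(case, cohort, deaths3)

    def test_depression_code_after_pseudo_date_blocks_default_rule(self):
        cohort, deaths, case = self._base()
        cohort.loc[cohort["patient_id"] == "B", "first_depression_date"] = (
            np.datetime64("2010-01-01")
        )
        assert "B" not in ncc.eligible_controls(case, cohort, deaths)
        assert "B" in ncc.eligible_controls(
            case, cohort, deaths, control_depression_window="any_time"
        )

    def test_short_followup_is_ineligible(self):
        cohort, deaths, case = self._base()
        cohort.loc[cohort["patient_id"] == "B", "censor_date"] = (
            np.datetime64("2006-01-31")  # only 30 days after B's entry
        )
        assert "B" not in ncc.eligible_controls(case, cohort, deaths)


class TestSampling:
    def test_two_eligible_gives_exactly_two_controls(self):
        cohort = _cohort([
            _cohort_row("A", entry="2005-01-01", censor="2005-04-11", reason="death"),
            _cohort_row("B", entry="2006-01-01"),
            _cohort_row("C", entry="2006-01-01"),
        ])
        deaths = _deaths([("A", np.datetime64("2005-04-11"), "cancer")])
        cases = ncc.extract_cases(cohort, deaths)
        sets, tally = ncc.sample_matched_sets(cases, cohort, deaths, seed=0)
        assert (sets["role"] == "control").sum() == 2
        assert tally == {"cases_total": 1, "cases_unmatched": 0, "sets": 1}

    def test_case_with_no_eligible_controls_is_dropped_and_tallied(self):
        cohort = _cohort([
            _cohort_row("A", entry="2005-01-01", censor="2005-04-11", reason="death"),
        ])
        deaths = _deaths([("A", np.datetime64("2005-04-11"), "cancer")])
        cases = ncc.extract_cases(cohort, deaths)
        sets, tally = ncc.sample_matched_sets(cases, cohort, deaths, seed=0)
        assert len(sets) == 0
        assert tally["cases_unmatched"] == 1

    def test_sampling_is_deterministic_under_a_seed(self, default_tables, default_cohort):
        _, t = default_tables
        cohort, _ = default_cohort
        cases = ncc.extract_cases(cohort, t["deaths"])
        a, _ = ncc.sample_matched_sets(cases, cohort, t["deaths"], seed=11)
        b, _ = ncc.sample_matched_sets(cases, cohort, t["deaths"], seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_matched_set_invariants_hold_on_a_full_run(self, default_tables, default_cohort):
        """1-4 controls, shared observation length, stratum agreement, no
        self-matching, correct pseudo-outcome anchoring."""
        _, t = default_tables
        cohort, _ = default_cohort
        cases = ncc.extract_cases(cohort, t["deaths"])
        sets, _ = ncc.sample_matched_sets(cases, cohort, t["deaths"], seed=1)
        assert sets["set_id"].nunique() == (sets["role"] == "case").sum()

        info = cohort.set_index("patient_id")
        for set_id, grp in sets.groupby("set_id"):
            case = grp[grp["role"] == "case"].iloc[0]
            controls = grp[grp["role"] == "control"]
            assert 1 <= len(controls) <= 4
            assert case["patient_id"] not in set(controls["patient_id"])
            assert (grp["observation_days"] == case["observation_days"]).all()
            cinfo = info.loc[case["patient_id"]]
            for _, ctrl in controls.iterrows():
                minfo = info.loc[ctrl["patient_id"]]
                assert minfo["gender"] == cinfo["gender"]
                assert minfo["practice_id"] == cinfo["practice_id"]
                assert abs(int(minfo["age_at_entry"]) - int(cinfo["age_at_entry"])) <= 5
                expected_pseudo = (
                    np.datetime64(minfo["entry_date"], "D")
                    + int(case["observation_days"])
                )
                assert np.datetime64(ctrl["reference_date"], "D") == expected_pseudo
                assert np.datetime64(minfo["censor_date"], "D") >= expected_pseudo

    def test_control_exposure_estimates_risk_set_exposure(self, null_tables):
        """Sampled controls are exposure-representative of their risk sets.

        Under the null, the exposure prevalence among sampled controls must
        track the brute-force prevalence among all eligible members at the
        same pseudo-outcome dates.
        """
        cfg, t = null_tables
        cohort, _ = ncc.build_cohort(
            t["patients"], t["prescriptions"], t["clinical_events"], t["deaths"]
        )
        cases = ncc.extract_cases(cohort, t["deaths"])
        sets, _ = ncc.sample_matched_sets(cases, cohort, t["deaths"], seed=3)
        expo = ncc.classify_for_sets(sets, t["prescriptions"], cohort)
        sampled = expo[expo["role"] == "control"]["any_antidepressant"]

        # brute-force: every eligible control of every case, classified at
        # its pseudo-outcome date
        entry = cohort.set_index("patient_id")["entry_date"]
        rows = []
        for case in cases.itertuples(index=False):
            for pid in ncc.eligible_controls(
                pd.Series(case._asdict()), cohort, t["deaths"]
            ):
                ref = np.datetime64(entry.loc[pid], "D") + int(case.observation_days)
                rows.append((f"F{len(rows)}", "control", pid, ref,
                             int(case.observation_days), case.cause_category))
        full = pd.DataFrame(rows, columns=sets.columns)
        full_expo = ncc.classify_for_sets(full, t["prescriptions"], cohort)
        p_full = full_expo["any_antidepressant"].mean()
        se = np.sqrt(p_full * (1 - p_full) / len(sampled))
        assert abs(sampled.mean() - p_full) <= 3 * se
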