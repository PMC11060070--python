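"""Phenotype the raw EHR tables into the base cohort.

The cohort is adults (>=18 at entry) with comorbid depression and newly
treated type 2 diabetes.  Entry is the date of the first oral antidiabetic
prescription, which must fall at least 183 days after registration; T2DM is
confirmed by at least two above-threshold glucose tests; early insulin
(possible type 1) and pregnancy-only antidiabetic prescribing (possible
gestational diabetes) are excluded.  Depression membership requires at
least one plain depression code dated after entry (context-specific codes
for dementia, maternity or severe mental illness never qualify).

All confounders are measured at study entry.  Missing ethnicity is imputed
as white; missing BMI is imputed by a single seeded draw from a normal
distribution fitted to the observed values (the complete-case sensitivity
analysis bounds the impact of this choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import as_days, reindex_dates


class ReferentialIntegrityError(ValueError):
    """A record references a patient_id absent from the patient table."""


@dataclass
class CohortParams:
    glucose_threshold: float = 11.1
    min_registration_lead_days: int = 183
    t1dm_insulin_window_days: int = 183
    age_min: int = 18
    depression_rule: str = "post_entry"  # or "any_time"
    study_end: str = "2018-12-31"
    contacts_window_days: int = 365
    polypharmacy_window_days: int = 90
    seed: int = 0  # BMI imputation draw

    def __post_init__(self) -> None:
        if self.depression_rule not in ("post_entry", "any_time"):
            raise ValueError(f"unknown depression_rule {self.depression_rule!r}")


# exclusion rules in flow-diagram order; each patient is tallied under the
# first rule it fails
EXCLUSION_ORDER = (
    "no_oral_antidiabetic",
    "first_oad_within_lead_window",
    "insufficient_glucose_evidence",
    "early_insulin_possible_t1dm",
    "pregnancy_only_antidiabetics",
    "no_qualifying_depression",
    "under_age_minimum",
    "no_followup_after_entry",
)


def _day_diff(later, earlier) -> np.ndarray:
    """Float day differences with NaN (not iNaT) where either date is missing."""
    delta = (np.asarray(later, dtype="datetime64[D]")
             - np.asarray(earlier, dtype="datetime64[D]"))
    out = delta.astype("timedelta64[D]").astype(float)
    return np.where(np.isnat(delta), np.nan, out)


def _check_referential(patients: pd.DataFrame, other: pd.DataFrame, what: str) -> None:
    known = set(patients["patient_id"])
    unknown = set(other["patient_id"]) - known
    if unknown:
        raise ReferentialIntegrityError(
            f"{what} references unknown patient_id(s), e.g. {sorted(unknown)[:3]}"
        )


def _t2dm_rule_frame(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
    glucose_threshold: float,
    lead_days: int = 183,
    t1dm_window: int = 183,
) -> pd.DataFrame:
    """Per-patient booleans for each T2DM inclusion rule plus the entry date."""
    _check_referential(patients, prescriptions, "prescriptions table")

    out = patients[["patient_id"]].copy()
    reg_start = as_days(patients["registration_start"])

    oad = prescriptions[prescriptions["drug_class"] == "oral_antidiabetic"]
    first_oad = oad.groupby("patient_id")["date"].min()
    entry = reindex_dates(first_oad, out["patient_id"])
    out["entry_date"] = entry
    out["has_oad"] = ~pd.isna(entry)
    out["lead_ok"] = out["has_oad"] & (_day_diff(entry, reg_start) >= lead_days)

    gl = clinical_events[clinical_events["code_category"] == "glucose_test"].copy()
    gl_val = pd.to_numeric(gl["value"], errors="coerce")
    high = gl[gl_val > glucose_threshold]
    n_high = high.groupby("patient_id").size()
    out["glucose_ok"] = n_high.reindex(out["patient_id"]).fillna(0).to_numpy() >= 2
    first_high = high.groupby("patient_id")["date"].min()
    out["first_high_glucose"] = reindex_dates(first_high, out["patient_id"])

    ins = prescriptions[prescriptions["drug_class"] == "insulin"]
    first_ins = ins.groupby("patient_id")["date"].min()
    ins_date = reindex_dates(first_ins, out["patient_id"])
    gap = _day_diff(ins_date, entry)  # NaN when no insulin or no entry
    out["insulin_ok"] = ~(gap < t1dm_window)

    out["pregnancy_ok"] = ~_pregnancy_only(patients, prescriptions, clinical_events)
    return out


def _pregnancy_only(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
) -> np.ndarray:
    """True where every antidiabetic prescription falls inside pregnancy."""
    flag = pd.Series(False, index=patients["patient_id"])
    preg = clinical_events[
        clinical_events["code_category"].isin(["pregnancy_start", "pregnancy_end"])
    ]
    if not len(preg):
        return flag.to_numpy()
    antidiab = prescriptions[
        prescriptions["drug_class"].isin(["oral_antidiabetic", "insulin"])
    ]
    for pid, ev in preg.groupby("patient_id"):
        rx_dates = as_days(antidiab.loc[antidiab["patient_id"] == pid, "date"])
        if len(rx_dates) == 0:
            continue
        starts = np.sort(as_days(ev.loc[ev["code_category"] == "pregnancy_start", "date"]))
        ends = np.sort(as_days(ev.loc[ev["code_category"] == "pregnancy_end", "date"]))
        inside = np.zeros(len(rx_dates), dtype=bool)
        for s, e in zip(starts, ends):
            inside |= (rx_dates >= s) & (rx_dates <= e)
        flag.loc[pid] = bool(inside.all())
    return flag.to_numpy()


def identify_t2dm_entry(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
    glucose_threshold: float,
    lead_days: int = 183,
    t1dm_window: int = 183,
) -> pd.Series:
    """Entry dates (first oral antidiabetic) for patients passing every rule."""
    rules = _t2dm_rule_frame(
        patients, prescriptions, clinical_events, glucose_threshold, lead_days, t1dm_window
    )
    ok = (
        rules["has_oad"]
        & rules["lead_ok"]
        & rules["glucose_ok"]
        & rules["insulin_ok"]
        & rules["pregnancy_ok"]
    )
    kept = rules[ok]
    return pd.Series(
        kept["entry_date"].to_numpy(dtype="datetime64[D]"),
        index=pd.Index(kept["patient_id"], name="patient_id"),
        name="entry_date",
    )


def flag_depression(
    clinical_events: pd.DataFrame,
    entry_dates: pd.Series,
    rule: str = "post_entry",
) -> dict[str, np.ndarray]:
    """Qualifying depression-code dates per patient, sorted ascending.

    Only plain ``depression`` codes qualify; context-specific variants
    (dementia, maternity, severe mental illness) never do, so a patient
    with only context codes is absent from the result.  Under the default
    ``post_entry`` rule a code must be dated strictly after entry.
    """
    dep = clinical_events[clinical_events["code_category"] == "depression"]
    dep = dep[dep["patient_id"].isin(entry_dates.index)]
    out: dict[str, np.ndarray] = {}
    for pid, ev in dep.groupby("patient_id"):
        dates = np.sort(as_days(ev["date"]))
        if rule == "post_entry":
            dates = dates[dates > np.datetime64(entry_dates.loc[pid], "D")]
        if len(dates):
            out[pid] = dates
    return out


def censor(
    patients: pd.DataFrame, deaths: pd.DataFrame, study_end
) -> pd.DataFrame:
    """Censor date and reason per patient: min(death, deregistration, study end).

    Ties are broken death > deregistration > study_end.
    """
    study_end = np.datetime64(study_end, "D")
    reg_end = as_days(patients["registration_end"])
    death = reindex_dates(
        deaths.set_index("patient_id")["death_date"], patients["patient_id"]
    )
    dates = np.stack(
        [
            np.where(pd.isna(death), np.datetime64("9999-12-31"), death),
            reg_end,
            np.full(len(patients), study_end),
        ]
    )
    which = np.argmin(dates, axis=0)  # argmin keeps the first (highest precedence)
    reason = np.asarray(["death", "deregistration", "study_end"], dtype=object)[which]
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "censor_date": dates.min(axis=0).astype("datetime64[D]"),
            "censor_reason": reason,
        }
    )


def build_cohort(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
    deaths: pd.DataFrame,
    params: CohortParams | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compose phenotyping into the cohort table plus an exclusion tally.

    Returns ``(cohort, tally)`` where the tally counts patients by the
    first inclusion rule they fail (flow-diagram accounting: input rows =
    excluded-by-rule + cohort rows).
    """
    params = params or CohortParams()
    n = len(patients)
    rules = _t2dm_rule_frame(
        patients,
        prescriptions,
        clinical_events,
        params.glucose_threshold,
        params.min_registration_lead_days,
        params.t1dm_insulin_window_days,
    ).set_index("patient_id")

    alive = pd.Series(True, index=rules.index)
    tally: dict[str, int] = {}

    def apply_rule(name: str, passed: pd.Series) -> None:
        failed = alive & ~passed
        tally[name] = int(failed.sum())
        alive[failed] = False

    apply_rule("no_oral_antidiabetic", rules["has_oad"])
    apply_rule("first_oad_within_lead_window", rules["lead_ok"])
    apply_rule("insufficient_glucose_evidence", rules["glucose_ok"])
    apply_rule("early_insulin_possible_t1dm", rules["insulin_ok"])
    apply_rule("pregnancy_only_antidiabetics", rules["pregnancy_ok"])

    entry_dates = pd.Series(
        rules.loc[alive, "entry_date"].to_numpy(dtype="datetime64[D]"),
        index=rules.index[alive],
    )
    dep_dates = flag_depression(clinical_events, entry_dates, params.depression_rule)
    apply_rule(
        "no_qualifying_depression",
        pd.Series(alive.index.isin(dep_dates.keys()), index=alive.index),
    )

    pat = patients.set_index("patient_id")
    entry_year = pd.Series(
        rules["entry_date"].to_numpy(dtype="datetime64[Y]").astype(float) + 1970,
        index=rules.index,
    )
    age_at_entry = entry_year - pat["year_of_birth"]
    apply_rule("under_age_minimum", age_at_entry >= params.age_min)

    cens = censor(patients, deaths, params.study_end).set_index("patient_id")
    apply_rule(
        "no_followup_after_entry",
        cens["censor_date"] >= rules["entry_date"],
    )

    member_ids = alive.index[alive]
    tally["cohort"] = len(member_ids)
    assert sum(tally.values()) == n

    if len(member_ids) == 0:
        warnings.warn("empty cohort after applying inclusion rules")

    cohort = _assemble_members(
        member_ids, pat, rules, cens, dep_dates, age_at_entry,
        prescriptions, clinical_events, deaths, params,
    )
    return cohort, tally


def _assemble_members(
    member_ids,
    pat: pd.DataFrame,
    rules: pd.DataFrame,
    cens: pd.DataFrame,
    dep_dates: dict,
    age_at_entry: pd.Series,
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
    deaths: pd.DataFrame,
    params: CohortParams,
) -> pd.DataFrame:
    ids = pd.Index(member_ids, name="patient_id")
    entry = rules.loc[ids, "entry_date"].to_numpy(dtype="datetime64[D]")
    entry_s = pd.Series(entry, index=ids)

    def latest_value_before(category: str) -> pd.Series:
        ev = clinical_events[
            (clinical_events["code_category"] == category)
            & clinical_events["patient_id"].isin(ids)
        ].copy()
        if not len(ev):
            return pd.Series(index=ids, dtype=object)
        ev["entry"] = entry_s.reindex(ev["patient_id"]).to_numpy()
        ev = ev[as_days(ev["date"]) <= as_days(ev["entry"])]
        ev = ev.sort_values(["patient_id", "date"], kind="mergesort")
        return ev.groupby("patient_id")["value"].last().reindex(ids)

    ethnicity = pat.loc[ids, "ethnicity"]
    eth_missing = ethnicity.isna() | (ethnicity.astype(str).str.len() == 0)
    ethnicity = ethnicity.where(~eth_missing, "white")

    bmi_raw = pd.to_numeric(latest_value_before("bmi"), errors="coerce")
    bmi_missing = bmi_raw.isna()
    observed = bmi_raw.dropna()
    if bmi_missing.any() and len(observed) >= 2:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(97,))
        )
        draws = rng.normal(observed.mean(), observed.std(ddof=1), size=int(bmi_missing.sum()))
        bmi = bmi_raw.copy()
        bmi[bmi_missing] = np.clip(draws, 14.0, 60.0)
    else:
        bmi = bmi_raw.fillna(observed.mean() if len(observed) else 30.0)

    smoking = latest_value_before("smoking_status").fillna("never")

    # comorbidity flags: any code on or before entry, one flag per name seen
    com = clinical_events[
        clinical_events["code_category"].str.startswith("comorbidity:")
    ]
    com_names = sorted({c.split(":", 1)[1] for c in com["code_category"].unique()})
    com_flags = {}
    for name in com_names:
        ev = com[(com["code_category"] == f"comorbidity:{name}") & com["patient_id"].isin(ids)]
        ev = ev[as_days(ev["date"]) <= as_days(entry_s.reindex(ev["patient_id"]).to_numpy())]
        com_flags[f"comorbidity_{name}"] = ids.isin(ev["patient_id"]).astype(int)

    # T2DM duration proxy: days from first above-threshold glucose test to entry
    first_high = rules.loc[ids, "first_high_glucose"].to_numpy(dtype="datetime64[D]")
    t2dm_days = np.maximum(
        (entry - first_high).astype("timedelta64[D]").astype(float), 0.0
    )

    # primary-care contact count in the window before entry
    ev = clinical_events[clinical_events["patient_id"].isin(ids)].copy()
    ev["entry"] = entry_s.reindex(ev["patient_id"]).to_numpy()
    delta = (as_days(ev["entry"]) - as_days(ev["date"])).astype(float)
    contacts = (
        ev[(delta >= 0) & (delta <= params.contacts_window_days)]
        .groupby("patient_id").size().reindex(ids).fillna(0).astype(int)
    )

    # polypharmacy: distinct drug classes prescribed in the window before entry
    rx = prescriptions[prescriptions["patient_id"].isin(ids)].copy()
    rx["entry"] = entry_s.reindex(rx["patient_id"]).to_numpy()
    rdelta = (as_days(rx["entry"]) - as_days(rx["date"])).astype(float)
    recent_rx = rx[(rdelta >= 0) & (rdelta <= params.polypharmacy_window_days)]
    poly = (
        recent_rx.groupby("patient_id")["drug_class"].nunique()
        .reindex(ids).fillna(0).astype(int)
    )

    # antidepressant prescribing history before (or on) study entry
    ad = rx[rx["drug_class"] == "antidepressant"]
    ad_pre = ad[as_days(ad["date"]) <= as_days(ad["entry"].to_numpy())]
    ad_history = ids.isin(ad_pre["patient_id"]).astype(int)

    first_dep = np.asarray(
        [dep_dates[p][0] for p in ids], dtype="datetime64[D]"
    )
    n_dep = np.asarray([len(dep_dates[p]) for p in ids])

    cohort = pd.DataFrame(
        {
            "patient_id": ids,
            "entry_date": entry,
            "censor_date": cens.loc[ids, "censor_date"].to_numpy(dtype="datetime64[D]"),
            "censor_reason": cens.loc[ids, "censor_reason"].to_numpy(),
            "first_depression_date": first_dep,
            "n_depression_codes": n_dep,
            "age_at_entry": age_at_entry.reindex(ids).astype(int).to_numpy(),
            "gender": pat.loc[ids, "gender"].to_numpy(),
            "practice_id": pat.loc[ids, "practice_id"].to_numpy(),
            "ethnicity": ethnicity.to_numpy(),
            "ethnicity_missing": eth_missing.astype(int).to_numpy(),
            "ethnicity_nonwhite": (ethnicity != "white").astype(int).to_numpy(),
            "bmi": bmi.to_numpy(dtype=float),
            "bmi_missing": bmi_missing.astype(int).to_numpy(),
            "smoking": smoking.to_numpy(),
            "smoking_ex": (smoking == "ex").astype(int).to_numpy(),
            "smoking_current": (smoking == "current").astype(int).to_numpy(),
            "t2dm_duration_years": t2dm_days / 365.25,
            "contacts_preentry": contacts.to_numpy(),
            "polypharmacy_preentry": poly.to_numpy(),
            "ad_history_preentry": ad_history,
        }
    )
    for name, flag in com_flags.items():
        cohort[name] = np.asarray(flag)
    return cohort.reset_index(drop=True)


def exclusion_report(tally: dict[str, int]) -> str:
    lines = ["Cohort exclusion flow", "---------------------"]
    total = sum(tally.values())
    lines.append(f"patients assessed: {total}")
    for rule in EXCLUSION_ORDER:
        if rule in tally:
            lines.append(f"excluded — {rule}: {tally[rule]}")
    lines.append(f"cohort members: {tally.get('cohort', 0)}")
    return "\n".join(lines) + "\n"
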