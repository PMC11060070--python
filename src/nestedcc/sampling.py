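"""Case extraction and incidence-density (risk-set) sampling of controls.

Each case (a cohort member with a death between entry and censoring) is
matched to up to four controls drawn uniformly without replacement from the
risk set: cohort members of the same gender and GP practice, entering within
five years of age of the case, still under observation for at least as many
days as the case, with no death on or before their pseudo-outcome date and
a qualifying depression code by then.  The pseudo-outcome date is the
control's own entry date plus the case's observation duration, so cases and
controls share the same observation-window length.  Members may serve as
controls in several sets and may later be cases themselves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import as_days, reindex_dates

SET_COLUMNS = [
    "set_id",
    "role",
    "patient_id",
    "reference_date",
    "observation_days",
    "cause_category",
]


def extract_cases(cohort: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """One record per cohort member whose death falls in (entry, censor]."""
    merged = cohort.merge(deaths, on="patient_id", how="inner")
    if not len(merged):
        return pd.DataFrame(
            columns=["patient_id", "outcome_date", "observation_days", "cause_category"]
        )
    obs = (as_days(merged["death_date"]) - as_days(merged["entry_date"])).astype(int)
    late = as_days(merged["death_date"]) > as_days(merged["censor_date"])
    invalid = (obs < 1) | late
    if invalid.any():
        warnings.warn(
            f"skipping {int(invalid.sum())} death record(s) on/before entry "
            "or after censoring"
        )
    kept = merged[~invalid]
    return pd.DataFrame(
        {
            "patient_id": kept["patient_id"].to_numpy(),
            "outcome_date": as_days(kept["death_date"]),
            "observation_days": obs[~invalid],
            "cause_category": kept["cause_category"].to_numpy(),
        }
    ).reset_index(drop=True)


class _RiskSetIndex:
    """Vectorised eligibility lookups over the cohort."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        deaths: pd.DataFrame,
        age_tolerance: int = 5,
        control_depression_window: str = "by_reference_date",
    ):
        self.age_tolerance = age_tolerance
        self.window_rule = control_depression_window
        self.pid = cohort["patient_id"].to_numpy(dtype=object)
        self.entry = as_days(cohort["entry_date"]).astype(np.int64)
        self.censor = as_days(cohort["censor_date"]).astype(np.int64)
        self.age = cohort["age_at_entry"].to_numpy(dtype=np.int64)
        self.first_dep = as_days(cohort["first_depression_date"]).astype(np.int64)
        death = reindex_dates(
            deaths.set_index("patient_id")["death_date"], cohort["patient_id"]
        )
        self.death = np.where(
            pd.isna(death), np.iinfo(np.int64).max, death.astype(np.int64)
        )
        self._stratum = list(
            zip(cohort["gender"].to_numpy(), cohort["practice_id"].to_numpy())
        )
        self._by_stratum: dict[tuple, np.ndarray] = {}
        for row, key in enumerate(self._stratum):
            self._by_stratum.setdefault(key, []).append(row)
        self._by_stratum = {k: np.asarray(v) for k, v in self._by_stratum.items()}
        self._pos = {p: i for i, p in enumerate(self.pid)}

    def eligible_rows(self, case_pid: str, observation_days: int) -> np.ndarray:
        i = self._pos[case_pid]
        rows = self._by_stratum[self._stratum[i]]
        rows = rows[rows != i]
        pseudo = self.entry[rows] + observation_days
        ok = (
            (np.abs(self.age[rows] - self.age[i]) <= self.age_tolerance)
            & (self.censor[rows] >= pseudo)
            & (self.death[rows] > pseudo)
        )
        if self.window_rule == "by_reference_date":
            ok &= self.first_dep[rows] <= pseudo
        return rows[ok]


def eligible_controls(
    case: pd.Series,
    cohort: pd.DataFrame,
    deaths: pd.DataFrame,
    age_tolerance: int = 5,
    control_depression_window: str = "by_reference_date",
) -> list[str]:
    """Sorted patient_ids eligible as controls for one case.

    Future cases are eligible ("regardless of whether they later became a
    case"); the age boundary is inclusive (|difference| <= tolerance).
    """
    member = cohort.set_index("patient_id").loc[case["patient_id"]]
    obs = int(case["observation_days"])
    pseudo = as_days(cohort["entry_date"]).astype(np.int64) + obs
    death = reindex_dates(
        deaths.set_index("patient_id")["death_date"], cohort["patient_id"]
    )
    death_i = np.where(pd.isna(death), np.iinfo(np.int64).max, death.astype(np.int64))
    ok = (
        (cohort["patient_id"].to_numpy() != case["patient_id"])
        & (cohort["gender"].to_numpy() == member["gender"])
        & (cohort["practice_id"].to_numpy() == member["practice_id"])
        & (np.abs(cohort["age_at_entry"].to_numpy() - int(member["age_at_entry"]))
           <= age_tolerance)
        & (as_days(cohort["censor_date"]).astype(np.int64) >= pseudo)
        & (death_i > pseudo)
    )
    if control_depression_window == "by_reference_date":
        ok &= as_days(cohort["first_depression_date"]).astype(np.int64) <= pseudo
    return sorted(cohort.loc[ok, "patient_id"])


def sample_matched_sets(
    cases: pd.DataFrame,
    cohort: pd.DataFrame,
    deaths: pd.DataFrame,
    max_controls: int = 4,
    seed: int | np.random.Generator = 0,
    age_tolerance: int = 5,
    control_depression_window: str = "by_reference_date",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample matched sets for every case; drop and tally unmatchable cases.

    Controls are drawn uniformly without replacement within a set (the same
    member may serve in several sets).  Output is a long-form table with one
    case row and 1..max_controls control rows per set; membership and order
    are fully determined by (inputs, seed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _RiskSetIndex(cohort, deaths, age_tolerance, control_depression_window)
    entry_by_pid = pd.Series(
        as_days(cohort["entry_date"]).astype(np.int64),
        index=cohort["patient_id"],
    )

    ordered = cases.sort_values(
        ["outcome_date", "patient_id"], kind="mergesort"
    ).reset_index(drop=True)

    records: list[tuple] = []
    unmatched = 0
    for k, case in enumerate(ordered.itertuples(index=False)):
        rows = index.eligible_rows(case.patient_id, int(case.observation_days))
        if len(rows) == 0:
            unmatched += 1
            continue
        # sort candidate ids for a draw independent of cohort row order
        cand = np.sort(index.pid[rows].astype(str))
        m = min(max_controls, len(cand))
        chosen = rng.choice(cand, size=m, replace=False)
        set_id = f"S{k:06d}"
        records.append(
            (set_id, "case", case.patient_id,
             np.datetime64(case.outcome_date, "D").astype(np.int64),
             int(case.observation_days), case.cause_category)
        )
        for pid in sorted(chosen):
            pseudo = int(entry_by_pid.loc[pid]) + int(case.observation_days)
            records.append(
                (set_id, "control", pid, pseudo,
                 int(case.observation_days), case.cause_category)
            )
    sets = pd.DataFrame(records, columns=SET_COLUMNS)
    if len(sets):
        sets["reference_date"] = sets["reference_date"].to_numpy(np.int64).astype(
            "datetime64[D]"
        )
    tally = {
        "cases_total": len(ordered),
        "cases_unmatched": unmatched,
        "sets": len(ordered) - unmatched,
    }
    return sets, tally
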