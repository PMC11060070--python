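"""Antidepressant treatment episodes and exposure classification.

A treatment episode (drug era) is a maximal run of prescriptions of any
antidepressant agent in which each prescription starts no more than 60 days
after the expected end (date + duration) of the previous one.  The episode
length is the days between its first and last prescription plus the
duration of that last prescription, and the cumulative duration is the sum
over episodes.

Exposure over an observation window (entry_date, reference_date] is encoded
four ways, which must always agree on the exposed/unexposed split:
any-use, timing (recent = any prescription within 182 days of the reference
date; past = all prescriptions more than 182 days before), a cumulative-
duration band, and a distinct-agent count band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import as_days

DURATION_BANDS = ("none", "lt6m", "m6to12", "m13to24", "gt24m")
AGENT_BANDS = ("0", "1", "2", "3plus")
TIMINGS = ("none", "recent", "past")


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    first_rx_date: np.datetime64
    last_rx_date: np.datetime64
    last_rx_duration_days: int

    @property
    def episode_days(self) -> int:
        span = (self.last_rx_date - self.first_rx_date).astype(int)
        return int(span) + self.last_rx_duration_days


@dataclass(frozen=True)
class ExposureProfile:
    patient_id: str
    set_id: str
    any_antidepressant: bool
    timing: str
    cumulative_days: int
    duration_band: str
    n_agents_band: str

    def encodings_consistent(self) -> bool:
        exposed = self.any_antidepressant
        return (
            (self.timing != "none") == exposed
            and (self.duration_band != "none") == exposed
            and (self.n_agents_band != "0") == exposed
        )


def build_episodes(
    prescriptions: pd.DataFrame,
    gap_days: int = 60,
    default_duration_days: int = 28,
) -> list[TreatmentEpisode]:
    """Scan date-ordered prescriptions into treatment episodes.

    Input rows need ``patient_id``, ``date`` and ``duration_days`` columns
    (unsorted input is sorted internally; all agents are pooled).  A new
    episode opens when a prescription starts more than ``gap_days`` after
    the expected end of the previous one.
    """
    if not len(prescriptions):
        return []
    # ties on date are broken by duration so the scan is order-invariant
    rx = prescriptions.sort_values(["date", "duration_days"], kind="mergesort")
    dates = as_days(rx["date"])
    durations = (
        pd.to_numeric(rx["duration_days"], errors="coerce")
        .fillna(default_duration_days)
        .astype(int)
        .to_numpy()
    )
    pid = rx["patient_id"].iloc[0]

    episodes: list[TreatmentEpisode] = []
    start = 0
    for j in range(1, len(dates)):
        expected_end = dates[j - 1] + durations[j - 1]
        if (dates[j] - expected_end).astype(int) > gap_days:
            episodes.append(
                TreatmentEpisode(pid, dates[start], dates[j - 1], int(durations[j - 1]))
            )
            start = j
    episodes.append(TreatmentEpisode(pid, dates[start], dates[-1], int(durations[-1])))
    return episodes


def cumulative_duration(episodes: list[TreatmentEpisode]) -> int:
    """Total cumulative treatment duration in days across episodes."""
    return sum(ep.episode_days for ep in episodes)


def duration_band(cumulative_days: int) -> str:
    """Band the cumulative duration: 0, 1-182, 183-365, 366-730, >=731 days."""
    if cumulative_days < 0:
        raise ValueError(f"cumulative_days must be >= 0, got {cumulative_days}")
    if cumulative_days == 0:
        return "none"
    if cumulative_days <= 182:
        return "lt6m"
    if cumulative_days <= 365:
        return "m6to12"
    if cumulative_days <= 730:
        return "m13to24"
    return "gt24m"


def agent_band(n_agents: int) -> str:
    if n_agents <= 0:
        return "0"
    return str(n_agents) if n_agents < 3 else "3plus"


def classify_exposure(
    patient_rx: pd.DataFrame,
    entry_date,
    reference_date,
    set_id: str = "",
    recent_days: int = 182,
    gap_days: int = 60,
    default_duration_days: int = 28,
) -> ExposureProfile:
    """Classify one participant's antidepressant exposure over a window.

    Only prescriptions with ``drug_class == "antidepressant"`` and
    entry_date < date <= reference_date count: a prescription on the entry
    date itself is pre-entry history, one on the reference date is exposure.
    Agents are compared case-insensitively.
    """
    entry = np.datetime64(entry_date, "D")
    reference = np.datetime64(reference_date, "D")
    if reference < entry:
        raise ValueError(f"reference_date {reference} precedes entry_date {entry}")
    pid = str(patient_rx["patient_id"].iloc[0]) if len(patient_rx) else ""

    rx = patient_rx
    if "drug_class" in rx.columns:
        rx = rx[rx["drug_class"] == "antidepressant"]
    dates = as_days(rx["date"])
    in_window = (dates > entry) & (dates <= reference)
    rx = rx[in_window]

    if not len(rx):
        return ExposureProfile(pid, set_id, False, "none", 0, "none", "0")

    lag = (reference - as_days(rx["date"])).astype(int)
    timing = "recent" if bool((lag <= recent_days).any()) else "past"
    episodes = build_episodes(rx, gap_days, default_duration_days)
    cum = cumulative_duration(episodes)
    n_agents = rx["agent"].astype(str).str.casefold().nunique()
    return ExposureProfile(
        str(rx["patient_id"].iloc[0]),
        set_id,
        True,
        timing,
        cum,
        duration_band(cum),
        agent_band(n_agents),
    )


def classify_for_sets(
    sets: pd.DataFrame,
    prescriptions: pd.DataFrame,
    cohort: pd.DataFrame,
    recent_days: int = 182,
    gap_days: int = 60,
    default_duration_days: int = 28,
) -> pd.DataFrame:
    """Exposure profiles for every (set_id, participant) row of a set table.

    Vectorised equivalent of calling :func:`classify_exposure` per row; the
    two paths are held equal by the test suite.
    """
    entry_by_pid = pd.Series(
        as_days(cohort["entry_date"]).astype(np.int64), index=cohort["patient_id"]
    )
    ad = prescriptions[prescriptions["drug_class"] == "antidepressant"].sort_values(
        ["patient_id", "date", "duration_days"], kind="mergesort"
    )
    dur = (
        pd.to_numeric(ad["duration_days"], errors="coerce")
        .fillna(default_duration_days)
        .astype(np.int64)
        .to_numpy()
    )
    dates = as_days(ad["date"]).astype(np.int64)
    agent_code = ad["agent"].astype(str).str.casefold().astype("category").cat.codes.to_numpy()
    grouped: dict[str, tuple] = {}
    for pid, grp in ad.groupby("patient_id", sort=False).indices.items():
        grouped[pid] = (dates[grp], dur[grp], agent_code[grp])

    records = []
    for row in sets.itertuples(index=False):
        entry = int(entry_by_pid.loc[row.patient_id])
        reference = int(np.datetime64(row.reference_date, "D").astype(np.int64))
        d = du = ag = None
        if row.patient_id in grouped:
            d_all, du_all, ag_all = grouped[row.patient_id]
            keep = (d_all > entry) & (d_all <= reference)
            if keep.any():
                d, du, ag = d_all[keep], du_all[keep], ag_all[keep]
        if d is None:
            records.append((row.set_id, row.patient_id, row.role, 0, "none", 0, "none", "0"))
            continue
        timing = "recent" if (reference - d[-1]) <= recent_days else "past"
        if len(d) == 1:
            cum = int(du[0])
        else:
            breaks = np.flatnonzero(d[1:] - (d[:-1] + du[:-1]) > gap_days)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(d) - 1]))
            cum = int(np.sum(d[ends] - d[starts] + du[ends]))
        records.append(
            (
                row.set_id,
                row.patient_id,
                row.role,
                1,
                timing,
                cum,
                duration_band(cum),
                agent_band(int(len(np.unique(ag)))),
            )
        )
    return pd.DataFrame(
        records,
        columns=[
            "set_id",
            "patient_id",
            "role",
            "any_antidepressant",
            "timing",
            "cumulative_days",
            "duration_band",
            "n_agents_band",
        ],
    )
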