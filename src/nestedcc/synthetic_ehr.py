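"""Synthetic longitudinal EHR generator with known causal structure.

The generator emits the four raw tables (patients, prescriptions,
clinical_events, deaths) that the analysis pipeline consumes, under a
ground-truth proportional-hazards mortality model so that the estimand of
the downstream nested case-control analysis is the configured ``beta_ad``.

Randomness is organised as one RNG stream per generator stage, spawned
deterministically from the master seed.  Each stage draws a single uniform
matrix with one row per patient and maps columns through inverse CDFs
(normal, exponential, geometric, Poisson), so enlarging ``n_patients``
leaves the records of the first patients unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import poisson as _poisson

from .config import SimulationConfig
from .tables import (
    DEATH_COLUMNS,
    EVENT_COLUMNS,
    PATIENT_COLUMNS,
    PRESCRIPTION_COLUMNS,
    write_tables,
)


class SimulationError(RuntimeError):
    """The hazard model produced non-finite rates."""


_STAGES = {"population": 0, "prescriptions": 1, "events": 2, "mortality": 3, "pregnancy": 4}

_ETHNICITIES = ("white", "south_asian", "black", "mixed", "other_ethnicity")
_ETHNICITY_PROBS = (0.80, 0.08, 0.05, 0.03, 0.04)
_SMOKING = ("never", "ex", "current")
_SMOKING_PROBS = (0.45, 0.30, 0.25)


def _uniforms(config: SimulationConfig, stage: str, n: int, k: int) -> np.ndarray:
    """One (n, k) uniform draw per stage, clipped away from {0, 1}."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGES[stage],))
    u = np.random.default_rng(ss).random((n, k))
    return np.clip(u, 1e-12, 1 - 1e-12)


def _exponential(u: np.ndarray, scale) -> np.ndarray:
    return -scale * np.log1p(-u)


def _geometric(u: np.ndarray, p: float) -> np.ndarray:
    return np.maximum(np.ceil(np.log1p(-u) / np.log1p(-p)), 1).astype(np.int64)


def _poisson_ppf(u: np.ndarray, lam: float) -> np.ndarray:
    return _poisson.ppf(u, lam).astype(np.int64)


def _d2i(dates) -> np.ndarray:
    """datetime64 -> int64 days since epoch."""
    return np.asarray(dates, dtype="datetime64[D]").astype(np.int64)


def _i2d(days) -> np.ndarray:
    return np.asarray(np.round(days), dtype=np.int64).astype("datetime64[D]")


def _categorical(u: np.ndarray, categories, probs) -> np.ndarray:
    cut = np.cumsum(probs)
    cut[-1] = 1.0 + 1e-12
    return np.asarray(categories, dtype=object)[np.searchsorted(cut, u, side="right")]


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Draw the patient table: demographics, registration windows, severity."""
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(columns=PATIENT_COLUMNS)
    U = _uniforms(config, "population", n, 8)

    u_gender = U[:, 0]
    z_yob = ndtri(U[:, 1])
    practice = np.floor(U[:, 2] * config.effective_n_practices).astype(np.int64)
    u_reg = U[:, 3]
    reg_years = config.registration_years_min + _exponential(
        U[:, 4],
        max(config.registration_years_mean - config.registration_years_min, 0.1),
    )
    u_eth = U[:, 5:7]
    severity = ndtri(U[:, 7])

    gender = np.where(u_gender < config.p_female, "female", "male")
    yob = np.clip(np.round(1950 + 12 * z_yob), 1920, 1990).astype(np.int64)

    reg_lo = _d2i(np.datetime64(config.registration_start_min, "D"))
    reg_hi = _d2i(np.datetime64(config.registration_start_max, "D"))
    reg_start = reg_lo + np.floor(u_reg * (reg_hi - reg_lo + 1)).astype(np.int64)
    reg_end = reg_start + np.maximum(np.round(reg_years * 365.25), 1).astype(np.int64)

    ethnicity = _categorical(u_eth[:, 0], _ETHNICITIES, _ETHNICITY_PROBS)
    ethnicity = np.where(u_eth[:, 1] < config.p_missing_ethnicity, "", ethnicity)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "gender": gender,
            "year_of_birth": yob,
            "practice_id": [f"G{j:03d}" for j in practice],
            "registration_start": _i2d(reg_start),
            "registration_end": _i2d(reg_end),
            "ethnicity": ethnicity,
            "latent_severity": severity,
        }
    )


# ---------------------------------------------------------------------------
# pregnancy intervals (shared between prescriptions and events stages)
# ---------------------------------------------------------------------------

def _pregnancy_intervals(patients: pd.DataFrame, config: SimulationConfig):
    n = len(patients)
    U = _uniforms(config, "pregnancy", n, 2)
    u_has = U[:, 0]
    u_start = U[:, 1]

    reg_start = _d2i(patients["registration_start"])
    reg_end = _d2i(patients["registration_end"])
    eligible = (
        (patients["gender"].to_numpy() == "female")
        & (patients["year_of_birth"].to_numpy() >= 1970)
        & (reg_end - reg_start >= 183 + 270 + 30)
    )
    has = eligible & (u_has < config.p_pregnancy)
    span = np.maximum(reg_end - reg_start - 270, 1)
    start = reg_start + 183 + np.floor(u_start * np.maximum(span - 183, 1)).astype(np.int64)
    start = np.minimum(start, reg_end - 270)
    end = start + 270
    return has, start, end


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

def _expand_runs(idx, start_days, counts, step):
    """Expand per-row arithmetic date runs into flat (row, date) arrays."""
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rows = np.repeat(idx, counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    dates = np.repeat(start_days, counts) + offsets * step
    return rows, dates


def generate_prescriptions(
    patients: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Emit oral antidiabetics, insulin, antidepressant courses and other drugs.

    Treated T2DM patients get a first oral antidiabetic at a random date at
    least 183 days after registration, with refills until the end of their
    window.  Antidepressant courses arrive as a renewal process whose start
    rate is ``ad_course_rate * exp(severity_link * latent_severity)``; each
    course is a run of prescriptions of the configured duration.
    """
    n = len(patients)
    if n == 0:
        return pd.DataFrame(columns=PRESCRIPTION_COLUMNS)
    C = config.max_courses
    dur = config.rx_duration_days
    U = _uniforms(config, "prescriptions", n, 39 + 3 * C)

    u_t2dm = U[:, 0]
    u_first = U[:, 1]
    u_ins_early = U[:, 2]
    u_ins_late = U[:, 3]
    u_ins_pos = U[:, 4]
    u_gest = U[:, 5]
    gaps = _exponential(U[:, 6 : 6 + C], 1.0)
    course_nrx = _geometric(U[:, 6 + C : 6 + 2 * C], 1.0 / config.course_rx_mean)
    course_agent = np.floor(U[:, 6 + 2 * C : 6 + 3 * C] * len(config.ad_agents)).astype(
        np.int64
    )
    base = 6 + 3 * C
    n_other = np.minimum(_poisson_ppf(U[:, base], 2.0), 30)
    u_other = U[:, base + 1 : base + 31]
    u_pre_ad = U[:, base + 31]
    u_pre_off = U[:, base + 32]

    reg_start = _d2i(patients["registration_start"])
    reg_end = _d2i(patients["registration_end"])
    study_end = _d2i(np.datetime64(config.study_end, "D"))
    severity = patients["latent_severity"].to_numpy(dtype=float)

    lo = reg_start + 183
    hi = np.minimum(reg_end, study_end)
    feasible = hi >= lo
    treated = (u_t2dm < config.p_t2dm) & feasible
    first_oad = lo + np.floor(u_first * np.maximum(hi - lo + 1, 1)).astype(np.int64)

    # gestational-only subset: all antidiabetic prescribing inside pregnancy
    has_preg, preg_start, preg_end = _pregnancy_intervals(patients, config)
    gest = (
        treated
        & has_preg
        & (u_gest < config.p_gestational_only)
        & (preg_start >= lo)
        & (preg_end <= hi)
    )
    first_oad = np.where(
        gest, preg_start + np.floor(u_first * 180).astype(np.int64), first_oad
    )
    oad_end = np.where(gest, preg_end, hi)

    rows: list[np.ndarray] = []
    dates: list[np.ndarray] = []
    classes: list[np.ndarray] = []
    agents: list[np.ndarray] = []

    # oral antidiabetic refills
    idx = np.where(treated)[0]
    counts = np.minimum(
        (oad_end[idx] - first_oad[idx]) // config.oad_refill_days + 1, 120
    )
    r, d = _expand_runs(idx, first_oad[idx], counts, config.oad_refill_days)
    rows.append(r)
    dates.append(d)
    classes.append(np.repeat("oral_antidiabetic", len(r)))
    agents.append(np.repeat("metformin", len(r)))

    # insulin
    early = treated & ~gest & (u_ins_early < config.p_insulin_early)
    late = treated & ~gest & ~early & (u_ins_late < config.p_insulin_late)
    ins_date = np.where(
        early,
        first_oad + 30 + np.floor(u_ins_pos * 152).astype(np.int64),
        first_oad + 183 + np.floor(u_ins_pos * 1817).astype(np.int64),
    )
    ins_ok = (early | late) & (ins_date <= hi)
    idx = np.where(ins_ok)[0]
    rows.append(idx)
    dates.append(ins_date[idx])
    classes.append(np.repeat("insulin", len(idx)))
    agents.append(np.repeat("insulin", len(idx)))

    # antidepressant courses (renewal process after the treatment clock start)
    clock = np.where(treated, first_oad, lo)
    with np.errstate(over="ignore"):
        rate = config.ad_course_rate * np.exp(config.severity_link * severity)
    scale = np.where(rate > 0, 1.0 / np.maximum(rate, 1e-300), np.inf)
    course_len = course_nrx * dur
    starts = np.empty((n, C), dtype=float)
    starts[:, 0] = clock + 1 + gaps[:, 0] * scale
    for c in range(1, C):
        starts[:, c] = starts[:, c - 1] + course_len[:, c - 1] + gaps[:, c] * scale
    valid = feasible[:, None] & (starts <= hi[:, None]) & (rate[:, None] > 0)

    agent_names = np.asarray(config.ad_agents, dtype=object)
    for c in range(C):
        idx = np.where(valid[:, c])[0]
        if len(idx) == 0:
            continue
        start = np.round(starts[idx, c]).astype(np.int64)
        start = np.minimum(start, hi[idx])
        k_max = np.minimum(course_nrx[idx, c], (hi[idx] - start) // dur + 1)
        r, d = _expand_runs(idx, start, k_max, dur)
        rows.append(r)
        dates.append(d)
        classes.append(np.repeat("antidepressant", len(r)))
        agents.append(np.repeat(agent_names[course_agent[idx, c]], k_max))

    # optional pre-entry antidepressant history
    if config.p_pre_entry_ad > 0:
        pre = treated & (u_pre_ad < config.p_pre_entry_ad)
        pre_date = first_oad - 1 - np.floor(u_pre_off * 300).astype(np.int64)
        pre &= pre_date >= reg_start
        idx = np.where(pre)[0]
        rows.append(idx)
        dates.append(pre_date[idx])
        classes.append(np.repeat("antidepressant", len(idx)))
        agents.append(agent_names[course_agent[idx, 0]])

    # unrelated prescribing (feeds the polypharmacy confounder)
    span = np.maximum(hi - reg_start, 1)
    mask = np.arange(30)[None, :] < n_other[:, None]
    r_idx, c_idx = np.where(mask & feasible[:, None])
    rows.append(r_idx)
    dates.append(reg_start[r_idx] + np.floor(u_other[r_idx, c_idx] * span[r_idx]).astype(np.int64))
    classes.append(np.repeat("other", len(r_idx)))
    agents.append(np.repeat("other", len(r_idx)))

    row = np.concatenate(rows)
    date = np.concatenate(dates)
    pid = patients["patient_id"].to_numpy(dtype=object)[row]
    df = pd.DataFrame(
        {
            "patient_id": pid,
            "date": _i2d(date),
            "drug_class": np.concatenate(classes),
            "agent": np.concatenate(agents),
            "duration_days": np.full(len(row), dur, dtype=np.int64),
        }
    )
    df = df.sort_values(
        ["patient_id", "date", "drug_class", "agent"], kind="mergesort"
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# clinical events
# ---------------------------------------------------------------------------

def _fmt(values: np.ndarray) -> np.ndarray:
    return np.asarray([f"{v:.3f}" for v in values], dtype=object)


def generate_clinical_events(
    patients: pd.DataFrame, prescriptions: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Emit depression codes, glucose tests, BMI, smoking, comorbidities.

    Treated T2DM patients (those with an oral antidiabetic) are guaranteed
    two above-threshold glucose tests before their first prescription, and
    receive post-entry depression codes with probability ``p_depression``.
    The ``value`` column is a string: formatted numbers for measurements,
    category labels for smoking, empty otherwise.
    """
    n = len(patients)
    if n == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    n_ctx = len(config.p_context_depression) * 2
    n_com = len(config.p_comorbidity) * 2
    U = _uniforms(config, "events", n, 22 + n_ctx + n_com)

    gl_off = 30 + np.floor(U[:, 0:2] * 336).astype(np.int64)
    gl_val = U[:, 2:4]
    u_norm_gl = U[:, 4:6]
    u_dep = U[:, 6]
    dep_first = 1 + _exponential(U[:, 7], 180.0)
    dep_extra = np.minimum(_poisson_ppf(U[:, 8], 1.5), 6)
    dep_gaps = _exponential(U[:, 9:15], 365.0)
    u_pre_dep = U[:, 15:17]
    u_bmi = U[:, 17:19]
    z_bmi = ndtri(U[:, 19])
    u_smoke = U[:, 20:22]
    u_ctx = U[:, 22 : 22 + n_ctx]
    u_com = U[:, 22 + n_ctx : 22 + n_ctx + n_com]

    pid = patients["patient_id"].to_numpy(dtype=object)
    reg_start = _d2i(patients["registration_start"])
    reg_end = _d2i(patients["registration_end"])
    study_end = _d2i(np.datetime64(config.study_end, "D"))
    hi = np.minimum(reg_end, study_end)
    span = np.maximum(hi - reg_start, 1)

    oad = prescriptions[prescriptions["drug_class"] == "oral_antidiabetic"]
    first_oad = oad.groupby("patient_id")["date"].min()
    entry = np.full(n, -1, dtype=np.int64)
    order = pd.Series(np.arange(n), index=pid)
    pos = order.reindex(first_oad.index).to_numpy()
    entry[pos] = _d2i(first_oad.to_numpy())
    treated = entry >= 0

    rows: list[np.ndarray] = []
    dates: list[np.ndarray] = []
    cats: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def emit(idx, date, category, value):
        rows.append(idx)
        dates.append(date)
        cats.append(
            np.repeat(category, len(idx)) if isinstance(category, str) else category
        )
        vals.append(
            np.repeat(value, len(idx)) if isinstance(value, str) else value
        )

    # two above-threshold glucose tests before entry (T2DM confirmation)
    idx = np.where(treated)[0]
    for j in range(2):
        date = np.maximum(entry[idx] - gl_off[idx, j], reg_start[idx])
        value = config.glucose_threshold + 0.1 + gl_val[idx, j] * 8.0
        emit(idx, date, "glucose_test", _fmt(value))

    # occasional normal-range tests for everyone
    idx = np.where(u_norm_gl[:, 0] < 0.3)[0]
    date = reg_start[idx] + np.floor(u_norm_gl[idx, 1] * span[idx]).astype(np.int64)
    emit(idx, date, "glucose_test", _fmt(4.0 + u_norm_gl[idx, 1] * 3.0))

    # qualifying depression codes, strictly after entry
    has_dep = treated & (u_dep < config.p_depression)
    code_day = np.empty((n, 7), dtype=float)
    code_day[:, 0] = entry + dep_first
    for j in range(6):
        code_day[:, j + 1] = code_day[:, j] + 1 + dep_gaps[:, j]
    keep = has_dep[:, None] & (code_day <= hi[:, None])
    keep[:, 1:] &= np.arange(6)[None, :] < dep_extra[:, None]
    r_idx, c_idx = np.where(keep)
    emit(r_idx, np.round(code_day[r_idx, c_idx]).astype(np.int64), "depression", "")

    # pre-entry depression history (does not qualify for cohort membership)
    idx = np.where(treated & (u_pre_dep[:, 0] < config.p_pre_entry_depression))[0]
    date = np.maximum(
        entry[idx] - 1 - np.floor(u_pre_dep[idx, 1] * 1000).astype(np.int64),
        reg_start[idx],
    )
    emit(idx, date, "depression", "")

    # context-specific depression codes (dementia / maternity / SMI)
    for k, (name, p) in enumerate(sorted(config.p_context_depression.items())):
        idx = np.where(u_ctx[:, 2 * k] < p)[0]
        date = reg_start[idx] + np.floor(u_ctx[idx, 2 * k + 1] * span[idx]).astype(np.int64)
        label = {"dementia": "depression_dementia_context",
                 "maternity": "depression_maternity_context",
                 "smi": "depression_smi_context"}[name]
        emit(idx, date, label, "")

    # BMI around entry, with missingness
    anchor = np.where(treated, entry, reg_start + 200)
    idx = np.where(u_bmi[:, 0] >= config.p_missing_bmi)[0]
    date = np.maximum(anchor[idx] - np.floor(u_bmi[idx, 1] * 90).astype(np.int64),
                      reg_start[idx])
    emit(idx, date, "bmi", _fmt(np.clip(31.0 + 5.0 * z_bmi[idx], 16.0, 55.0)))

    # smoking status at entry
    idx = np.arange(n)
    date = np.maximum(anchor - np.floor(u_smoke[:, 1] * 90).astype(np.int64), reg_start)
    emit(idx, date, "smoking_status",
         _categorical(u_smoke[:, 0], _SMOKING, _SMOKING_PROBS))

    # comorbidity codes shortly after registration
    for k, (name, p) in enumerate(sorted(config.p_comorbidity.items())):
        idx = np.where(u_com[:, 2 * k] < p)[0]
        date = reg_start[idx] + np.floor(u_com[idx, 2 * k + 1] * 90).astype(np.int64)
        emit(idx, date, f"comorbidity:{name}", "")

    # pregnancy intervals
    has_preg, preg_start, preg_end = _pregnancy_intervals(patients, config)
    idx = np.where(has_preg)[0]
    emit(idx, preg_start[idx], "pregnancy_start", "")
    emit(idx, preg_end[idx], "pregnancy_end", "")

    row = np.concatenate(rows)
    df = pd.DataFrame(
        {
            "patient_id": pid[row],
            "date": _i2d(np.concatenate(dates)),
            "code_category": np.concatenate(cats),
            "value": np.concatenate(vals),
        }
    )
    df = df.sort_values(
        ["patient_id", "date", "code_category", "value"], kind="mergesort"
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def generate_mortality(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: SimulationConfig,
    clinical_events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw death dates from the piecewise-constant proportional-hazards model.

    The hazard clock starts at registration; the rate multiplies by
    ``exp(beta_ad)`` at the first antidepressant prescription.  Deaths after
    the end of registration or the study period are administratively
    censored (no record emitted).  Comorbidity covariates are read from
    ``clinical_events`` when provided; ``generate_ehr`` always provides them.
    """
    n = len(patients)
    if n == 0:
        return pd.DataFrame(columns=DEATH_COLUMNS)
    U = _uniforms(config, "mortality", n, 2)
    e_wait = _exponential(U[:, 0], 1.0)
    u_cause = U[:, 1]

    pid = patients["patient_id"].to_numpy(dtype=object)
    reg_start = _d2i(patients["registration_start"])
    reg_end = _d2i(patients["registration_end"])
    study_end = _d2i(np.datetime64(config.study_end, "D"))
    severity = patients["latent_severity"].to_numpy(dtype=float)
    yob = patients["year_of_birth"].to_numpy(dtype=np.int64)
    age_ref = (reg_start.astype("datetime64[D]").astype("datetime64[Y]").astype(int)
               + 1970 - yob)

    lp = config.severity_link * severity + config.beta_age * (age_ref - 65.0)
    if clinical_events is not None and len(clinical_events):
        order = pd.Series(np.arange(n), index=pid)
        for name, beta in config.beta_confounders.items():
            ev = clinical_events[clinical_events["code_category"] == f"comorbidity:{name}"]
            flag = np.zeros(n)
            if len(ev):
                pos = order.reindex(ev["patient_id"].unique()).dropna().to_numpy(int)
                flag[pos] = 1.0
            lp += beta * flag

    with np.errstate(over="raise"):
        try:
            r0 = config.baseline_hazard * np.exp(lp)
            r1 = r0 * np.exp(config.beta_ad)
        except FloatingPointError as exc:
            raise SimulationError("non-finite hazard in mortality model") from exc
    if not (np.all(np.isfinite(r0)) and np.all(np.isfinite(r1))):
        raise SimulationError("non-finite hazard in mortality model")
    if config.baseline_hazard == 0:
        return pd.DataFrame(columns=DEATH_COLUMNS)

    ad = prescriptions[prescriptions["drug_class"] == "antidepressant"]
    first_ad = ad.groupby("patient_id")["date"].min()
    t_ad = np.full(n, np.inf)
    if len(first_ad):
        order = pd.Series(np.arange(n), index=pid)
        pos = order.reindex(first_ad.index).to_numpy(int)
        t_ad[pos] = _d2i(first_ad.to_numpy()) - reg_start[pos]

    # sequential exponential waiting across the exposure change point
    t_death = np.where(
        e_wait <= r0 * t_ad,
        e_wait / r0,
        t_ad + (e_wait - r0 * np.where(np.isfinite(t_ad), t_ad, 0.0)) / r1,
    )
    death_day = reg_start + np.floor(t_death).astype(np.int64) + 1
    observed = death_day <= np.minimum(reg_end, study_end)

    causes = list(config.cause_probs)
    cause = _categorical(u_cause, causes, [config.cause_probs[c] for c in causes])

    idx = np.where(observed)[0]
    df = pd.DataFrame(
        {
            "patient_id": pid[idx],
            "death_date": _i2d(death_day[idx]),
            "cause_category": cause[idx],
        }
    )
    return df.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_ehr(
    config: SimulationConfig, out_dir=None
) -> dict[str, pd.DataFrame]:
    """Generate all four tables; optionally write them to ``out_dir``.

    Prescriptions and clinical events dated after a patient's death are
    dropped: records cannot postdate death.  The death time itself is drawn
    from the pre-truncation antidepressant schedule, which is equivalent
    because a first prescription after death implies death occurred in the
    unexposed state.
    """
    patients = generate_population(config)
    prescriptions = generate_prescriptions(patients, config)
    events = generate_clinical_events(patients, prescriptions, config)
    deaths = generate_mortality(patients, prescriptions, config, clinical_events=events)

    death_map = deaths.set_index("patient_id")["death_date"] if len(deaths) else None

    def truncate(df: pd.DataFrame, date_col: str) -> pd.DataFrame:
        if death_map is None or not len(df):
            return df.reset_index(drop=True)
        limit = death_map.reindex(df["patient_id"]).to_numpy()
        keep = pd.isna(limit) | (df[date_col].to_numpy() <= limit)
        return df[keep].reset_index(drop=True)

    prescriptions = truncate(prescriptions, "date")
    events = truncate(events, "date")

    tables = {
        "patients": patients,
        "prescriptions": prescriptions,
        "clinical_events": events,
        "deaths": deaths,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            write_tables(tables, out_dir)
        except OSError as exc:
            raise OSError(f"cannot write tables to {out_dir}: {exc}") from exc
        config.to_file(out_dir / "config.txt")
    return tables
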