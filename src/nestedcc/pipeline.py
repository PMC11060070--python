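"""End-to-end orchestration: cohort -> sampling -> exposure -> fits -> reports.

``run`` executes the whole nested case-control analysis on the four raw
tables: it phenotypes the cohort, extracts cases, samples matched controls
by incidence density, classifies antidepressant exposure over each matched
observation window, and fits univariable and confounder-adjusted
conditional-logit models for the requested exposure contrasts and causes of
death, plus optional complete-case sensitivity re-runs.  All outputs are
plain text and byte-identical under a fixed (config, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .clogit import (
    EstimationError,
    design_from_long,
    fit,
    irr_table,
    render_irr_table,
)
from .cohort import CohortParams, build_cohort, exclusion_report
from .config import CAUSE_CATEGORIES, AnalysisConfig
from .exposure import classify_for_sets
from .sampling import extract_cases, sample_matched_sets
from .tables import read_tables

logger = logging.getLogger("nestedcc")

NAMED_CAUSES = ("endocrine", "cardiovascular", "cancer", "respiratory", "unnatural")

CONTRAST_COLUMNS = {
    "any": ["any_antidepressant"],
    "timing": ["timing_recent", "timing_past"],
    "duration_band": [
        "duration_band_lt6m",
        "duration_band_m6to12",
        "duration_band_m13to24",
        "duration_band_gt24m",
    ],
    "n_agents": ["n_agents_1", "n_agents_2", "n_agents_3plus"],
}


def cause_distribution(cases: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of cases by cause of death.

    Causes outside the five named categories are pooled as "other" (such
    cases are excluded from cause-specific analyses but remain in the
    all-cause analysis).  Percentages are rounded to two decimals.
    """
    if not len(cases):
        return pd.DataFrame(columns=["cause", "count", "percentage"])
    cause = cases["cause_category"].where(
        cases["cause_category"].isin(NAMED_CAUSES), "other"
    )
    total = len(cases)
    counts = cause.value_counts()
    rows = [
        (c, int(counts.get(c, 0)), round(100.0 * counts.get(c, 0) / total, 2))
        for c in CAUSE_CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["cause", "count", "percentage"])


def cause_specific_design(sets: pd.DataFrame, cause: str) -> pd.DataFrame:
    """Sets whose case died of ``cause``; controls travel with their case."""
    case_rows = sets[(sets["role"] == "case")]
    if cause == "other":
        wanted = case_rows[~case_rows["cause_category"].isin(NAMED_CAUSES)]
    else:
        wanted = case_rows[case_rows["cause_category"] == cause]
    return sets[sets["set_id"].isin(wanted["set_id"])].reset_index(drop=True)


def _expand_exposure(expo: pd.DataFrame) -> pd.DataFrame:
    out = expo.copy()
    out["timing_recent"] = (out["timing"] == "recent").astype(int)
    out["timing_past"] = (out["timing"] == "past").astype(int)
    for band in ("lt6m", "m6to12", "m13to24", "gt24m"):
        out[f"duration_band_{band}"] = (out["duration_band"] == band).astype(int)
    for band in ("1", "2", "3plus"):
        out[f"n_agents_{band}"] = (out["n_agents_band"] == band).astype(int)
    return out


def _fit_pair(long_df, contrast, adjust):
    cols = CONTRAST_COLUMNS[contrast]
    out = []
    for covs in (cols, cols + [c for c in adjust if c in long_df.columns]):
        try:
            out.append(fit(design_from_long(long_df, covs)))
        except EstimationError:
            out.append(None)
    return tuple(out)


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    cohort: pd.DataFrame
    exclusion_tally: dict
    cases: pd.DataFrame
    sets: pd.DataFrame
    sampling_tally: dict
    exposure: pd.DataFrame
    cause_table: pd.DataFrame
    fits: dict = dc_field(default_factory=dict)  # (cause, contrast) -> (uni, multi)
    irr_tables: dict = dc_field(default_factory=dict)  # cause -> DataFrame
    sensitivity: dict = dc_field(default_factory=dict)  # name -> DataFrame
    log_lines: list = dc_field(default_factory=list)


def _analyse(tables, config: AnalysisConfig, log) -> tuple:
    params = CohortParams(
        glucose_threshold=config.glucose_threshold,
        min_registration_lead_days=config.min_registration_lead_days,
        t1dm_insulin_window_days=config.t1dm_insulin_window_days,
        age_min=config.age_min,
        depression_rule=config.depression_rule,
        study_end=config.study_end,
        contacts_window_days=config.contacts_window_days,
        polypharmacy_window_days=config.polypharmacy_window_days,
        seed=config.seed,
    )
    cohort, tally = build_cohort(
        tables["patients"],
        tables["prescriptions"],
        tables["clinical_events"],
        tables["deaths"],
        params,
    )
    log(f"cohort: {len(cohort)} members")
    cases = extract_cases(cohort, tables["deaths"])
    log(f"cases: {len(cases)}")
    sets, stally = sample_matched_sets(
        cases,
        cohort,
        tables["deaths"],
        max_controls=config.max_controls,
        seed=config.seed,
        age_tolerance=config.age_match_tolerance,
        control_depression_window=config.control_depression_window,
    )
    log(f"matched sets: {stally['sets']} (unmatched cases: {stally['cases_unmatched']})")
    expo = classify_for_sets(
        sets,
        tables["prescriptions"],
        cohort,
        recent_days=config.recent_days,
        gap_days=config.episode_gap_days,
        default_duration_days=config.default_rx_duration_days,
    )
    long_df = _expand_exposure(expo).merge(
        cohort.drop(columns=["entry_date", "censor_date"]), on="patient_id", how="left"
    )
    return cohort, tally, cases, sets, stally, expo, long_df


def run(
    config: AnalysisConfig,
    tables: dict[str, pd.DataFrame] | None = None,
    out_dir=None,
) -> AnalysisReport:
    """Execute the full analysis; optionally write plain-text reports."""
    if tables is None:
        tables = read_tables(config.tables_dir)
    log_lines: list[str] = []

    def log(msg: str, stage: str = "pipeline") -> None:
        line = f"[{stage}] {msg}"
        log_lines.append(line)
        logger.info(line)

    log(f"seed: {config.seed}")
    log(f"config hash: {_config_hash(config)}")
    for name, df in tables.items():
        log(f"input rows — {name}: {len(df)}")

    cohort, tally, cases, sets, stally, expo, long_df = _analyse(tables, config, log)

    report = AnalysisReport(
        config=config,
        cohort=cohort,
        exclusion_tally=tally,
        cases=cases,
        sets=sets,
        sampling_tally=stally,
        exposure=expo,
        cause_table=cause_distribution(cases),
        log_lines=log_lines,
    )

    for cause in config.causes:
        cause_sets = sets if cause == "all" else cause_specific_design(sets, cause)
        sub = long_df[long_df["set_id"].isin(cause_sets["set_id"])]
        pairs, labels = [], []
        for contrast in config.contrasts:
            if not len(sub):
                report.fits[(cause, contrast)] = (None, None)
                continue
            pair = _fit_pair(sub, contrast, list(config.adjust))
            report.fits[(cause, contrast)] = pair
            pairs.append(pair)
            labels.append(contrast)
        if pairs:
            report.irr_tables[cause] = irr_table(pairs, labels)
        log(f"fitted cause={cause}: {len(pairs)} contrasts")

    for name, flag, column in (
        ("complete_case_ethnicity", config.complete_case_ethnicity, "ethnicity_missing"),
        ("complete_case_bmi", config.complete_case_bmi, "bmi_missing"),
    ):
        if not flag:
            continue
        table = _sensitivity_run(tables, config, cohort, column, log)
        report.sensitivity[name] = table

    if out_dir is not None:
        _write_reports(report, out_dir)
    return report


def _sensitivity_run(tables, config: AnalysisConfig, cohort, missing_col: str, log):
    """Re-run matching and the any-antidepressant fit on the complete-case cohort."""
    keep = cohort.loc[cohort[missing_col] == 0, "patient_id"]
    restricted = cohort[cohort["patient_id"].isin(keep)].reset_index(drop=True)
    cases2 = extract_cases(restricted, tables["deaths"])
    sets2, _ = sample_matched_sets(
        cases2,
        restricted,
        tables["deaths"],
        max_controls=config.max_controls,
        seed=config.seed,
        age_tolerance=config.age_match_tolerance,
        control_depression_window=config.control_depression_window,
    )
    expo2 = classify_for_sets(
        sets2,
        tables["prescriptions"],
        restricted,
        recent_days=config.recent_days,
        gap_days=config.episode_gap_days,
        default_duration_days=config.default_rx_duration_days,
    )
    long2 = _expand_exposure(expo2).merge(
        restricted.drop(columns=["entry_date", "censor_date"]),
        on="patient_id",
        how="left",
    )
    pair = _fit_pair(long2, "any", list(config.adjust))
    log(f"sensitivity {missing_col}: {len(sets2[sets2['role'] == 'case'])} sets")
    return irr_table([pair], ["any"])


def baseline_table(report: AnalysisReport) -> pd.DataFrame:
    """Baseline characteristics of included individuals, by case/control role."""
    merged = report.sets.merge(report.cohort, on="patient_id", how="left")
    rows = []
    for role in ("case", "control"):
        grp = merged[merged["role"] == role].drop_duplicates("patient_id")
        if not len(grp):
            continue
        q = grp["age_at_entry"].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "role": role,
                "n": len(grp),
                "age_median_iqr": f"{q[0.5]:.0f} ({q[0.25]:.0f}–{q[0.75]:.0f})",
                "female_pct": round(100 * (grp["gender"] == "female").mean(), 2),
                "nonwhite_pct": round(100 * grp["ethnicity_nonwhite"].mean(), 2),
                "bmi_mean": round(grp["bmi"].mean(), 2),
                "current_smoker_pct": round(100 * grp["smoking_current"].mean(), 2),
                "ad_history_pct": round(100 * grp["ad_history_preentry"].mean(), 2),
            }
        )
        for col in sorted(c for c in grp.columns if c.startswith("comorbidity_")):
            rows[-1][f"{col}_pct"] = round(100 * grp[col].mean(), 2)
    return pd.DataFrame(rows)


def _config_hash(config: AnalysisConfig) -> str:
    from .config import _flatten

    text = "\n".join(f"{k}={v}" for k, v in sorted(_flatten(config).items()))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_reports(report: AnalysisReport, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "exclusions.txt").write_text(exclusion_report(report.exclusion_tally))
    report.cause_table.to_csv(out_dir / "cause_distribution.csv", index=False)
    baseline_table(report).to_csv(out_dir / "baseline.csv", index=False)
    chunks = []
    for cause, table in report.irr_tables.items():
        chunks.append(f"== cause: {cause} ==\n{render_irr_table(table)}")
    (out_dir / "irr_tables.txt").write_text("\n".join(chunks) or "no fits\n")
    if report.sensitivity:
        chunks = [
            f"== {name} ==\n{render_irr_table(tab)}"
            for name, tab in report.sensitivity.items()
        ]
        (out_dir / "sensitivity.txt").write_text("\n".join(chunks))
    (out_dir / "run_log.txt").write_text("\n".join(report.log_lines) + "\n")
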