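"""Configuration objects for the simulation and the analysis pipeline.

Both configs round-trip through flat ``key = value`` text files.  Nested
mappings (for example the per-confounder log hazard ratios) are flattened
with dotted keys (``beta_confounders.cvd = 0.5``); sequences are
comma-separated.  All calendar dates are ISO-8601 strings; date arithmetic
elsewhere in the package is done in integer days.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ConfigurationError(ValueError):
    """An invalid configuration field; the message names the field."""


CAUSE_CATEGORIES = (
    "endocrine",
    "cardiovascular",
    "cancer",
    "respiratory",
    "unnatural",
    "other",
)

#: Default probability of each primary cause of death.  The named-cause
#: fractions follow the observed case distribution in UK primary-care
#: patients with comorbid depression and type 2 diabetes; the remainder is
#: pooled as "other".
DEFAULT_CAUSE_PROBS = {
    "endocrine": 0.0396,
    "cardiovascular": 0.3131,
    "cancer": 0.2823,
    "respiratory": 0.1511,
    "unnatural": 0.0262,
    "other": 0.1877,
}

DEFAULT_AGENTS = (
    "citalopram",
    "sertraline",
    "fluoxetine",
    "mirtazapine",
    "amitriptyline",
    "venlafaxine",
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_date(name: str, value: str) -> np.datetime64:
    try:
        return np.datetime64(value, "D")
    except ValueError as exc:
        raise ConfigurationError(f"{name} is not an ISO-8601 date: {value!r}") from exc


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic EHR generator.

    The mortality model is piecewise-constant proportional hazards:

        h(t) = baseline_hazard * exp(beta_ad * AD_active(t)
                                     + sum_c beta_confounders[c] * x_c
                                     + beta_age * (age - 65)
                                     + severity_link * latent_severity)

    where ``AD_active(t)`` steps from 0 to 1 at the first antidepressant
    prescription.  ``severity_link`` couples a latent depression-severity
    variable to *both* the antidepressant course start rate and the death
    hazard; it is the confounding-by-indication knob.
    """

    n_patients: int = 5000
    seed: int = 0
    study_start: str = "2000-01-01"
    study_end: str = "2018-12-31"
    # Registration start dates are drawn from this window; it may precede
    # the study start, because pre-study records feed cohort selection.
    registration_start_min: str = "1995-01-01"
    registration_start_max: str = "2012-12-31"
    registration_years_mean: float = 12.0
    registration_years_min: float = 2.0
    n_practices: int = 0  # 0 -> max(2, n_patients // 500)
    p_female: float = 0.5
    p_t2dm: float = 0.6
    p_depression: float = 0.75
    baseline_hazard: float = 5e-5  # deaths per person-day
    beta_ad: float = math.log(2.0)
    beta_confounders: dict[str, float] = field(
        default_factory=lambda: {"cvd": 0.5, "copd": 0.4}
    )
    p_comorbidity: dict[str, float] = field(
        default_factory=lambda: {"cvd": 0.30, "copd": 0.15}
    )
    beta_age: float = 0.05  # per year of age over 65
    severity_link: float = 0.0
    cause_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_PROBS)
    )
    rx_duration_days: int = 28
    ad_course_rate: float = 2.0e-4  # course starts per person-day
    ad_agents: tuple[str, ...] = DEFAULT_AGENTS
    max_courses: int = 6
    course_rx_mean: float = 5.0  # mean prescriptions per course (geometric)
    p_pre_entry_ad: float = 0.0
    oad_refill_days: int = 90
    p_insulin_early: float = 0.03  # insulin <183 d after first oral agent
    p_insulin_late: float = 0.12
    p_pregnancy: float = 0.10  # women born 1970+
    p_gestational_only: float = 0.02  # antidiabetics only during pregnancy
    p_context_depression: dict[str, float] = field(
        default_factory=lambda: {"dementia": 0.03, "maternity": 0.02, "smi": 0.02}
    )
    p_pre_entry_depression: float = 0.30
    glucose_threshold: float = 11.1  # mmol/L, random plasma glucose cut-off
    p_missing_ethnicity: float = 0.30
    p_missing_bmi: float = 0.25

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be >= 0, got {self.n_patients}")
        for name in (
            "p_female",
            "p_t2dm",
            "p_depression",
            "p_pre_entry_ad",
            "p_insulin_early",
            "p_insulin_late",
            "p_pregnancy",
            "p_gestational_only",
            "p_pre_entry_depression",
            "p_missing_ethnicity",
            "p_missing_bmi",
        ):
            _check_prob(name, getattr(self, name))
        for key, value in self.p_comorbidity.items():
            _check_prob(f"p_comorbidity.{key}", value)
        for key, value in self.p_context_depression.items():
            _check_prob(f"p_context_depression.{key}", value)
        for key, value in self.cause_probs.items():
            if key not in CAUSE_CATEGORIES:
                raise ConfigurationError(f"cause_probs has unknown cause {key!r}")
            _check_prob(f"cause_probs.{key}", value)
        if abs(sum(self.cause_probs.values()) - 1.0) > 1e-12:
            raise ConfigurationError("cause_probs must sum to 1 within 1e-12")
        if self.baseline_hazard < 0:
            raise ConfigurationError(
                f"baseline_hazard must be >= 0, got {self.baseline_hazard}"
            )
        if self.severity_link < 0:
            raise ConfigurationError(
                f"severity_link must be >= 0, got {self.severity_link}"
            )
        if self.rx_duration_days < 1:
            raise ConfigurationError(
                f"rx_duration_days must be >= 1, got {self.rx_duration_days}"
            )
        start = _check_date("study_start", self.study_start)
        end = _check_date("study_end", self.study_end)
        if not start < end:
            raise ConfigurationError("study_start must precede study_end")
        reg_min = _check_date("registration_start_min", self.registration_start_min)
        reg_max = _check_date("registration_start_max", self.registration_start_max)
        if reg_min > reg_max:
            raise ConfigurationError(
                "registration_start_min must not exceed registration_start_max"
            )
        if self.ad_course_rate < 0:
            raise ConfigurationError(
                f"ad_course_rate must be >= 0, got {self.ad_course_rate}"
            )
        if self.max_courses < 1:
            raise ConfigurationError(f"max_courses must be >= 1, got {self.max_courses}")
        if self.course_rx_mean < 1:
            raise ConfigurationError(
                f"course_rx_mean must be >= 1, got {self.course_rx_mean}"
            )

    @property
    def effective_n_practices(self) -> int:
        if self.n_practices > 0:
            return self.n_practices
        return max(2, self.n_patients // 500)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_file(self, path) -> None:
        write_flat_config(self, path)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        return read_flat_config(cls, path)


DEFAULT_ADJUSTMENT = (
    "ethnicity_nonwhite",
    "bmi",
    "smoking_ex",
    "smoking_current",
    "comorbidity_cvd",
    "comorbidity_copd",
    "t2dm_duration_years",
    "contacts_preentry",
    "polypharmacy_preentry",
    "ad_history_preentry",
)

KNOWN_CONTRASTS = ("any", "timing", "duration_band", "n_agents")
KNOWN_CAUSES = ("all",) + CAUSE_CATEGORIES


@dataclass
class AnalysisConfig:
    """Configuration of the full analysis pipeline."""

    tables_dir: str = ""
    seed: int = 0
    study_end: str = "2018-12-31"
    glucose_threshold: float = 11.1
    min_registration_lead_days: int = 183
    t1dm_insulin_window_days: int = 183
    age_min: int = 18
    depression_rule: str = "post_entry"  # or "any_time"
    control_depression_window: str = "by_reference_date"  # or "any_time"
    max_controls: int = 4
    age_match_tolerance: int = 5
    episode_gap_days: int = 60
    recent_days: int = 182
    default_rx_duration_days: int = 28
    contacts_window_days: int = 365
    polypharmacy_window_days: int = 90
    contrasts: tuple[str, ...] = KNOWN_CONTRASTS
    causes: tuple[str, ...] = ("all",)
    adjust: tuple[str, ...] = DEFAULT_ADJUSTMENT
    complete_case_ethnicity: bool = False
    complete_case_bmi: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.causes) - set(KNOWN_CAUSES)
        if unknown:
            raise ConfigurationError(f"causes contains unknown categories {sorted(unknown)}")
        unknown = set(self.contrasts) - set(KNOWN_CONTRASTS)
        if unknown:
            raise ConfigurationError(f"contrasts contains unknown entries {sorted(unknown)}")
        if self.depression_rule not in ("post_entry", "any_time"):
            raise ConfigurationError(
                f"depression_rule must be post_entry or any_time, got {self.depression_rule!r}"
            )
        if self.control_depression_window not in ("by_reference_date", "any_time"):
            raise ConfigurationError(
                "control_depression_window must be by_reference_date or any_time, "
                f"got {self.control_depression_window!r}"
            )
        if not 1 <= self.max_controls:
            raise ConfigurationError(f"max_controls must be >= 1, got {self.max_controls}")
        _check_date("study_end", self.study_end)

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_file(self, path) -> None:
        write_flat_config(self, path)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        return read_flat_config(cls, path)


# -- flat key=value serialisation -------------------------------------------

def _flatten(obj) -> dict[str, str]:
    out: dict[str, str] = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        if isinstance(value, dict):
            for key, sub in value.items():
                out[f"{f.name}.{key}"] = repr(sub)
        elif isinstance(value, (tuple, list)):
            out[f.name] = ",".join(str(v) for v in value)
        else:
            out[f.name] = str(value)
    return out


def write_flat_config(obj, path) -> None:
    lines = [f"{key} = {value}" for key, value in _flatten(obj).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_scalar(text: str, target_type):
    if target_type is bool:
        return text.strip().lower() in ("true", "1", "yes")
    if target_type is int:
        return int(text)
    if target_type is float:
        return float(text)
    return text.strip()


def read_flat_config(cls, path):
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    defaults = cls()
    for key, text in raw.items():
        base, dot, sub = key.partition(".")
        if base not in fields:
            raise ConfigurationError(f"unknown configuration field {key!r}")
        current = getattr(defaults, base)
        if dot:
            mapping = dict(kwargs.get(base, current))
            mapping[sub] = float(text)
            kwargs[base] = mapping
        elif isinstance(current, tuple):
            kwargs[base] = tuple(s.strip() for s in text.split(",") if s.strip())
        else:
            kwargs[base] = _parse_scalar(text, type(current))
    return cls(**kwargs)
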