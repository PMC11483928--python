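"""Study configuration.

All date arithmetic in the package happens in integer days; months appear
only at reporting time, via a single fixed month length (Julian year / 12 =
30.4375 days).  Every convention that the line-of-therapy algorithm depends
on — discontinuation gaps, the combination window, the study window — lives
here so that a whole analysis is reproducible from one YAML file.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Default enrolment window of the study design this package models.
DEFAULT_STUDY_START = dt.date(2016, 1, 1)
DEFAULT_STUDY_END = dt.date(2021, 8, 31)

#: Fixed month length in days (Julian year / 12).
MONTH_DAYS = 30.4375


class StudyConfig(BaseModel):
    """Tunable conventions of the patient-journey analysis.

    Parameters
    ----------
    study_window:
        Enrolment/observation window ``[start, end]`` (inclusive dates).
    month_length_days:
        Days per month used for every day→month conversion.
    biologic_gap_months, oral_gap_months:
        Permissible off-drug interval before a refill is considered a new
        treatment episode: 3 months for biologics, 2 months for oral and
        all other drug classes.  Converted to days with ``round``.
    gap_overrides_days:
        Per-drug-code overrides of the discontinuation gap, in days.
    combination_window_days:
        A main drug starting within this many days of the current line's
        start joins the regimen as a combination instead of opening a new
        line.
    stockpiling:
        If true, overlapping dispensings carry leftover supply forward;
        default truncates (overlap never extends coverage beyond the last
        dispensing's own end).
    apheresis_dominates:
        If true, apheresis/plasma exchange wins the general-regimen label
        over any co-occurring main category regardless of priority rank.
    psv_baseline_only:
        Restrict the psoriasis-vulgaris subgroup flag to baseline-period
        diagnoses instead of any-time presence.
    ltfu_from_last_activity:
        Treat the last recorded claim date as end of follow-up (the data
        model has no explicit disenrollment).
    censor_last_episode_always:
        Drug survival censors each patient's final episode of a drug even
        when it ends long before end of follow-up.  Setting this false
        censors only episodes ending within the drug's gap window of
        follow-up end (sensitivity analysis).
    duration_over_episodes:
        ``"cumulative"`` sums a patient's on-drug days across episodes for
        the >1-year / >2-year treatment-duration proportions;
        ``"longest"`` uses the single longest episode.
    gpp_codes / psv_codes:
        Diagnosis codes identifying the index disease and the psoriasis
        vulgaris comorbidity.
    window_slack_days:
        Records may predate the study window by up to this many days
        (baseline look-back) without being flagged by validation.
    """

    study_window: tuple[dt.date, dt.date] = (DEFAULT_STUDY_START, DEFAULT_STUDY_END)
    month_length_days: float = MONTH_DAYS
    biologic_gap_months: float = 3.0
    oral_gap_months: float = 2.0
    gap_overrides_days: dict[str, int] = Field(default_factory=dict)
    combination_window_days: int = 30
    stockpiling: bool = False
    apheresis_dominates: bool = False
    psv_baseline_only: bool = False
    ltfu_from_last_activity: bool = True
    censor_last_episode_always: bool = True
    duration_over_episodes: str = "cumulative"
    strict_catalog: bool = False
    gpp_codes: tuple[str, ...] = ("L40.1",)
    psv_codes: tuple[str, ...] = ("L40.0",)
    min_followup_days: int = 365
    baseline_days: int = 365
    window_slack_days: int = 730

    @field_validator("duration_over_episodes")
    @classmethod
    def _check_duration_mode(cls, v: str) -> str:
        if v not in {"cumulative", "longest"}:
            raise ValueError("duration_over_episodes must be 'cumulative' or 'longest'")
        return v

    @model_validator(mode="after")
    def _check_window(self) -> "StudyConfig":
        start, end = self.study_window
        if end <= start:
            raise ValueError("study window end must follow its start")
        if self.combination_window_days < 0:
            raise ValueError("combination_window_days must be non-negative")
        return self

    # -- gap thresholds ------------------------------------------------

    def gap_days(self, gap_class: str) -> int:
        """Discontinuation gap in days for a gap class (biologic/oral/other)."""
        months = self.biologic_gap_months if gap_class == "biologic" else self.oral_gap_months
        return round(months * self.month_length_days)

    # -- (de)serialisation --------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "study_window" in raw:
            raw["study_window"] = tuple(
                dt.date.fromisoformat(d) if isinstance(d, str) else d
                for d in raw["study_window"]
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump()
        data["study_window"] = [d.isoformat() for d in self.study_window]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


DEFAULT_CONFIG = StudyConfig()
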