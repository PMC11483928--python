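"""Cohort construction: eligibility, index date, follow-up and subgroups.

A patient enters the cohort at the date of their first confirmed GPP
diagnosis (ICD-10 L40.1) inside the study window — the *index date* — and
is followed until the earliest of study end, death, or last recorded
claim.  Patients are excluded when they have only one confirmed GPP
diagnosis date, or when they could not be followed for more than a year
after index (unless they died within that year).  Baseline comorbidity is
the Quan-coded Charlson index over the year preceding index.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .config import StudyConfig
from .model import ClaimsBundle
from .quan_cci import compute_cci_quan

REASONS = ("ok", "single_gpp_diagnosis", "insufficient_followup", "unclear_history")


@dataclass(frozen=True)
class EligibilityDecision:
    patient_id: str
    included: bool
    reason: str

    def __post_init__(self) -> None:
        assert self.included == (self.reason == "ok")


def determine_index_date(
    diagnoses: pd.DataFrame, config: StudyConfig
) -> dt.date | None:
    """Earliest confirmed GPP diagnosis date inside the study window, if any.

    ``diagnoses`` must already be restricted to one patient.  Order of the
    input rows is irrelevant.
    """
    if not len(diagnoses):
        return None
    start, end = config.study_window
    mask = (
        diagnoses["code"].isin(config.gpp_codes)
        & diagnoses["confirmed"]
        & (diagnoses["date"] >= pd.Timestamp(start))
        & (diagnoses["date"] <= pd.Timestamp(end))
    )
    if not mask.any():
        return None
    return diagnoses.loc[mask, "date"].min().date()


def followup_end_date(
    patient: pd.Series,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: StudyConfig,
) -> dt.date:
    """End of follow-up: min(study end, death, last recorded activity)."""
    end = pd.Timestamp(config.study_window[1])
    death = patient.get("death_date")
    if pd.notna(death):
        end = min(end, pd.Timestamp(death))
    if config.ltfu_from_last_activity:
        last = pd.Timestamp.min
        if len(diagnoses):
            last = max(last, diagnoses["date"].max())
        if len(prescriptions):
            last = max(last, prescriptions["date"].max())
        if last > pd.Timestamp.min:
            end = min(end, last)
    return end.date()


def apply_eligibility(
    patient: pd.Series,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
    followup_end: dt.date | None = None,
) -> EligibilityDecision:
    """Inclusion decision for one patient.

    Exclusion reasons, in the order they are checked: no confirmed GPP
    index diagnosis in the window (``unclear_history``); a single distinct
    confirmed GPP diagnosis date (``single_gpp_diagnosis``); follow-up of
    at most one year without death in that year (``insufficient_followup``).
    """
    pid = str(patient["patient_id"])
    index = determine_index_date(diagnoses, config)
    if index is None:
        return EligibilityDecision(pid, False, "unclear_history")

    confirmed = diagnoses[
        diagnoses["code"].isin(config.gpp_codes) & diagnoses["confirmed"]
    ]
    n_distinct_dates = confirmed["date"].dt.normalize().nunique()
    if n_distinct_dates < 2:
        return EligibilityDecision(pid, False, "single_gpp_diagnosis")

    if followup_end is None:
        followup_end = config.study_window[1]
    followed_days = (followup_end - index).days
    if followed_days <= config.min_followup_days:
        death = patient.get("death_date")
        died_within = (
            pd.notna(death)
            and index <= pd.Timestamp(death).date() <= index + dt.timedelta(days=config.min_followup_days)
        )
        if not died_within:
            return EligibilityDecision(pid, False, "insufficient_followup")
    return EligibilityDecision(pid, True, "ok")


def assign_subgroups(
    index_date: dt.date,
    age_at_index: int,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
) -> dict[str, bool]:
    """Subgroup flags: psoriasis-vulgaris comorbidity and elderly age bands.

    PsV is flagged on any confirmed L40.0 (or configured code) anywhere in
    the record by default; ``psv_baseline_only`` restricts the search to the
    baseline year.
    """
    dx = diagnoses[diagnoses["code"].isin(config.psv_codes) & diagnoses["confirmed"]]
    if config.psv_baseline_only:
        lo = pd.Timestamp(index_date - dt.timedelta(days=config.baseline_days))
        hi = pd.Timestamp(index_date)
        dx = dx[(dx["date"] >= lo) & (dx["date"] < hi)]
    return {
        "has_psv": bool(len(dx)),
        "age_ge_65": age_at_index >= 65,
        "age_ge_75": age_at_index >= 75,
    }


def build_cohort(bundle: ClaimsBundle, config: StudyConfig | None = None) -> pd.DataFrame:
    """Build the cohort table: one row per bundle patient.

    Columns: patient_id, included, reason, index_date, followup_end,
    age_at_index, cci_score, has_psv, age_ge_65, age_ge_75.  Excluded
    patients keep their decision but carry NaT/NA analysis fields.
    """
    config = config or StudyConfig(study_window=bundle.study_window)
    dx_by_pid = dict(tuple(bundle.diagnoses.groupby("patient_id", sort=False)))
    rx_by_pid = dict(tuple(bundle.prescriptions.groupby("patient_id", sort=False)))
    empty_dx = bundle.diagnoses.iloc[0:0]
    empty_rx = bundle.prescriptions.iloc[0:0]

    rows = []
    for _, patient in bundle.patients.iterrows():
        pid = str(patient["patient_id"])
        dx = dx_by_pid.get(pid, empty_dx)
        rx = rx_by_pid.get(pid, empty_rx)
        fend = followup_end_date(patient, dx, rx, config)
        decision = apply_eligibility(patient, dx, config, followup_end=fend)
        row = {
            "patient_id": pid,
            "included": decision.included,
            "reason": decision.reason,
            "index_date": pd.NaT,
            "followup_end": pd.NaT,
            "age_at_index": pd.NA,
            "cci_score": pd.NA,
            "has_psv": pd.NA,
            "age_ge_65": pd.NA,
            "age_ge_75": pd.NA,
        }
        index = determine_index_date(dx, config)
        if index is not None:
            age = int(index.year - int(patient["birth_year"]))
            lo = pd.Timestamp(index - dt.timedelta(days=config.baseline_days))
            hi = pd.Timestamp(index)
            baseline_codes = dx.loc[
                (dx["date"] >= lo) & (dx["date"] < hi), "code"
            ].tolist()
            flags = assign_subgroups(index, age, dx, config)
            row.update(
                index_date=pd.Timestamp(index),
                followup_end=pd.Timestamp(fend),
                age_at_index=age,
                cci_score=compute_cci_quan(baseline_codes),
                **flags,
            )
        rows.append(row)
    cohort = pd.DataFrame(rows)
    # one decision per bundle patient, by construction
    assert len(cohort) == len(bundle.patients)
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for col in ("index_date", "followup_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
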