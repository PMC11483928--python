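"""Claims data model: reading, writing and validating claims bundles.

A claims bundle is three tables — patients, dated diagnoses, dated
prescriptions — plus the study window.  Dates are calendar dates at day
resolution; intervals elsewhere in the package are half-open ``[start,
end)``.  Rows whose dates cannot be parsed are rejected with a located
error rather than imputed, so an analysis is auditable back to its input.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MONTH_DAYS, StudyConfig

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "death_date"]
DIAGNOSIS_COLUMNS = ["patient_id", "code", "date", "confirmed"]
PRESCRIPTION_COLUMNS = ["patient_id", "drug_code", "date", "days_supply"]

SEXES = {"male", "female", "unknown"}


def months_from_days(days: float, month_length: float = MONTH_DAYS) -> float:
    """Convert a day count to months using the package-wide month length.

    The single conversion used everywhere durations are reported.
    """
    if days < 0:
        raise ValueError(f"negative duration: {days}")
    return days / month_length


@dataclass
class ValidationMessage:
    severity: str  # "error" | "warning"
    locator: str   # e.g. "prescriptions row 12" or "patient P00001"
    text: str


@dataclass
class ValidationReport:
    messages: list[ValidationMessage] = field(default_factory=list)

    @property
    def error_count(self) -> int:
        return sum(1 for m in self.messages if m.severity == "error")

    @property
    def warning_count(self) -> int:
        return sum(1 for m in self.messages if m.severity == "warning")

    def add(self, severity: str, locator: str, text: str) -> None:
        self.messages.append(ValidationMessage(severity, locator, text))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ValidationReport(errors={self.error_count}, warnings={self.warning_count})"


@dataclass
class ClaimsBundle:
    """In-memory claims bundle.

    ``patients``, ``diagnoses`` and ``prescriptions`` are pandas frames with
    the documented column schemas; ``parse_errors`` collects row-level
    problems encountered while reading (bad dates etc.) so nothing is
    silently dropped.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    study_window: tuple[dt.date, dt.date]
    parse_errors: list[ValidationMessage] = field(default_factory=list)

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.diagnoses.copy(),
            self.prescriptions.copy(),
            self.study_window,
            list(self.parse_errors),
        )


def _empty_frame(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def _parse_dates(df: pd.DataFrame, column: str, table: str,
                 errors: list[ValidationMessage], required: bool) -> pd.DataFrame:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    if required:
        bad = parsed.isna() & df[column].notna() & (df[column].astype(str).str.len() > 0)
        bad |= df[column].isna()
        for idx in df.index[bad]:
            errors.append(ValidationMessage(
                "error", f"{table} row {idx}", f"unparseable {column}: {df.loc[idx, column]!r}"))
        df = df.loc[~bad].copy()
        parsed = parsed.loc[df.index]
    else:
        bad = parsed.isna() & df[column].notna() & (df[column].astype(str).str.len() > 0)
        for idx in df.index[bad]:
            errors.append(ValidationMessage(
                "error", f"{table} row {idx}", f"unparseable {column}: {df.loc[idx, column]!r}"))
        df = df.loc[~bad].copy()
        parsed = parsed.loc[df.index]
    df[column] = parsed
    return df


def read_claims_bundle(
    patients_path: str | Path,
    diagnoses_path: str | Path,
    prescriptions_path: str | Path,
    window: tuple[dt.date, dt.date],
) -> ClaimsBundle:
    """Read the three claims CSVs into a bundle.

    Missing files and missing mandatory columns are fatal; rows with
    unparseable dates are removed and recorded in ``parse_errors``.
    """
    frames = {}
    for name, path, cols in (
        ("patients", patients_path, PATIENT_COLUMNS),
        ("diagnoses", diagnoses_path, DIAGNOSIS_COLUMNS),
        ("prescriptions", prescriptions_path, PRESCRIPTION_COLUMNS),
    ):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str, "code": str, "drug_code": str})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing mandatory column(s): {missing}")
        frames[name] = df[cols].copy()

    errors: list[ValidationMessage] = []
    patients = frames["patients"]
    patients["birth_year"] = pd.to_numeric(patients["birth_year"], errors="coerce").astype("Int64")
    patients = _parse_dates(patients, "death_date", "patients", errors, required=False)

    diagnoses = _parse_dates(frames["diagnoses"], "date", "diagnoses", errors, required=True)
    if len(diagnoses):
        diagnoses["confirmed"] = (
            diagnoses["confirmed"].map(_coerce_bool).fillna(True).astype(bool)
        )
    else:
        diagnoses["confirmed"] = pd.Series(dtype=bool)

    prescriptions = _parse_dates(frames["prescriptions"], "date", "prescriptions", errors, required=True)
    prescriptions["days_supply"] = pd.to_numeric(
        prescriptions["days_supply"], errors="coerce").astype("Int64")

    return ClaimsBundle(
        patients.reset_index(drop=True),
        diagnoses.reset_index(drop=True),
        prescriptions.reset_index(drop=True),
        window,
        errors,
    )


def _coerce_bool(v):
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, np.integer, float)):
        return bool(v)
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes", "t"}
    return None


def write_claims_bundle(bundle: ClaimsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle to ``patients.csv`` / ``diagnoses.csv`` / ``prescriptions.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    patients = bundle.patients.copy()
    patients["death_date"] = pd.to_datetime(patients["death_date"]).dt.strftime("%Y-%m-%d")
    paths["patients"] = out_dir / "patients.csv"
    patients.to_csv(paths["patients"], index=False)

    diagnoses = bundle.diagnoses.copy()
    diagnoses["date"] = pd.to_datetime(diagnoses["date"]).dt.strftime("%Y-%m-%d")
    paths["diagnoses"] = out_dir / "diagnoses.csv"
    diagnoses.to_csv(paths["diagnoses"], index=False)

    prescriptions = bundle.prescriptions.copy()
    prescriptions["date"] = pd.to_datetime(prescriptions["date"]).dt.strftime("%Y-%m-%d")
    paths["prescriptions"] = out_dir / "prescriptions.csv"
    prescriptions.to_csv(paths["prescriptions"], index=False)
    return paths


def validate_bundle(bundle: ClaimsBundle, config: StudyConfig | None = None) -> ValidationReport:
    """Enumerate every invariant violation in a parsed bundle.

    Reports, never raises, for data-content problems; the bundle itself is
    left untouched.
    """
    config = config or StudyConfig(study_window=bundle.study_window)
    report = ValidationReport()
    report.messages.extend(bundle.parse_errors)

    patients, dx, rx = bundle.patients, bundle.diagnoses, bundle.prescriptions
    start, end = bundle.study_window
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    slack = pd.Timedelta(days=config.window_slack_days)

    dup = patients["patient_id"][patients["patient_id"].duplicated()]
    for pid in dup.unique():
        report.add("error", f"patient {pid}", "duplicate patient_id")

    known = set(patients["patient_id"])
    for table, df in (("diagnoses", dx), ("prescriptions", rx)):
        unknown = ~df["patient_id"].isin(known)
        for idx in df.index[unknown]:
            report.add("error", f"{table} row {idx}",
                       f"unknown patient_id {df.loc[idx, 'patient_id']!r}")

    for idx in patients.index:
        sex = patients.loc[idx, "sex"]
        if sex not in SEXES:
            report.add("warning", f"patients row {idx}", f"unrecognised sex {sex!r}")
        death = patients.loc[idx, "death_date"]
        if pd.notna(death) and pd.Timestamp(death) < start_ts:
            report.add("error", f"patients row {idx}",
                       "death_date precedes study window start")

    if len(dx):
        empty = dx["code"].isna() | (dx["code"].astype(str).str.len() == 0)
        for idx in dx.index[empty]:
            report.add("error", f"diagnoses row {idx}", "empty diagnosis code")
        out = (dx["date"] < start_ts - slack) | (dx["date"] > end_ts + slack)
        for idx in dx.index[out]:
            report.add("warning", f"diagnoses row {idx}",
                       f"date {dx.loc[idx, 'date'].date()} far outside study window")

    if len(rx):
        bad_supply = rx["days_supply"].notna() & (rx["days_supply"] <= 0)
        for idx in rx.index[bad_supply]:
            report.add("error", f"prescriptions row {idx}",
                       f"non-positive days_supply {rx.loc[idx, 'days_supply']}")
        out = (rx["date"] < start_ts - slack) | (rx["date"] > end_ts + slack)
        for idx in rx.index[out]:
            report.add("warning", f"prescriptions row {idx}",
                       f"date {rx.loc[idx, 'date'].date()} far outside study window")

    # death before any recorded activity for the patient is a content error
    deaths = patients.dropna(subset=["death_date"]).set_index("patient_id")["death_date"]
    if len(deaths) and len(dx):
        first_dx = dx.groupby("patient_id")["date"].min()
        both = deaths.index.intersection(first_dx.index)
        for pid in both:
            if pd.Timestamp(deaths[pid]) < first_dx[pid]:
                report.add("error", f"patient {pid}",
                           "death_date precedes first diagnosis date")
    if len(deaths) and len(rx):
        last_rx = rx.groupby("patient_id")["date"].max()
        both = deaths.index.intersection(last_rx.index)
        for pid in both:
            if last_rx[pid] > pd.Timestamp(deaths[pid]):
                report.add("warning", f"patient {pid}",
                           "prescription recorded after death_date")
    return report


def empty_bundle(window: tuple[dt.date, dt.date]) -> ClaimsBundle:
    """A structurally valid bundle with zero records."""
    dx = _empty_frame(DIAGNOSIS_COLUMNS)
    dx["date"] = pd.Series(dtype="datetime64[ns]")
    dx["confirmed"] = pd.Series(dtype=bool)
    rx = _empty_frame(PRESCRIPTION_COLUMNS)
    rx["date"] = pd.Series(dtype="datetime64[ns]")
    rx["days_supply"] = pd.Series(dtype="Int64")
    pt = _empty_frame(PATIENT_COLUMNS)
    pt["death_date"] = pd.Series(dtype="datetime64[ns]")
    pt["birth_year"] = pd.Series(dtype="Int64")
    return ClaimsBundle(pt, dx, rx, window)
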