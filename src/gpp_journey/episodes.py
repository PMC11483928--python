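"""Treatment episodes: gap-based merging of dispensing coverage.

Each dispensing covers ``[date, date + supply)`` days, where supply is the
recorded days-supply or the drug's catalog default.  Successive coverage
intervals of the same patient and drug merge into one episode as long as
the off-drug gap (next start minus current coverage end) stays within the
drug's discontinuation threshold — 3 months for biologics, 2 months for
oral and other classes.  A longer gap splits the treatment history into
separate episodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import Catalog, DrugClass, gap_threshold_days
from .config import StudyConfig


@dataclass(frozen=True)
class CoverageInterval:
    patient_id: str
    drug_code: str
    start: pd.Timestamp
    end: pd.Timestamp  # half-open

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("coverage interval must have end > start")


@dataclass(frozen=True)
class Episode:
    start: pd.Timestamp
    end: pd.Timestamp
    n_prescriptions: int


def coverage_intervals(
    prescriptions: pd.DataFrame,
    drug_class: DrugClass,
    stockpiling: bool = False,
) -> list[CoverageInterval]:
    """Turn one patient-drug's dispensings into coverage intervals.

    With ``stockpiling`` enabled, a dispensing issued while the previous
    one still covers the patient starts only when that coverage runs out,
    carrying the overlap forward; by default overlap is simply truncated.
    """
    rx = prescriptions.sort_values("date", kind="mergesort")
    intervals: list[CoverageInterval] = []
    carry_end: pd.Timestamp | None = None
    for _, row in rx.iterrows():
        supply = row["days_supply"]
        days = int(supply) if pd.notna(supply) else drug_class.default_coverage_days
        start = row["date"]
        if stockpiling and carry_end is not None and start < carry_end:
            start = carry_end
        end = start + pd.Timedelta(days=days)
        carry_end = end if carry_end is None else max(carry_end, end)
        intervals.append(CoverageInterval(
            str(row["patient_id"]), str(row["drug_code"]), start, end))
    return intervals


def merge_into_episodes(
    intervals: list[CoverageInterval] | list[tuple],
    gap_days: int,
) -> list[Episode]:
    """Merge coverage intervals into maximal episodes.

    Intervals whose gap (next start − running coverage end) is at most
    ``gap_days`` coalesce; the episode end is the maximum covered end.
    Accepts ``CoverageInterval`` objects or plain ``(start, end)`` pairs.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be non-negative")
    if not intervals:
        return []

    def as_pair(iv):
        if isinstance(iv, CoverageInterval):
            return iv.start, iv.end
        return iv[0], iv[1]

    pairs = sorted((as_pair(iv) for iv in intervals), key=lambda p: (p[0], p[1]))
    episodes: list[Episode] = []
    cur_start, cur_end = pairs[0]
    n = 1
    for start, end in pairs[1:]:
        gap = (start - cur_end).days if hasattr(start - cur_end, "days") else start - cur_end
        if gap <= gap_days:
            cur_end = max(cur_end, end)
            n += 1
        else:
            episodes.append(Episode(cur_start, cur_end, n))
            cur_start, cur_end, n = start, end, 1
    episodes.append(Episode(cur_start, cur_end, n))
    return episodes


EPISODE_COLUMNS = [
    "patient_id", "drug_code", "category1", "category2", "is_supplementary",
    "episode_index", "start", "end", "duration_days", "n_prescriptions", "is_last",
]


def build_episodes(
    prescriptions: pd.DataFrame,
    catalog: Catalog,
    config: StudyConfig,
) -> pd.DataFrame:
    """Episode table for a whole prescriptions frame.

    One row per (patient, drug, episode); ``episode_index`` is 1-based in
    chronological order and ``is_last`` marks the patient's final episode
    of that drug — the episode that drug-survival analysis censors.
    """
    rows = []
    if len(prescriptions):
        for (pid, code), group in prescriptions.groupby(["patient_id", "drug_code"], sort=True):
            drug_class = catalog.classify(str(code), strict=config.strict_catalog)
            gap = gap_threshold_days(drug_class, config)
            intervals = coverage_intervals(group, drug_class, stockpiling=config.stockpiling)
            merged = merge_into_episodes(intervals, gap)
            for i, ep in enumerate(merged, start=1):
                rows.append({
                    "patient_id": str(pid),
                    "drug_code": str(code),
                    "category1": drug_class.category1,
                    "category2": drug_class.category2,
                    "is_supplementary": drug_class.is_supplementary,
                    "episode_index": i,
                    "start": ep.start,
                    "end": ep.end,
                    "duration_days": int((ep.end - ep.start).days),
                    "n_prescriptions": ep.n_prescriptions,
                    "is_last": i == len(merged),
                })
    if not rows:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    df = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    return df.sort_values(["patient_id", "drug_code", "episode_index"]).reset_index(drop=True)


def write_episodes(episodes: pd.DataFrame, path) -> None:
    out = episodes.copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
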