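"""Kaplan–Meier machinery plus TTNT and drug-survival analyses.

The product-limit estimator is implemented here from first principles
(S(t) = Π_{t_i ≤ t} (1 − d_i/n_i), Greenwood variance, log-log
transformed 95% band for the median CI).  Two study-specific censoring
conventions drive the analyses:

* time to next therapy (TTNT): each line of therapy contributes the time
  from its start to the next line's start as an event; a patient's last
  line contributes time to end of follow-up as a censored observation;
* drug survival: all episodes of a drug across its recipients enter the
  fit; a patient's final episode of that drug is censored, earlier
  episodes are events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import StudyConfig
from .model import months_from_days

Z95 = stats.norm.ppf(0.975)


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times of a sample."""

    event_times: np.ndarray     # ascending, distinct
    n_at_risk: np.ndarray       # at-risk count just before each event time
    n_events: np.ndarray        # events at each event time
    survival: np.ndarray        # S(t) at each event time
    greenwood_var: np.ndarray   # Greenwood variance of S(t)
    n_samples: int
    n_total_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(durations, events) -> KMCurve:
    """Fit the Kaplan–Meier estimator.

    ``durations`` are positive follow-up times; ``events`` flags true for
    an observed event, false for censoring.  Units censored exactly at an
    event time are counted at risk at that time (standard convention).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit requires at least one sample")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    if t.shape != e.shape:
        raise ValueError("durations and events must have equal length")

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])

    # at risk just before u: everyone with duration >= u
    n_at_risk = np.array([np.sum(t >= u) for u in event_times], dtype=float)
    n_events = np.array([np.sum(t[e] == u) for u in event_times], dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - n_events / n_at_risk
        survival = np.cumprod(frac)
        terms = np.where(n_at_risk > n_events,
                         n_events / (n_at_risk * (n_at_risk - n_events)), np.nan)
        gw = survival**2 * np.cumsum(np.nan_to_num(terms, nan=0.0))
        gw = np.where(survival == 0.0, 0.0, gw)

    return KMCurve(
        event_times=event_times,
        n_at_risk=n_at_risk.astype(int),
        n_events=n_events.astype(int),
        survival=survival,
        greenwood_var=gw,
        n_samples=int(t.size),
        n_total_events=int(e.sum()),
    )


def _loglog_band(curve: KMCurve, z: float = Z95) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise 95% band for S(t) on the log(-log) scale.

    Where the transform is undefined (S = 0 or 1) the band collapses onto
    the estimate.
    """
    s = curve.survival
    lower = s.copy()
    upper = s.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(s)
        se_cll = np.sqrt(curve.greenwood_var) / np.abs(s * logs)
        theta_lo = np.exp(z * se_cll)
        theta_hi = np.exp(-z * se_cll)
        ok = (s > 0) & (s < 1) & np.isfinite(se_cll)
        lower[ok] = s[ok] ** theta_lo[ok]
        upper[ok] = s[ok] ** theta_hi[ok]
    return lower, upper


def km_median_ci(curve: KMCurve, z: float = Z95):
    """Median survival time with its 95% CI.

    Median: smallest event time with S(t) ≤ 0.5, or None when the curve
    never falls that far.  CI bounds invert the log-log band
    (Brookmeyer–Crowley); an upper bound the band never crosses is
    reported as ``inf``.
    """
    def first_crossing(values: np.ndarray):
        idx = np.nonzero(values <= 0.5)[0]
        return float(curve.event_times[idx[0]]) if idx.size else None

    median = first_crossing(curve.survival)
    if median is None:
        return None, (None, None)
    lower_s, upper_s = _loglog_band(curve, z)
    lo = first_crossing(lower_s)
    hi = first_crossing(upper_s)
    return median, (lo, np.inf if hi is None else hi)


def summarize_km(durations, events, month_length: float) -> dict:
    """n / events / KM median (months) with CI, plus the observed range of
    event durations and their raw median (reported alongside for
    comparison)."""
    curve = km_fit(durations, events)
    median, (lo, hi) = km_median_ci(curve)
    ev = np.asarray(durations, dtype=float)[np.asarray(events, dtype=bool)]

    def to_months(v):
        if v is None:
            return None
        if np.isinf(v):
            return np.inf
        return months_from_days(v, month_length)

    return {
        "n": int(len(np.asarray(durations))),
        "n_events": int(curve.n_total_events),
        "median_months": to_months(median),
        "ci_low_months": to_months(lo),
        "ci_high_months": to_months(hi),
        "range_min_months": to_months(float(ev.min())) if ev.size else None,
        "range_max_months": to_months(float(ev.max())) if ev.size else None,
        "raw_median_months": to_months(float(np.median(ev))) if ev.size else None,
    }


# ---------------------------------------------------------------------------
# time to next therapy
# ---------------------------------------------------------------------------

def ttnt_samples(lots: pd.DataFrame) -> pd.DataFrame:
    """Survival samples from a LOT table.

    Each non-last line yields an event with duration next-start minus
    start; each last line a censored duration to end of follow-up.
    Durations are floored at one day.
    """
    if not len(lots):
        return pd.DataFrame(columns=[
            "patient_id", "lot_number", "specific_regimen", "general_regimen",
            "duration_days", "event"])
    rows = []
    for pid, group in lots.groupby("patient_id", sort=False):
        group = group.sort_values("lot_number")
        starts = list(group["start"])
        for i, (_, lot) in enumerate(group.iterrows()):
            if i + 1 < len(group):
                dur = (starts[i + 1] - lot["start"]).days
                event = True
            else:
                dur = (lot["followup_end"] - lot["start"]).days
                event = False
            rows.append({
                "patient_id": pid,
                "lot_number": int(lot["lot_number"]),
                "specific_regimen": lot["specific_regimen"],
                "general_regimen": lot["general_regimen"],
                "duration_days": max(int(dur), 1),
                "event": event,
            })
    return pd.DataFrame(rows)


def ttnt_table(
    lots: pd.DataFrame,
    config: StudyConfig,
    granularity: str = "by_line",
    min_group_size: int = 1,
) -> pd.DataFrame:
    """TTNT summary at the requested granularity.

    ``granularity``: ``by_line`` (per line number), ``all_lines`` (one
    pooled row), or ``by_specific_regimen`` (per general/specific regimen
    across all lines).
    """
    samples = ttnt_samples(lots)
    if granularity == "by_line":
        keys = ["lot_number"]
    elif granularity == "all_lines":
        samples = samples.assign(group="all lines")
        keys = ["group"]
    elif granularity == "by_specific_regimen":
        keys = ["general_regimen", "specific_regimen"]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    rows = []
    if len(samples):
        for key, group in samples.groupby(keys, sort=True):
            if len(group) < min_group_size:
                continue
            summary = summarize_km(
                group["duration_days"], group["event"], config.month_length_days)
            if not isinstance(key, tuple):
                key = (key,)
            rows.append({**dict(zip(keys, key)), **summary})
    return pd.DataFrame(rows, columns=keys + [
        "n", "n_events", "median_months", "ci_low_months", "ci_high_months",
        "range_min_months", "range_max_months", "raw_median_months"])


# ---------------------------------------------------------------------------
# drug survival
# ---------------------------------------------------------------------------

def drug_survival_samples(
    episodes: pd.DataFrame,
    config: StudyConfig,
    followup_end: pd.Series | None = None,
) -> pd.DataFrame:
    """Episode-level survival samples for drug-survival analysis.

    The default policy censors each patient's last episode of a drug
    unconditionally (the study convention).  With
    ``censor_last_episode_always`` off, a last episode is censored only
    when it ends within the drug's gap window of the patient's follow-up
    end (``followup_end``: patient_id-indexed series) and counts as an
    event otherwise.
    """
    if not len(episodes):
        return pd.DataFrame(columns=["patient_id", "drug_code", "duration_days", "event"])
    df = episodes.copy()
    if config.censor_last_episode_always or followup_end is None:
        df["event"] = ~df["is_last"]
    else:
        gap = df["category1"].eq("Biologics").map(
            {True: config.gap_days("biologic"), False: config.gap_days("oral")})
        fend = df["patient_id"].map(followup_end)
        near_end = (pd.to_datetime(fend) - df["end"]).dt.days <= gap
        df["event"] = ~(df["is_last"] & near_end)
    out = df[["patient_id", "drug_code", "duration_days", "event"]].copy()
    out["duration_days"] = out["duration_days"].clip(lower=1)
    return out


def drug_survival_table(
    episodes: pd.DataFrame,
    config: StudyConfig,
    followup_end: pd.Series | None = None,
    min_patients: int = 1,
) -> pd.DataFrame:
    """Per-drug survival summary.

    For each drug: all recipients' episodes enter the KM fit with the
    last-episode censoring convention; >1-year and >2-year treatment
    proportions are computed over patients from cumulative on-drug days
    (or the longest episode, per configuration).
    """
    columns = ["drug_code", "n_patients", "n_episodes", "median_months",
               "ci_low_months", "ci_high_months", "n_gt1yr", "pct_gt1yr",
               "n_gt2yr", "pct_gt2yr"]
    if not len(episodes):
        return pd.DataFrame(columns=columns)
    samples = drug_survival_samples(episodes, config, followup_end)

    rows = []
    for drug, group in episodes.groupby("drug_code", sort=True):
        n_patients = group["patient_id"].nunique()
        if n_patients < min_patients:
            continue
        s = samples[samples["drug_code"] == drug]
        summary = summarize_km(s["duration_days"], s["event"], config.month_length_days)

        per_patient = group.groupby("patient_id")["duration_days"]
        on_drug = per_patient.sum() if config.duration_over_episodes == "cumulative" \
            else per_patient.max()
        n1 = int((on_drug > 365.25).sum())
        n2 = int((on_drug > 730.5).sum())
        rows.append({
            "drug_code": drug,
            "n_patients": int(n_patients),
            "n_episodes": int(len(group)),
            "median_months": summary["median_months"],
            "ci_low_months": summary["ci_low_months"],
            "ci_high_months": summary["ci_high_months"],
            "n_gt1yr": n1,
            "pct_gt1yr": 100.0 * n1 / n_patients,
            "n_gt2yr": n2,
            "pct_gt2yr": 100.0 * n2 / n_patients,
        })
    return pd.DataFrame(rows, columns=columns)
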