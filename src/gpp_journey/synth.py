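"""Synthetic longitudinal claims with fully known ground truth.

The generator emulates the structure of a hospital claims extract for a
rare relapsing skin disease: per-patient diagnosis streams carrying the
index code (L40.1) and comorbidity codes, dated dispensing records for
the catalogued medication classes, deaths and loss to follow-up inside a
fixed study window.  Patient pathways are drawn from a small Markov
grammar over named regimen states; because every line boundary, episode
boundary and censoring flag is chosen by the generator, the derived
tables can be checked against exact truth.

Claims are emitted only through the documented bundle schema, so tests
exercise the same I/O path as real data.  Ground truth is defined under
the package's documented conventions (91/61-day gaps, 30-day combination
window); the presets avoid rule-boundary ambiguity except the
``edge_cases`` preset, which documents its expected outcome per case.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from math import log
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .catalog import Catalog, load_catalog
from .config import DEFAULT_STUDY_END, DEFAULT_STUDY_START, MONTH_DAYS, StudyConfig
from .model import ClaimsBundle, write_claims_bundle

LN2 = log(2.0)


class DurationDist(BaseModel):
    """Line-duration distribution: exponential/Weibull/fixed, parameterised
    in months via the package month length."""

    dist: Literal["exponential", "weibull", "fixed"] = "exponential"
    median_months: float | None = None
    shape: float | None = None
    scale_months: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "DurationDist":
        if self.dist in {"exponential", "fixed"}:
            if self.median_months is None or self.median_months <= 0:
                raise ValueError(f"{self.dist} distribution needs median_months > 0")
        else:
            if not self.shape or not self.scale_months or self.shape <= 0 or self.scale_months <= 0:
                raise ValueError("weibull distribution needs shape > 0 and scale_months > 0")
        return self

    def median_days(self) -> float:
        if self.dist in {"exponential", "fixed"}:
            return self.median_months * MONTH_DAYS
        return self.scale_months * MONTH_DAYS * LN2 ** (1.0 / self.shape)

    def sample_days(self, rng: np.random.Generator) -> int:
        if self.dist == "fixed":
            days = self.median_months * MONTH_DAYS
        elif self.dist == "exponential":
            days = rng.exponential(self.median_months * MONTH_DAYS / LN2)
        else:
            days = self.scale_months * MONTH_DAYS * rng.weibull(self.shape)
        return max(1, round(days))


class PathwayState(BaseModel):
    """One regimen state of the pathway grammar."""

    drugs: list[str]
    duration: DurationDist
    next: dict[str, float] = Field(default_factory=dict)
    gap_prob: float = 0.0               # chance of an untreated spell before the next line
    gap_range_days: tuple[int, int] = (100, 180)

    @model_validator(mode="after")
    def _check(self) -> "PathwayState":
        if not self.drugs:
            raise ValueError("a pathway state needs at least one drug")
        total = sum(self.next.values())
        if total > 1.0 + 1e-9 or any(p < 0 for p in self.next.values()):
            raise ValueError("transition probabilities must be non-negative and sum to <= 1")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ValueError("gap_prob must be a probability")
        return self


class ScenarioConfig(BaseModel):
    """Full specification of a synthetic cohort scenario."""

    name: str = "custom"
    n_patients: int = 300
    seed: int = 0
    study_window: tuple[dt.date, dt.date] = (DEFAULT_STUDY_START, DEFAULT_STUDY_END)
    states: dict[str, PathwayState] = Field(default_factory=dict)
    initial: dict[str, float] = Field(default_factory=dict)
    cadence: dict[str, tuple[int, int]] = Field(default_factory=dict)  # drug -> (interval, supply)
    supplementary_prob: float = 0.0
    supplementary_drugs: list[str] = Field(default_factory=lambda: ["topical_corticosteroid", "antihistamine"])
    # presets keep lines longer than the biologic discontinuation gap so a
    # drug recurring two lines later can never bridge across at episode level
    min_line_days: int = 100
    max_line_days: int = 1080
    visit_interval_days: int = 90
    annual_death_rate: float = 0.03
    age_mean: float = 57.2
    age_sd: float = 19.9
    male_frac: float = 0.475
    psv_prevalence: float = 0.366
    comorbidities: list[tuple[str, float]] = Field(default_factory=lambda: [
        ("I10", 0.18), ("M545", 0.17), ("E119", 0.08), ("I21", 0.04),
        ("J44", 0.05), ("C50", 0.02), ("C78", 0.005),
    ])
    special_patients: list[str] = Field(default_factory=list)
    index_margin_days: int = 500
    max_lines: int = 6

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        total = sum(self.initial.values())
        if total > 1.0 + 1e-9 or any(p < 0 for p in self.initial.values()):
            raise ValueError("initial probabilities must be non-negative and sum to <= 1")
        for name in self.initial:
            if name not in self.states:
                raise ValueError(f"initial state {name!r} not defined")
        for state in self.states.values():
            for nxt in state.next:
                if nxt not in self.states:
                    raise ValueError(f"transition target {nxt!r} not defined")
        if not 0.0 <= self.supplementary_prob <= 1.0:
            raise ValueError("supplementary_prob must be a probability")
        return self


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueLot:
    start: str                 # ISO date
    end: str
    state: str
    regimen_categories: list[str]
    supp_present: bool
    ttnt_days: int
    event: bool                # False = last line, censored


@dataclass
class PatientTruth:
    patient_id: str
    included: bool
    reason: str
    index_date: str | None = None
    followup_end: str | None = None
    death_date: str | None = None
    age_at_index: int | None = None
    has_psv: bool = False
    lots: list[TrueLot] = field(default_factory=list)
    episodes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    scenario: str
    seed: int
    patients: dict[str, PatientTruth] = field(default_factory=dict)
    state_median_days: dict[str, float] = field(default_factory=dict)
    lot_truth_valid: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "lot_truth_valid": self.lot_truth_valid,
            "state_median_days": self.state_median_days,
            "patients": {pid: asdict(p) for pid, p in self.patients.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        truth = cls(raw["scenario"], raw["seed"],
                    state_median_days=raw["state_median_days"],
                    lot_truth_valid=raw["lot_truth_valid"])
        for pid, p in raw["patients"].items():
            lots = [TrueLot(**lot) for lot in p.pop("lots")]
            episodes = {d: [tuple(iv) for iv in ivs] for d, ivs in p.pop("episodes").items()}
            truth.patients[pid] = PatientTruth(**p, lots=lots, episodes=episodes)
        return truth


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_categorical(rng: np.random.Generator, table: dict[str, float]) -> str | None:
    """Sample a key from a sub-probability table; residual mass maps to None."""
    u = rng.random()
    acc = 0.0
    for key in table:  # insertion order is part of the scenario definition
        acc += table[key]
        if u < acc:
            return key
    return None


def _drug_cadence(config: ScenarioConfig, catalog: Catalog, drug: str) -> tuple[int, int]:
    if drug in config.cadence:
        interval, supply = config.cadence[drug]
    else:
        days = catalog.classify(drug).default_coverage_days
        interval, supply = days, days
    if interval > supply:
        raise ValueError(f"cadence for {drug}: interval {interval} exceeds supply {supply}")
    return interval, supply


def _emit_fills(rx_rows: list, pid: str, drug: str, start: dt.date, end: dt.date,
                interval: int, supply: int) -> None:
    """Dispensings covering exactly [start, end): the final fill's supply is
    trimmed so coverage ends on the line boundary."""
    t = start
    while t < end:
        this_supply = min(supply, (end - t).days)
        rx_rows.append((pid, drug, t, this_supply))
        t = t + dt.timedelta(days=interval)


def _merge_days(fills: list[tuple[dt.date, int]], gap_days: int) -> list[tuple[dt.date, dt.date]]:
    """Generator-side episode truth: merge (date, supply) fills under the
    documented gap rule."""
    if not fills:
        return []
    fills = sorted(fills)
    episodes = []
    cur_start = fills[0][0]
    cur_end = fills[0][0] + dt.timedelta(days=fills[0][1])
    for date, supply in fills[1:]:
        end = date + dt.timedelta(days=supply)
        if (date - cur_end).days <= gap_days:
            cur_end = max(cur_end, end)
        else:
            episodes.append((cur_start, cur_end))
            cur_start, cur_end = date, end
    episodes.append((cur_start, cur_end))
    return episodes


def _validate_grammar(config: ScenarioConfig, catalog: Catalog) -> None:
    """Adjacent states must differ in main-category composition, otherwise a
    transition would be invisible to the category-level algorithm."""
    def main_cats(name: str) -> frozenset[str]:
        cats = set()
        for d in config.states[name].drugs:
            cls = catalog.classify(d)
            if not cls.is_supplementary:
                cats.add(cls.category2)
        return frozenset(cats)

    for name, state in config.states.items():
        for nxt in state.next:
            if main_cats(name) and main_cats(name) == main_cats(nxt):
                raise ValueError(
                    f"transition {name!r} → {nxt!r} keeps the main-category set "
                    f"{set(main_cats(name))} unchanged; the line change would be undetectable")


def generate_cohort(
    config: ScenarioConfig,
    catalog: Catalog | None = None,
    study_config: StudyConfig | None = None,
) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle plus its exact ground truth.

    Deterministic for a fixed config (including seed).  Included patients
    carry at least two confirmed index-disease diagnoses; the
    ``special_patients`` list injects documented edge cases (some of them
    ineligible by design).
    """
    catalog = catalog or load_catalog()
    study_config = study_config or StudyConfig(study_window=config.study_window)
    _validate_grammar(config, catalog)
    rng = np.random.default_rng(config.seed)
    window_start, window_end = config.study_window

    patient_rows: list[dict] = []
    dx_rows: list[tuple[str, str, dt.date, bool]] = []
    rx_rows: list[tuple[str, str, dt.date, int]] = []
    truth = GroundTruth(config.name, config.seed)
    for name, state in config.states.items():
        truth.state_median_days[name] = state.duration.median_days()

    for tag in config.special_patients:
        _emit_special(tag, config, catalog, study_config,
                      patient_rows, dx_rows, rx_rows, truth)

    n_regular = config.n_patients - len(config.special_patients)
    for i in range(max(n_regular, 0)):
        _emit_regular(f"P{i:04d}", rng, config, catalog, study_config,
                      patient_rows, dx_rows, rx_rows, truth)

    bundle = _assemble_bundle(patient_rows, dx_rows, rx_rows, config.study_window)
    return bundle, truth


def _emit_regular(pid, rng, config: ScenarioConfig, catalog: Catalog,
                  study_config: StudyConfig, patient_rows, dx_rows, all_rx_rows,
                  truth: GroundTruth) -> None:
    window_start, window_end = config.study_window
    rx_rows: list[tuple[str, str, dt.date, int]] = []  # this patient's fills
    age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 95))
    sex = "male" if rng.random() < config.male_frac else "female"
    span = (window_end - window_start).days - config.index_margin_days
    index = window_start + dt.timedelta(days=int(rng.integers(0, max(span, 1))))
    birth_year = index.year - age

    # death: exponential hazard from index, floored away from the index visit pair
    if config.annual_death_rate > 0:
        death_delay = max(30, round(rng.exponential(365.25 / config.annual_death_rate)))
        death = index + dt.timedelta(days=min(death_delay, 36500))
        death_date = death if death <= window_end else None
    else:
        death_date = None
    obs_end = min(window_end, death_date) if death_date else window_end

    # pathway: true line sequence before clipping
    lines: list[tuple[str, dt.date, dt.date]] = []
    state_name = _sample_categorical(rng, config.initial)
    t = index
    while state_name is not None and len(lines) < config.max_lines:
        state = config.states[state_name]
        dur = int(np.clip(state.duration.sample_days(rng),
                          config.min_line_days, config.max_line_days))
        end = t + dt.timedelta(days=dur)
        lines.append((state_name, t, end))
        nxt = _sample_categorical(rng, state.next)
        gap = 0
        if nxt is not None and state.gap_prob > 0 and rng.random() < state.gap_prob:
            lo, hi = state.gap_range_days
            gap = int(rng.integers(lo, hi + 1))
        t = end + dt.timedelta(days=gap)
        state_name = nxt

    # clip to observation end
    clipped = []
    for name, start, end in lines:
        if start >= obs_end:
            break
        clipped.append((name, start, min(end, obs_end)))
    lines = clipped

    # prescriptions per line (+ optional supplementary attachment)
    supp_attachments: list[tuple[dt.date, dt.date]] = []
    for name, start, end in lines:
        state = config.states[name]
        for drug in state.drugs:
            interval, supply = _drug_cadence(config, catalog, drug)
            _emit_fills(rx_rows, pid, drug, start, end, interval, supply)
        has_main = any(not catalog.classify(d).is_supplementary for d in state.drugs)
        dur = (end - start).days
        if has_main and config.supplementary_drugs and dur >= 30 \
                and rng.random() < config.supplementary_prob:
            drug = config.supplementary_drugs[int(rng.integers(0, len(config.supplementary_drugs)))]
            off = int(rng.integers(0, max(dur // 3, 1)))
            s_start = start + dt.timedelta(days=off)
            s_len = int(rng.integers(max(dur // 3, 1), max(dur - off, dur // 3 + 1)))
            s_end = min(s_start + dt.timedelta(days=max(s_len, 1)), end)
            if s_end > s_start:
                interval, supply = _drug_cadence(config, catalog, drug)
                _emit_fills(rx_rows, pid, drug, s_start, s_end, interval, supply)
                supp_attachments.append((s_start, s_end))

    # diagnoses: confirmed index pair, quarterly follow-up visits, final visit
    gpp = study_config.gpp_codes[0]
    dx_rows.append((pid, gpp, index, True))
    second = min(index + dt.timedelta(days=14), obs_end)
    dx_rows.append((pid, gpp, second, True))
    visit = index + dt.timedelta(days=config.visit_interval_days)
    while visit < obs_end:
        dx_rows.append((pid, gpp, visit, True))
        visit += dt.timedelta(days=config.visit_interval_days)
    dx_rows.append((pid, gpp, obs_end, True))

    has_psv = rng.random() < config.psv_prevalence
    if has_psv:
        psv_day = index + dt.timedelta(days=int(rng.integers(-300, 301)))
        psv_day = min(max(psv_day, index - dt.timedelta(days=360)), obs_end)
        dx_rows.append((pid, study_config.psv_codes[0], psv_day, True))
    for code, prob in config.comorbidities:
        if rng.random() < prob:
            day = index - dt.timedelta(days=int(rng.integers(30, 361)))
            dx_rows.append((pid, code, day, True))

    patient_rows.append({"patient_id": pid, "sex": sex, "birth_year": birth_year,
                         "death_date": death_date})

    # ground truth
    pt = PatientTruth(pid, included=True, reason="ok",
                      index_date=index.isoformat(),
                      followup_end=obs_end.isoformat(),
                      death_date=death_date.isoformat() if death_date else None,
                      age_at_index=age, has_psv=has_psv)
    # death within the first year keeps the patient eligible; an untreated
    # patient (residual initial mass) is still included with zero lines
    for k, (name, start, end) in enumerate(lines):
        state = config.states[name]
        cats = sorted({catalog.classify(d).category2 for d in state.drugs})
        if k + 1 < len(lines):
            ttnt = (lines[k + 1][1] - start).days
            event = True
        else:
            ttnt = (obs_end - start).days
            event = False
        supp_here = any(s < end and start < e for s, e in supp_attachments)
        pt.lots.append(TrueLot(start.isoformat(), end.isoformat(), name, cats,
                               supp_here, max(ttnt, 1), event))
    _fill_episode_truth(pt, pid, rx_rows, catalog, study_config)
    truth.patients[pid] = pt
    all_rx_rows.extend(rx_rows)


def _fill_episode_truth(pt: PatientTruth, pid: str, rx_rows, catalog: Catalog,
                        study_config: StudyConfig) -> None:
    fills_by_drug: dict[str, list[tuple[dt.date, int]]] = {}
    for rpid, drug, date, supply in rx_rows:
        if rpid == pid:
            fills_by_drug.setdefault(drug, []).append((date, supply))
    pt.episodes = {}
    for drug, fills in sorted(fills_by_drug.items()):
        gap = study_config.gap_days(catalog.classify(drug).gap_class)
        override = study_config.gap_overrides_days.get(drug)
        if override is not None:
            gap = override
        pt.episodes[drug] = [
            (s.isoformat(), e.isoformat()) for s, e in _merge_days(fills, gap)]


def _emit_special(tag: str, config: ScenarioConfig, catalog: Catalog,
                  study_config: StudyConfig, patient_rows, dx_rows, rx_rows,
                  truth: GroundTruth) -> None:
    """Hand-built edge-case patients with documented expected outcomes."""
    window_start, _ = config.study_window
    gpp = study_config.gpp_codes[0]
    d0 = window_start + dt.timedelta(days=120)

    def day(n: int) -> dt.date:
        return d0 + dt.timedelta(days=n)

    def fills(pid, drug, start, end):
        interval, supply = _drug_cadence(config, catalog, drug)
        _emit_fills(rx_rows, pid, drug, start, end, interval, supply)

    pid = f"edge_{tag}"
    if tag == "single_dx":
        # one confirmed diagnosis only → excluded (single_gpp_diagnosis)
        patient_rows.append({"patient_id": pid, "sex": "female", "birth_year": 1970,
                             "death_date": None})
        dx_rows.append((pid, gpp, d0, True))
        fills(pid, "etretinate", d0, day(90))
        truth.patients[pid] = PatientTruth(pid, False, "single_gpp_diagnosis")
    elif tag == "short_followup":
        # 200 days of activity, alive → excluded (insufficient_followup)
        patient_rows.append({"patient_id": pid, "sex": "male", "birth_year": 1960,
                             "death_date": None})
        dx_rows += [(pid, gpp, d0, True), (pid, gpp, day(14), True),
                    (pid, gpp, day(200), True)]
        fills(pid, "etretinate", d0, day(180))
        truth.patients[pid] = PatientTruth(pid, False, "insufficient_followup")
    elif tag == "early_death":
        # died 200 days after index → included despite short follow-up
        patient_rows.append({"patient_id": pid, "sex": "male", "birth_year": 1945,
                             "death_date": day(200)})
        dx_rows += [(pid, gpp, d0, True), (pid, gpp, day(14), True),
                    (pid, gpp, day(200), True)]
        fills(pid, "etretinate", d0, day(200))
        pt = PatientTruth(pid, True, "ok", d0.isoformat(), day(200).isoformat(),
                          day(200).isoformat(), age_at_index=d0.year - 1945)
        pt.lots = [TrueLot(d0.isoformat(), day(200).isoformat(), "etretinate",
                           ["Etretinate"], False, 200, False)]
        _fill_episode_truth(pt, pid, rx_rows, catalog, study_config)
        truth.patients[pid] = pt
    elif tag == "same_day_combo":
        # three main drugs starting together → one combination line
        patient_rows.append({"patient_id": pid, "sex": "female", "birth_year": 1980,
                             "death_date": None})
        dx_rows += [(pid, gpp, d0, True), (pid, gpp, day(14), True),
                    (pid, gpp, day(300), True), (pid, gpp, day(600), True)]
        for drug in ("etretinate", "cyclosporin", "secukinumab"):
            fills(pid, drug, d0, day(300))
        pt = PatientTruth(pid, True, "ok", d0.isoformat(), day(600).isoformat(),
                          None, age_at_index=d0.year - 1980)
        pt.lots = [TrueLot(d0.isoformat(), day(300).isoformat(), "combo",
                           ["Cyclosporin", "Etretinate", "IL-17 inhibitors"],
                           False, 600, False)]
        _fill_episode_truth(pt, pid, rx_rows, catalog, study_config)
        truth.patients[pid] = pt
    elif tag == "single_fill":
        # one dispensing, long observation → one short episode, one line
        patient_rows.append({"patient_id": pid, "sex": "male", "birth_year": 1975,
                             "death_date": None})
        dx_rows += [(pid, gpp, d0, True), (pid, gpp, day(14), True),
                    (pid, gpp, day(500), True)]
        rx_rows.append((pid, "etretinate", d0, 30))
        pt = PatientTruth(pid, True, "ok", d0.isoformat(), day(500).isoformat(),
                          None, age_at_index=d0.year - 1975)
        pt.lots = [TrueLot(d0.isoformat(), day(30).isoformat(), "etretinate",
                           ["Etretinate"], False, 500, False)]
        _fill_episode_truth(pt, pid, rx_rows, catalog, study_config)
        truth.patients[pid] = pt
    else:
        raise ValueError(f"unknown special patient tag {tag!r}")


def _assemble_bundle(patient_rows, dx_rows, rx_rows, window) -> ClaimsBundle:
    patients = pd.DataFrame(patient_rows, columns=["patient_id", "sex", "birth_year", "death_date"])
    patients["death_date"] = pd.to_datetime(patients["death_date"])
    patients = patients.sort_values("patient_id").reset_index(drop=True)

    dx = pd.DataFrame(dx_rows, columns=["patient_id", "code", "date", "confirmed"])
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx.sort_values(["patient_id", "date", "code"], kind="mergesort").reset_index(drop=True)

    rx = pd.DataFrame(rx_rows, columns=["patient_id", "drug_code", "date", "days_supply"])
    rx["date"] = pd.to_datetime(rx["date"])
    rx["days_supply"] = rx["days_supply"].astype("Int64")
    rx = rx.sort_values(["patient_id", "drug_code", "date"], kind="mergesort").reset_index(drop=True)
    return ClaimsBundle(patients, dx, rx, window)


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------

class NoiseConfig(BaseModel):
    """Bounded perturbations of an emitted bundle.

    ``jitter_days`` shifts every dispensing forward by up to that many
    days; it must stay strictly below the smallest discontinuation gap so
    episode counts cannot change.  ``n_gaps`` punches that many
    supra-threshold holes (of ``gap_days``) into long oral-drug episodes,
    which must split them.
    """

    jitter_days: int = 0
    n_gaps: int = 0
    gap_days: int = 75

    @model_validator(mode="after")
    def _check(self) -> "NoiseConfig":
        if self.jitter_days < 0 or self.n_gaps < 0:
            raise ValueError("noise magnitudes must be non-negative")
        return self


def inject_noise(
    bundle: ClaimsBundle,
    truth: GroundTruth,
    noise: NoiseConfig,
    seed: int,
    catalog: Catalog | None = None,
    study_config: StudyConfig | None = None,
) -> tuple[ClaimsBundle, GroundTruth]:
    """Apply bounded noise; episode ground truth is re-derived, and gap
    injection into main drugs invalidates the line-of-therapy truth."""
    catalog = catalog or load_catalog()
    study_config = study_config or StudyConfig(study_window=bundle.study_window)
    min_gap = min(study_config.gap_days("oral"), study_config.gap_days("biologic"))
    if noise.jitter_days >= min_gap:
        raise ValueError(
            f"jitter_days={noise.jitter_days} crosses the smallest discontinuation "
            f"gap ({min_gap} d); relabel it as gap injection instead")

    rng = np.random.default_rng(seed)
    out = bundle.copy()
    new_truth = GroundTruth(truth.scenario, truth.seed,
                            {pid: _copy_patient(p) for pid, p in truth.patients.items()},
                            dict(truth.state_median_days), truth.lot_truth_valid)
    rx = out.prescriptions
    if not len(rx):
        return out, new_truth

    if noise.jitter_days > 0:
        shift = rng.integers(0, noise.jitter_days + 1, size=len(rx))
        rx["date"] = rx["date"] + pd.to_timedelta(shift, unit="D")
        new_truth.lot_truth_valid = False  # boundaries move by up to jitter_days

    if noise.n_gaps > 0:
        oral_gap = study_config.gap_days("oral")
        if noise.gap_days <= oral_gap:
            raise ValueError(
                f"gap_days={noise.gap_days} does not exceed the oral threshold "
                f"({oral_gap} d); a sub-threshold hole cannot split an episode")
        candidates = []
        for (pid, drug), grp in rx.groupby(["patient_id", "drug_code"], sort=True):
            cls = catalog.classify(str(drug))
            if cls.gap_class != "oral" or len(grp) < 5:
                continue
            candidates.append((str(pid), str(drug), grp.index.to_numpy()))
        rng.shuffle(candidates)
        dropped: list[np.ndarray] = []
        injected = 0
        for pid, drug, idx in candidates:
            if injected >= noise.n_gaps:
                break
            dates = rx.loc[idx].sort_values("date")
            cut = len(dates) // 2
            anchor_end = dates.iloc[cut - 1]["date"] + pd.Timedelta(
                days=int(dates.iloc[cut - 1]["days_supply"]))
            removable = dates.index[
                (dates["date"] >= anchor_end - pd.Timedelta(days=60))
                & (dates["date"] < anchor_end + pd.Timedelta(days=noise.gap_days))]
            remaining = dates.drop(index=removable)
            if len(remaining) < 2:
                continue
            after = remaining[remaining["date"] >= anchor_end]
            if not len(after):
                continue
            before = remaining[remaining["date"] < anchor_end]
            if not len(before):
                continue
            prev_end = (before["date"] + pd.to_timedelta(
                before["days_supply"].astype(int), unit="D")).max()
            if (after["date"].min() - prev_end).days <= oral_gap:
                continue
            dropped.append(removable.to_numpy())
            injected += 1
            new_truth.lot_truth_valid = False
        if dropped:
            rx = rx.drop(index=np.concatenate(dropped)).reset_index(drop=True)
            out.prescriptions = rx

    # re-derive episode truth from the perturbed dispensings
    rx_rows = [(str(r.patient_id), str(r.drug_code), r.date.date(), int(r.days_supply))
               for r in rx.itertuples()]
    for pid, pt in new_truth.patients.items():
        if pt.included:
            _fill_episode_truth(pt, pid, rx_rows, catalog, study_config)
    return out, new_truth


def _copy_patient(p: PatientTruth) -> PatientTruth:
    return PatientTruth(
        p.patient_id, p.included, p.reason, p.index_date, p.followup_end,
        p.death_date, p.age_at_index, p.has_psv,
        [TrueLot(**asdict(lot)) for lot in p.lots],
        {d: list(ivs) for d, ivs in p.episodes.items()},
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _exp(median_months: float) -> DurationDist:
    return DurationDist(dist="exponential", median_months=median_months)


PRESET_NAMES = ("simple_switching", "combinations", "bio_switch", "edge_cases")


def preset_scenarios(name: str, n_patients: int = 300, seed: int = 0) -> ScenarioConfig:
    """Named, fully specified scenario configurations.

    * ``simple_switching`` — monotherapy pathways with a first-line mix
      dominated by etretinate, cyclosporin, corticosteroids and topicals,
      switching toward biologics in later lines;
    * ``combinations`` — multi-drug regimens, add-ons, component
      discontinuations and supplementary attachments;
    * ``bio_switch`` — pathways ending in cross-class biologic-to-biologic
      transitions, some after an untreated spell;
    * ``edge_cases`` — hand-built boundary patients (single diagnosis,
      short follow-up, death within a year, same-day combination starts,
      a single dispensing) plus a regular background cohort.
    """
    if name == "simple_switching":
        states = {
            "etretinate": PathwayState(drugs=["etretinate"], duration=_exp(6.0),
                                       next={"cyclosporin": 0.35, "secukinumab": 0.3}),
            "cyclosporin": PathwayState(drugs=["cyclosporin"], duration=_exp(5.0),
                                        next={"etretinate": 0.25, "secukinumab": 0.35}),
            "corticosteroid": PathwayState(drugs=["systemic_corticosteroid"], duration=_exp(4.0),
                                           next={"etretinate": 0.4, "secukinumab": 0.2}),
            "topical": PathwayState(drugs=["topical_corticosteroid"], duration=_exp(5.0),
                                    next={"etretinate": 0.4, "cyclosporin": 0.2}),
            "secukinumab": PathwayState(drugs=["secukinumab"], duration=_exp(14.0),
                                        next={"guselkumab": 0.25}),
            "guselkumab": PathwayState(drugs=["guselkumab"], duration=_exp(12.0),
                                       next={}),
        }
        initial = {"etretinate": 0.3, "topical": 0.16, "cyclosporin": 0.16,
                   "corticosteroid": 0.16, "secukinumab": 0.12, "guselkumab": 0.07}
        return ScenarioConfig(name=name, n_patients=n_patients, seed=seed,
                              states=states, initial=initial, supplementary_prob=0.0)
    if name == "combinations":
        states = {
            "etr": PathwayState(drugs=["etretinate"], duration=_exp(6.0),
                                next={"etr_cs": 0.3, "cyc_etr": 0.3, "il17": 0.2}),
            "etr_cs": PathwayState(drugs=["etretinate", "systemic_corticosteroid"],
                                   duration=_exp(5.0), next={"il17": 0.3, "etr": 0.3}),
            "cyc_etr": PathwayState(drugs=["cyclosporin", "etretinate"],
                                    duration=_exp(4.0), next={"etr_cs": 0.3, "il17": 0.2}),
            "il17": PathwayState(drugs=["secukinumab"], duration=_exp(14.0),
                                 next={"il17_etr": 0.35}),
            "il17_etr": PathwayState(drugs=["secukinumab", "etretinate"],
                                     duration=_exp(10.0), next={}),
        }
        initial = {"etr": 0.3, "cyc_etr": 0.25, "etr_cs": 0.2, "il17": 0.2}
        return ScenarioConfig(name=name, n_patients=n_patients, seed=seed,
                              states=states, initial=initial, supplementary_prob=0.5)
    if name == "bio_switch":
        states = {
            "secukinumab": PathwayState(drugs=["secukinumab"], duration=_exp(14.0),
                                        next={"guselkumab": 0.4, "adalimumab": 0.25},
                                        gap_prob=0.3),
            "adalimumab": PathwayState(drugs=["adalimumab"], duration=_exp(12.0),
                                       next={"guselkumab": 0.35, "secukinumab": 0.2},
                                       gap_prob=0.3),
            "guselkumab": PathwayState(drugs=["guselkumab"], duration=_exp(12.0),
                                       next={"secukinumab": 0.25, "adalimumab": 0.15},
                                       gap_prob=0.3),
            "etretinate": PathwayState(drugs=["etretinate"], duration=_exp(5.0),
                                       next={"secukinumab": 0.5, "adalimumab": 0.3}),
        }
        initial = {"etretinate": 0.35, "secukinumab": 0.3, "adalimumab": 0.2,
                   "guselkumab": 0.15}
        return ScenarioConfig(name=name, n_patients=n_patients, seed=seed,
                              states=states, initial=initial, supplementary_prob=0.0)
    if name == "edge_cases":
        base = preset_scenarios("simple_switching", n_patients=n_patients, seed=seed)
        return base.model_copy(update={
            "name": name,
            "special_patients": ["single_dx", "short_followup", "early_death",
                                 "same_day_combo", "single_fill"],
        })
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


def lot_recovery(lots: pd.DataFrame, truth: GroundTruth) -> dict:
    """Compare a derived LOT table against generator ground truth.

    A patient matches when their derived line sequence equals the true one
    in line starts, regimen-category sets, event/censor flags and TTNT
    durations (and, for lines with main drugs, the supplementary flag).
    Returns counts plus per-patient mismatch descriptions.
    """
    from .catalog import SUPPLEMENTARY_CATEGORIES

    derived: dict[str, list[tuple]] = {}
    ttnt_rows: dict[str, list] = {}
    for pid, group in lots.groupby("patient_id", sort=False):
        group = group.sort_values("lot_number")
        seq = []
        starts = list(group["start"])
        for i, (_, row) in enumerate(group.iterrows()):
            if i + 1 < len(group):
                ttnt = (starts[i + 1] - row["start"]).days
                event = True
            else:
                ttnt = (row["followup_end"] - row["start"]).days
                event = False
            cats = frozenset(row["regimen_categories"].split(" | "))
            seq.append((row["start"].date().isoformat(), cats, event,
                        max(int(ttnt), 1), bool(row["supp_present"])))
        derived[str(pid)] = seq

    n_checked = 0
    mismatches: list[str] = []
    for pid, pt in truth.patients.items():
        if not pt.included:
            continue
        n_checked += 1
        want = [(lot.start, frozenset(lot.regimen_categories), lot.event,
                 max(lot.ttnt_days, 1), lot.supp_present) for lot in pt.lots]
        got = derived.get(pid, [])
        ok = len(want) == len(got)
        if ok:
            for w, g in zip(want, got):
                same = w[:4] == g[:4]
                has_main = bool(w[1] - SUPPLEMENTARY_CATEGORIES)
                if has_main:
                    same = same and (w[4] == g[4])
                if not same:
                    ok = False
                    break
        if not ok:
            mismatches.append(f"{pid}: expected {want}, derived {got}")
    return {
        "n_patients": n_checked,
        "n_matched": n_checked - len(mismatches),
        "fraction_matched": (n_checked - len(mismatches)) / n_checked if n_checked else 1.0,
        "mismatches": mismatches,
    }


def simulate_to_dir(preset: str, seed: int, out_dir: str | Path,
                    n_patients: int = 300) -> tuple[ClaimsBundle, GroundTruth]:
    """Write a preset's three CSVs plus groundtruth.json to a directory."""
    config = preset_scenarios(preset, n_patients=n_patients, seed=seed)
    bundle, truth = generate_cohort(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_claims_bundle(bundle, out_dir)
    truth.to_json(out_dir / "groundtruth.json")
    return bundle, truth
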