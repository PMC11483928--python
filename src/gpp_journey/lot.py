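"""Line-of-therapy (LOT) derivation from treatment episodes.

A patient's treated time is swept into *regimen states* — maximal
intervals with a constant set of concurrently active main and
supplementary treatment categories — and the states are folded into
numbered lines of therapy under these transition rules:

1. a main drug starting within the combination window of the current
   line's start joins the regimen (combination) without opening a line;
2. a main drug starting later, while the line is still active, opens a
   new line made of all then-active main drugs (add-on);
3. after all main drugs end, the next main-drug start opens a new line
   (switch), regardless of similarity;
4. discontinuing one component of a combination opens a new line of the
   remaining main drugs;
5. supplementary starts/stops never change the line while a main drug is
   active;
6. periods covered only by supplementary drugs form their own line;
7. an identical regimen resuming after an untreated spell no longer than
   the largest component gap threshold continues the same line; a longer
   spell ends the line at last coverage end.

Each line carries a *specific regimen* label (the sorted category
combination, with a "+ supplementary drug" suffix when supplementary
classes co-occur) and a *general regimen* label: the single member
category with the best (smallest) priority rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import Catalog
from .config import StudyConfig

SUPPLEMENTARY_SUFFIX = " + supplementary drug"


@dataclass(frozen=True)
class RegimenState:
    start: pd.Timestamp
    end: pd.Timestamp
    main: frozenset[str]  # active main category2 labels
    supp: frozenset[str]  # active supplementary category2 labels

    @property
    def duration_days(self) -> int:
        return int((self.end - self.start).days)


@dataclass
class LineOfTherapy:
    patient_id: str
    lot_number: int
    start: pd.Timestamp
    end: pd.Timestamp
    main_categories: frozenset[str]
    supp_categories: frozenset[str]
    supp_present: bool
    specific_regimen: str = ""
    general_regimen: str = ""
    is_last: bool = False

    @property
    def regimen_categories(self) -> frozenset[str]:
        """Categories defining the regimen: main set, or the supplementary
        set for supplementary-only lines."""
        return self.main_categories if self.main_categories else self.supp_categories


def build_regimen_timeline(
    episodes: pd.DataFrame,
    index_date: pd.Timestamp,
    followup_end: pd.Timestamp,
) -> list[RegimenState]:
    """Sweep-line partition of ``[index_date, followup_end)`` for one patient.

    Episodes are trimmed to the window; every episode boundary starts a new
    state; zero-drug spells appear as explicit untreated states.  The
    returned states tile the window exactly, and consecutive states differ
    in composition.
    """
    index_date = pd.Timestamp(index_date)
    followup_end = pd.Timestamp(followup_end)
    if followup_end <= index_date:
        return []

    spans: list[tuple[pd.Timestamp, pd.Timestamp, str, bool]] = []
    for _, ep in episodes.iterrows():
        start = max(pd.Timestamp(ep["start"]), index_date)
        end = min(pd.Timestamp(ep["end"]), followup_end)
        if end <= start:
            continue  # trimmed away entirely
        spans.append((start, end, ep["category2"], bool(ep["is_supplementary"])))

    cuts = sorted({index_date, followup_end, *(s for s, *_ in spans), *(e for _, e, *_ in spans)})
    states: list[RegimenState] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        main = frozenset(c for s, e, c, supp in spans if s <= lo < e and not supp)
        supp = frozenset(c for s, e, c, is_supp in spans if s <= lo < e and is_supp)
        if states and states[-1].main == main and states[-1].supp == supp:
            states[-1] = RegimenState(states[-1].start, hi, main, supp)
        else:
            states.append(RegimenState(lo, hi, main, supp))
    return states


def label_regimen(
    main_categories: frozenset[str] | set[str],
    supplementary,
    catalog: Catalog,
    apheresis_dominates: bool = False,
) -> tuple[str, str]:
    """(general, specific) labels for a regimen.

    ``supplementary`` is either a bool (supplementary classes co-occurred)
    or, for supplementary-only regimens, the set of supplementary
    categories themselves — the best-ranked one then stands in as the
    regimen member and any remaining ones trigger the suffix.
    """
    main = set(main_categories)
    if main:
        supp_present = bool(supplementary)
    else:
        supp_set = set(supplementary) if not isinstance(supplementary, bool) else set()
        if not supp_set:
            raise ValueError("cannot label an empty regimen")
        best = min(supp_set, key=catalog.category_priority)
        main = {best}
        supp_present = bool(supp_set - {best})

    if apheresis_dominates and "Apheresis/plasma exchange" in main:
        general = "Apheresis/plasma exchange"
    else:
        general = min(main, key=catalog.category_priority)
    specific = " + ".join(sorted(main))
    if supp_present:
        specific += SUPPLEMENTARY_SUFFIX
    return general, specific


def _regimen_gap_limit(categories: frozenset[str], catalog: Catalog, config: StudyConfig) -> int:
    """Largest component gap threshold of a regimen's categories."""
    if not categories:
        return config.gap_days("oral")
    return max(config.gap_days(catalog.category_gap_class(c)) for c in categories)


def derive_lots(
    timeline: list[RegimenState],
    patient_id: str,
    catalog: Catalog,
    config: StudyConfig,
) -> list[LineOfTherapy]:
    """Fold a regimen timeline into numbered lines of therapy."""
    lots: list[LineOfTherapy] = []
    cur: LineOfTherapy | None = None
    followup_end = timeline[-1].end if timeline else None

    def close(end: pd.Timestamp) -> None:
        nonlocal cur
        if cur is not None:
            cur.end = end
            lots.append(cur)
            cur = None

    def open_main(state: RegimenState) -> LineOfTherapy:
        return LineOfTherapy(
            patient_id, 0, state.start, state.end,
            main_categories=state.main,
            supp_categories=state.supp,
            supp_present=bool(state.supp),
        )

    for state in timeline:
        main, supp = state.main, state.supp
        if not main and not supp:
            # untreated spell: rule 7 — short spells keep the line open
            if cur is not None:
                limit = _regimen_gap_limit(cur.regimen_categories, catalog, config)
                if state.duration_days > limit:
                    close(state.start)
            continue

        if not main:
            # supplementary-only coverage (rule 6)
            if cur is not None and cur.main_categories:
                close(state.start)
            if cur is None:
                cur = LineOfTherapy(
                    patient_id, 0, state.start, state.end,
                    main_categories=frozenset(),
                    supp_categories=supp,
                    supp_present=True,
                )
            else:
                cur.supp_categories = cur.supp_categories | supp
            continue

        if cur is None:
            cur = open_main(state)
        elif not cur.main_categories:
            # supplementary-only line ends when a main drug starts
            close(state.start)
            cur = open_main(state)
        else:
            active = cur.main_categories
            if main == active:
                pass  # composition unchanged (supplementary churn, rule 5)
            elif (main > active
                  and (state.start - cur.start).days <= config.combination_window_days):
                cur.main_categories = main  # rule 1: late joiner within window
            else:
                # rules 2/3/4: add-on, switch, or component discontinuation
                close(state.start)
                cur = open_main(state)
        cur.supp_present = cur.supp_present or bool(supp)
        cur.supp_categories = cur.supp_categories | supp

    if cur is not None and followup_end is not None:
        close(followup_end)  # last line stays open to end of follow-up

    for i, lot in enumerate(lots, start=1):
        lot.lot_number = i
        lot.general_regimen, lot.specific_regimen = "", ""
        general, specific = label_regimen(
            lot.main_categories,
            lot.supp_present if lot.main_categories else lot.supp_categories,
            catalog,
            apheresis_dominates=config.apheresis_dominates,
        )
        lot.general_regimen, lot.specific_regimen = general, specific
        lot.is_last = i == len(lots)
    return lots


LOT_COLUMNS = [
    "patient_id", "lot_number", "start", "end", "specific_regimen",
    "general_regimen", "regimen_categories", "supp_present", "is_last",
    "followup_end",
]


def derive_lot_table(
    episodes: pd.DataFrame,
    cohort: pd.DataFrame,
    catalog: Catalog,
    config: StudyConfig,
) -> pd.DataFrame:
    """LOT table for every included cohort patient.

    ``regimen_categories`` holds the defining category set as a sorted
    " | "-joined string; ``followup_end`` is carried along for censoring.
    """
    included = cohort[cohort["included"]]
    eps_by_pid = dict(tuple(episodes.groupby("patient_id", sort=False))) if len(episodes) else {}
    empty = episodes.iloc[0:0]

    rows = []
    for _, pat in included.iterrows():
        pid = str(pat["patient_id"])
        timeline = build_regimen_timeline(
            eps_by_pid.get(pid, empty), pat["index_date"], pat["followup_end"])
        for lot in derive_lots(timeline, pid, catalog, config):
            rows.append({
                "patient_id": pid,
                "lot_number": lot.lot_number,
                "start": lot.start,
                "end": lot.end,
                "specific_regimen": lot.specific_regimen,
                "general_regimen": lot.general_regimen,
                "regimen_categories": " | ".join(sorted(lot.regimen_categories)),
                "supp_present": lot.supp_present,
                "is_last": lot.is_last,
                "followup_end": pat["followup_end"],
            })
    if not rows:
        return pd.DataFrame(columns=LOT_COLUMNS)
    return (pd.DataFrame(rows, columns=LOT_COLUMNS)
            .sort_values(["patient_id", "lot_number"]).reset_index(drop=True))


def write_lots(lots: pd.DataFrame, path) -> None:
    out = lots.copy()
    for col in ("start", "end", "followup_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
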