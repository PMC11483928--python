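"""Descriptive treatment-pattern surfaces.

Sankey-style flows between general regimens across successive lines of
therapy, combination-frequency tables (which partner classes overlap a
drug class's episodes), and bio-switching matrices (after the last
episode of each biologic, which different biologic is started next).
All results are plain frames; plotting lives in :mod:`gpp_journey.plotting`
and never originates numbers.
"""

from __future__ import annotations

import pandas as pd

from .catalog import Catalog

NO_FURTHER_THERAPY = "No further therapy"

STRATA = ("all", "psv", "no_psv", "age65", "age75")


def stratum_patients(cohort: pd.DataFrame, stratum: str) -> set[str]:
    """Patient ids of an included-cohort stratum."""
    inc = cohort[cohort["included"]]
    if stratum == "all":
        sel = inc
    elif stratum == "psv":
        sel = inc[inc["has_psv"].astype(bool)]
    elif stratum == "no_psv":
        sel = inc[~inc["has_psv"].astype(bool)]
    elif stratum == "age65":
        sel = inc[inc["age_ge_65"].astype(bool)]
    elif stratum == "age75":
        sel = inc[inc["age_ge_75"].astype(bool)]
    else:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    return set(sel["patient_id"].astype(str))


def sankey_flows(
    lots: pd.DataFrame,
    depth: int = 3,
    cohort: pd.DataFrame | None = None,
    stratum: str = "all",
) -> pd.DataFrame:
    """Patient flows between general regimens over the first ``depth`` lines.

    For each line k < depth, counts patients by (regimen at line k →
    regimen at line k+1), with an explicit terminal sink for patients who
    have no line k+1.  Outflows from a regimen at line k therefore sum to
    that regimen's patient count at line k.
    """
    if depth < 2:
        raise ValueError("depth must be at least 2")
    columns = ["line", "from_regimen", "to_regimen", "n"]
    if not len(lots):
        return pd.DataFrame(columns=columns)
    df = lots
    if cohort is not None and stratum != "all":
        keep = stratum_patients(cohort, stratum)
        df = df[df["patient_id"].astype(str).isin(keep)]

    by_line = df.pivot_table(
        index="patient_id", columns="lot_number", values="general_regimen",
        aggfunc="first")
    rows = []
    for line in range(1, depth):
        if line not in by_line.columns:
            break
        cur = by_line[line].dropna()
        nxt = by_line[line + 1] if (line + 1) in by_line.columns else pd.Series(dtype=object)
        nxt = nxt.reindex(cur.index).fillna(NO_FURTHER_THERAPY)
        counts = (pd.DataFrame({"from_regimen": cur, "to_regimen": nxt})
                  .value_counts().reset_index(name="n"))
        counts.insert(0, "line", line)
        rows.append(counts)
    if not rows:
        return pd.DataFrame(columns=columns)
    return (pd.concat(rows, ignore_index=True)
            .sort_values(["line", "from_regimen", "to_regimen"])
            .reset_index(drop=True)[columns])


def combination_frequencies(
    episodes: pd.DataFrame,
    anchors: list[str],
    catalog: Catalog,
    partner_level: str = "category2",
) -> pd.DataFrame:
    """Co-prescription percentages among patients exposed to each anchor class.

    An exposed patient counts toward a partner when any partner episode
    overlaps any anchor episode by at least one day.  ``anchors`` are
    category2 labels; partners are reported at ``category2`` or
    ``drug_code`` level.
    """
    known = set(catalog.priority_table)
    for anchor in anchors:
        if anchor not in known:
            raise ValueError(f"unknown anchor category {anchor!r}")
    if partner_level not in {"category2", "drug_code"}:
        raise ValueError("partner_level must be 'category2' or 'drug_code'")
    columns = ["anchor", "partner", "n_exposed", "n_with_partner", "pct"]
    rows = []
    for anchor in anchors:
        anchor_eps = episodes[episodes["category2"] == anchor]
        exposed = sorted(anchor_eps["patient_id"].astype(str).unique())
        partners = episodes[episodes["category2"] != anchor]
        partner_values = sorted(partners[partner_level].astype(str).unique())
        hits = {p: 0 for p in partner_values}
        for pid in exposed:
            a = anchor_eps[anchor_eps["patient_id"] == pid]
            b = partners[partners["patient_id"] == pid]
            if not len(b):
                continue
            seen = set()
            for _, ae in a.iterrows():
                overlap = b[(b["start"] < ae["end"]) & (ae["start"] < b["end"])]
                # half-open intervals: strict inequalities give >= 1 day overlap
                seen.update(overlap[partner_level].astype(str))
            for p in seen:
                hits[p] += 1
        for p in partner_values:
            if hits[p] == 0:
                continue
            rows.append({
                "anchor": anchor, "partner": p,
                "n_exposed": len(exposed), "n_with_partner": hits[p],
                "pct": 100.0 * hits[p] / len(exposed) if exposed else 0.0,
            })
        if not partner_values and exposed:
            rows.append({"anchor": anchor, "partner": None,
                         "n_exposed": len(exposed), "n_with_partner": 0, "pct": 0.0})
    return pd.DataFrame(rows, columns=columns)


def bioswitch_matrix(
    episodes: pd.DataFrame,
    catalog: Catalog,
    cohort: pd.DataFrame,
    stratum: str = "all",
    max_window_days: int | None = None,
) -> pd.DataFrame:
    """Switching from each biologic to the next different biologic.

    For every recipient of an index biologic, take their last episode of
    it; the switch destination is the first *different* biologic drug with
    an episode starting after that episode ends and before the patient's
    follow-up end (optionally within ``max_window_days``).  Patients with
    no such start are non-switchers.  Destinations are tallied by
    biologic class (category2).
    """
    keep = stratum_patients(cohort, stratum)
    fend = (cohort[cohort["included"]]
            .assign(patient_id=lambda d: d["patient_id"].astype(str))
            .set_index("patient_id")["followup_end"])
    bio = episodes[
        episodes["category1"].eq("Biologics")
        & episodes["patient_id"].astype(str).isin(keep)
    ]
    columns = ["index_biologic", "n_treated", "n_switched", "dest_class", "n_dest"]
    rows = []
    for drug in sorted(bio["drug_code"].unique()):
        drug_eps = bio[bio["drug_code"] == drug]
        dest_counts: dict[str, int] = {}
        n_treated = 0
        n_switched = 0
        for pid, group in drug_eps.groupby("patient_id"):
            n_treated += 1
            last_end = group["end"].max()
            later = bio[
                (bio["patient_id"] == pid)
                & (bio["drug_code"] != drug)
                & (bio["start"] > last_end)
            ]
            if pid in fend.index:
                later = later[later["start"] < fend.loc[pid]]
            if max_window_days is not None:
                later = later[(later["start"] - last_end).dt.days <= max_window_days]
            if not len(later):
                continue
            first = later.sort_values(["start", "drug_code"]).iloc[0]
            n_switched += 1
            dest = str(first["category2"])
            dest_counts[dest] = dest_counts.get(dest, 0) + 1
        if n_treated == 0:
            continue
        if dest_counts:
            for dest, n in sorted(dest_counts.items()):
                rows.append({"index_biologic": drug, "n_treated": n_treated,
                             "n_switched": n_switched, "dest_class": dest, "n_dest": n})
        else:
            rows.append({"index_biologic": drug, "n_treated": n_treated,
                         "n_switched": 0, "dest_class": None, "n_dest": 0})
    return pd.DataFrame(rows, columns=columns)
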