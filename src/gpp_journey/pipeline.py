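"""End-to-end analysis pipeline: bundle → cohort → episodes → lines → reports.

``run_pipeline`` ties the stages together exactly as the documented
conventions prescribe: eligibility and follow-up first, then per-patient
treatment episodes restricted to each patient's observation window, the
line-of-therapy derivation, and finally the survival and pattern tables.
``write_reports`` emits deterministic CSVs so that identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import BIOLOGIC_CATEGORIES, Catalog, load_catalog
from .cohort import build_cohort, write_cohort
from .config import StudyConfig
from .episodes import build_episodes, write_episodes
from .lot import derive_lot_table, write_lots
from .model import ClaimsBundle
from .patterns import bioswitch_matrix, combination_frequencies, sankey_flows
from .survival import drug_survival_table, ttnt_table

COMBINATION_ANCHORS = sorted(BIOLOGIC_CATEGORIES) + [
    "Apheresis/plasma exchange", "Cyclosporin", "Etretinate", "Methotrexate",
]


@dataclass
class PipelineResults:
    cohort: pd.DataFrame
    episodes: pd.DataFrame
    lots: pd.DataFrame
    ttnt_by_line: pd.DataFrame
    ttnt_all: pd.DataFrame
    ttnt_by_regimen: pd.DataFrame
    drug_survival: pd.DataFrame
    sankey: pd.DataFrame
    bioswitch: pd.DataFrame
    combinations: pd.DataFrame
    extras: dict = field(default_factory=dict)


def restrict_to_followup(
    prescriptions: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Keep dispensings of included patients dated within [index, follow-up end)."""
    included = cohort[cohort["included"]][["patient_id", "index_date", "followup_end"]]
    merged = prescriptions.merge(included, on="patient_id", how="inner")
    keep = (merged["date"] >= merged["index_date"]) & (merged["date"] < merged["followup_end"])
    return merged.loc[keep, prescriptions.columns].reset_index(drop=True)


def run_pipeline(
    bundle: ClaimsBundle,
    catalog: Catalog | None = None,
    config: StudyConfig | None = None,
) -> PipelineResults:
    catalog = catalog or load_catalog()
    config = config or StudyConfig(study_window=bundle.study_window)

    cohort = build_cohort(bundle, config)
    rx = restrict_to_followup(bundle.prescriptions, cohort)
    episodes = build_episodes(rx, catalog, config)
    lots = derive_lot_table(episodes, cohort, catalog, config)

    fend = (cohort[cohort["included"]]
            .assign(patient_id=lambda d: d["patient_id"].astype(str))
            .set_index("patient_id")["followup_end"])
    results = PipelineResults(
        cohort=cohort,
        episodes=episodes,
        lots=lots,
        ttnt_by_line=ttnt_table(lots, config, "by_line"),
        ttnt_all=ttnt_table(lots, config, "all_lines"),
        ttnt_by_regimen=ttnt_table(lots, config, "by_specific_regimen"),
        drug_survival=drug_survival_table(episodes, config, followup_end=fend),
        sankey=sankey_flows(lots, depth=3, cohort=cohort, stratum="all"),
        bioswitch=bioswitch_matrix(episodes, catalog, cohort),
        combinations=combination_frequencies(episodes, COMBINATION_ANCHORS, catalog),
    )
    return results


def write_reports(results: PipelineResults, out_dir: str | Path) -> dict[str, Path]:
    """Write every result table as CSV; float formatting is fixed so the
    output is reproducible byte for byte."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        paths[name] = out_dir / f"{name}.csv"
        df.to_csv(paths[name], index=False, float_format="%.6g")

    write_cohort(results.cohort, out_dir / "cohort.csv")
    paths["cohort"] = out_dir / "cohort.csv"
    write_episodes(results.episodes, out_dir / "episodes.csv")
    paths["episodes"] = out_dir / "episodes.csv"
    write_lots(results.lots, out_dir / "lots.csv")
    paths["lots"] = out_dir / "lots.csv"
    emit("ttnt_by_line", results.ttnt_by_line)
    emit("ttnt_all", results.ttnt_all)
    emit("ttnt_by_regimen", results.ttnt_by_regimen)
    emit("drug_survival", results.drug_survival)
    emit("sankey", results.sankey)
    emit("bioswitch", results.bioswitch)
    emit("combinations", results.combinations)
    return paths
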