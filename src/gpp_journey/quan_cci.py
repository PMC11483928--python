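"""Charlson comorbidity index from ICD-10 codes via the Quan coding algorithm.

Seventeen condition groups are detected by ICD-10 prefix match (codes are
normalised by removing the dot, so ``I25.2`` and ``I252`` are equivalent).
Each group scores its original Charlson weight at most once, and the usual
hierarchy applies: metastatic solid tumour supersedes any malignancy,
moderate/severe liver disease supersedes mild, and complicated diabetes
supersedes uncomplicated.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from typing import Iterable

#: (superior, suppressed) — if both groups match, only the superior scores.
_HIERARCHY = (
    ("metastatic_solid_tumor", "any_malignancy"),
    ("moderate_severe_liver_disease", "mild_liver_disease"),
    ("diabetes_with_complication", "diabetes_without_complication"),
)


@lru_cache(maxsize=1)
def condition_table() -> dict[str, tuple[int, tuple[str, ...]]]:
    """condition → (weight, ICD-10 prefixes), loaded from the shipped table."""
    source = resources.files("gpp_journey.data").joinpath("quan_cci_icd10.csv")
    table: dict[str, tuple[int, tuple[str, ...]]] = {}
    for row in csv.DictReader(source.read_text(encoding="utf-8").splitlines()):
        table[row["condition"]] = (
            int(row["weight"]),
            tuple(row["prefixes"].split(";")),
        )
    return table


def normalise_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def detect_conditions(codes: Iterable[str]) -> set[str]:
    """Condition groups present in a code list, after hierarchy resolution."""
    norm = {normalise_code(c) for c in codes if str(c).strip()}
    found: set[str] = set()
    for condition, (_w, prefixes) in condition_table().items():
        if any(code.startswith(p) for p in prefixes for code in norm):
            found.add(condition)
    for superior, suppressed in _HIERARCHY:
        if superior in found:
            found.discard(suppressed)
    return found


def compute_cci_quan(codes: Iterable[str]) -> int:
    """Charlson score: sum of weights over detected (hierarchy-resolved) groups."""
    table = condition_table()
    return sum(table[c][0] for c in detect_conditions(codes))
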