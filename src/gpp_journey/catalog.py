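"""Drug catalog: treatment categories, prioritization and gap classes.

The catalog encodes the twelve treatment categories used to label
regimens, their priority ranks (1 = strongest claim to name a combination
regimen), which classes are merely *supplementary* (topicals, other oral
medications, arthritis treatments — their starts and stops never change a
combination line of therapy), each drug's discontinuation-gap class and a
default coverage duration used when a dispensing carries no days-supply.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .config import StudyConfig

CATEGORY2_PRIORITY: dict[str, int] = {
    "IL-17 inhibitors": 1,
    "TNF-α inhibitors": 2,
    "IL-23 inhibitors": 3,
    "Etretinate": 4,
    "Cyclosporin": 5,
    "Apheresis/plasma exchange": 6,
    "Systemic corticosteroids": 7,
    "Apremilast": 8,
    "Methotrexate": 9,
    "Topical therapy": 10,
    "Other oral medications": 11,
    "Arthritis treatment": 12,
}

SUPPLEMENTARY_CATEGORIES = frozenset(
    {"Topical therapy", "Other oral medications", "Arthritis treatment"}
)

BIOLOGIC_CATEGORIES = frozenset(
    {"IL-17 inhibitors", "TNF-α inhibitors", "IL-23 inhibitors"}
)

CATEGORY1_VALUES = frozenset({
    "Biologics",
    "Systemic oral medications",
    "Apheresis/plasma exchange",
    "Topical therapy",
    "Arthritis treatment",
})

GAP_CLASSES = frozenset({"biologic", "oral", "other"})


@dataclass(frozen=True)
class DrugClass:
    drug_code: str
    drug_name: str
    category1: str
    category2: str
    priority: int
    is_supplementary: bool
    gap_class: str
    default_coverage_days: int


class CatalogError(ValueError):
    """Raised for malformed catalogs (duplicate codes, broken priority map)."""


class UnknownDrugError(KeyError):
    """Raised in strict mode when a drug code is absent from the catalog."""


#: Fallback classification for codes absent from the catalog (lenient mode).
FALLBACK_CLASS = DrugClass(
    drug_code="<unknown>",
    drug_name="Unclassified medication",
    category1="Systemic oral medications",
    category2="Other oral medications",
    priority=CATEGORY2_PRIORITY["Other oral medications"],
    is_supplementary=True,
    gap_class="oral",
    default_coverage_days=30,
)


@dataclass
class Catalog:
    entries: dict[str, DrugClass]
    priority_table: dict[str, int]

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        if sorted(self.priority_table.values()) != list(range(1, 13)):
            raise CatalogError("priority table must map the 12 categories onto 1..12")
        if set(self.priority_table) != set(CATEGORY2_PRIORITY):
            raise CatalogError("priority table must cover exactly the 12 treatment categories")
        for code, entry in self.entries.items():
            if entry.category2 not in self.priority_table:
                raise CatalogError(f"{code}: unknown category2 {entry.category2!r}")
            if entry.priority != self.priority_table[entry.category2]:
                raise CatalogError(
                    f"{code}: priority {entry.priority} contradicts "
                    f"{entry.category2!r} → {self.priority_table[entry.category2]}")
            if entry.is_supplementary != (entry.category2 in SUPPLEMENTARY_CATEGORIES):
                raise CatalogError(f"{code}: is_supplementary inconsistent with category2")
            if (entry.gap_class == "biologic") != (entry.category1 == "Biologics"):
                raise CatalogError(f"{code}: gap_class must be 'biologic' iff category1 is Biologics")
            if entry.gap_class not in GAP_CLASSES:
                raise CatalogError(f"{code}: unknown gap_class {entry.gap_class!r}")
            if entry.default_coverage_days <= 0:
                raise CatalogError(f"{code}: default_coverage_days must be positive")

    # -- queries -------------------------------------------------------

    def classify(self, drug_code: str, strict: bool = False) -> DrugClass:
        try:
            return self.entries[drug_code]
        except KeyError:
            if strict:
                raise UnknownDrugError(drug_code) from None
            return replace(FALLBACK_CLASS, drug_code=drug_code)

    def category_priority(self, category2: str) -> int:
        return self.priority_table[category2]

    def category_gap_class(self, category2: str) -> str:
        return "biologic" if category2 in BIOLOGIC_CATEGORIES else "oral"

    def drug_codes(self) -> list[str]:
        return sorted(self.entries)

    def biologic_codes(self) -> list[str]:
        return sorted(c for c, e in self.entries.items() if e.category1 == "Biologics")

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        fields = ["drug_code", "drug_name", "category1", "category2", "priority",
                  "is_supplementary", "gap_class", "default_coverage_days"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for code in sorted(self.entries):
                e = self.entries[code]
                writer.writerow({
                    "drug_code": e.drug_code, "drug_name": e.drug_name,
                    "category1": e.category1, "category2": e.category2,
                    "priority": e.priority, "is_supplementary": e.is_supplementary,
                    "gap_class": e.gap_class,
                    "default_coverage_days": e.default_coverage_days,
                })


def _parse_bool(v: str) -> bool:
    return str(v).strip().lower() in {"true", "1", "yes", "t"}


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load a drug catalog from CSV, or the embedded default when ``path`` is None.

    The default catalog reproduces the twelve-category prioritization and
    covers the named drugs of the reference treatment landscape (the three
    IL-17, three TNF-α and three IL-23 inhibitors, etretinate, cyclosporin,
    methotrexate, apremilast, systemic corticosteroids, antihistamines,
    immunosuppressants, topical agents, apheresis, arthritis treatment).
    """
    if path is None:
        source = resources.files("gpp_journey.data").joinpath("default_catalog.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")

    entries: dict[str, DrugClass] = {}
    for row in csv.DictReader(text.splitlines()):
        code = row["drug_code"].strip()
        if code in entries:
            raise CatalogError(f"duplicate drug_code {code!r}")
        entries[code] = DrugClass(
            drug_code=code,
            drug_name=row["drug_name"].strip(),
            category1=row["category1"].strip(),
            category2=row["category2"].strip(),
            priority=int(row["priority"]),
            is_supplementary=_parse_bool(row["is_supplementary"]),
            gap_class=row["gap_class"].strip(),
            default_coverage_days=int(row["default_coverage_days"]),
        )
    # the priority map implied by the file must be a function …
    implied: dict[str, int] = {}
    for e in entries.values():
        if e.category2 in implied and implied[e.category2] != e.priority:
            raise CatalogError(f"category {e.category2!r} assigned two priorities")
        implied[e.category2] = e.priority
    # … and is completed from the canonical table for categories with no drug
    table = dict(CATEGORY2_PRIORITY)
    for cat, pri in implied.items():
        if cat not in table:
            raise CatalogError(f"unknown category2 {cat!r}")
        table[cat] = pri
    if sorted(table.values()) != list(range(1, 13)):
        raise CatalogError("catalog priorities are not a bijection onto 1..12")
    return Catalog(entries=entries, priority_table=table)


def classify_drug(catalog: Catalog, drug_code: str, strict: bool = False) -> DrugClass:
    """Resolve a drug code to its class; unknown codes fall back to
    supplementary 'Other oral medications' unless ``strict``."""
    return catalog.classify(drug_code, strict=strict)


def gap_threshold_days(drug_class: DrugClass, config: StudyConfig) -> int:
    """Discontinuation gap for a drug: 3 months for biologics, 2 months
    otherwise (both via the configured month length), with per-drug
    overrides taking precedence."""
    override = config.gap_overrides_days.get(drug_class.drug_code)
    if override is not None:
        return int(override)
    return config.gap_days(drug_class.gap_class)
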