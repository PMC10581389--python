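"""Drug → torsades-de-pointes risk-category catalog.

The first step of the QTc-prolongation algorithm classifies the proposed
drug by its TdP risk, following the public CredibleMeds-style scheme of
*known*, *possible* and *conditional* risk categories.  The engine works
from a local, versioned catalog file rather than a live web lookup, so a
site can drop in its own export; a small illustrative fixture ships with
the package.

Name matching is exact on the canonical (trimmed, case-folded) form plus
explicit synonyms.  There is deliberately no fuzzy matching: a near-miss
silently resolving to the wrong drug is a patient-safety hazard in a
decision-support tool, whereas an unrecognised name surfaces visibly as
``NOT_LISTED``.
"""

from __future__ import annotations

import json
from collections import Counter
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "RiskCategory",
    "CatalogEntry",
    "RiskCatalog",
    "CatalogError",
    "load_catalog",
    "load_default_catalog",
    "classify_drug",
    "count_qt_drugs",
    "canonical_name",
]


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog files."""


class RiskCategory(str, Enum):
    """TdP risk category in the CredibleMeds-style classification."""

    KNOWN_RISK = "KNOWN_RISK"
    POSSIBLE_RISK = "POSSIBLE_RISK"
    CONDITIONAL_RISK = "CONDITIONAL_RISK"
    NOT_LISTED = "NOT_LISTED"


def canonical_name(name: str) -> str:
    """Canonical form used for all catalog matching: trimmed, case-folded."""
    return name.strip().casefold()


class CatalogEntry(BaseModel):
    drug_name: str
    risk_category: RiskCategory
    synonyms: tuple[str, ...] = ()

    @field_validator("drug_name")
    @classmethod
    def _canonical_nonempty(cls, v: str) -> str:
        v = canonical_name(v)
        if not v:
            raise ValueError("drug_name must be non-empty")
        return v

    @field_validator("synonyms", mode="before")
    @classmethod
    def _canonical_synonyms(cls, v) -> tuple[str, ...]:
        if v is None:
            return ()
        return tuple(canonical_name(s) for s in v if canonical_name(s))


class RiskCatalog(BaseModel):
    """Lookup table from drug name (or synonym) to risk category.

    Lookup of any name returns exactly one category; absent names map to
    :attr:`RiskCategory.NOT_LISTED` rather than raising.
    """

    entries: tuple[CatalogEntry, ...]
    source_label: str = "unspecified"
    version_tag: str = "0"

    _index: dict[str, RiskCategory] = {}

    def model_post_init(self, __context) -> None:
        index: dict[str, RiskCategory] = {}
        for entry in self.entries:
            for name in (entry.drug_name, *entry.synonyms):
                if name in index:
                    raise CatalogError(f"duplicate drug name or synonym: {name!r}")
                index[name] = entry.risk_category
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, name: str) -> RiskCategory:
        key = canonical_name(name)
        if not key:
            raise ValueError("drug name query must be non-empty")
        return self._index.get(key, RiskCategory.NOT_LISTED)


def _parse_entry(record: Mapping[str, object], where: str) -> CatalogEntry:
    try:
        raw_cat = str(record["risk_category"]).strip().upper()
        category = RiskCategory(raw_cat)
    except KeyError:
        raise CatalogError(f"{where}: missing risk_category")
    except ValueError:
        raise CatalogError(
            f"{where}: unknown risk category {record.get('risk_category')!r}"
        )
    name = record.get("drug_name")
    if not name or not str(name).strip():
        raise CatalogError(f"{where}: missing drug_name")
    return CatalogEntry(
        drug_name=str(name),
        risk_category=category,
        synonyms=tuple(record.get("synonyms") or ()),
    )


def load_catalog(
    path: str | Path,
    format: Optional[str] = None,
    source_label: Optional[str] = None,
    version_tag: str = "0",
) -> RiskCatalog:
    """Load a risk catalog from a TSV or JSON file.

    TSV layout: header ``drug_name<TAB>risk_category<TAB>synonyms`` with
    synonyms ``;``-separated (third column optional).  JSON layout: array
    of objects with the same keys.  Format is inferred from the suffix
    when not given.  Duplicate names (including via synonyms) are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"catalog file not found: {path}")
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt not in ("tsv", "json"):
        raise CatalogError(f"unsupported catalog format: {fmt!r}")
    text = path.read_text(encoding="utf-8")
    entries: list[CatalogEntry] = []
    if fmt == "json":
        try:
            records = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CatalogError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(records, list):
            raise CatalogError(f"{path}: JSON catalog must be an array of objects")
        for i, rec in enumerate(records):
            entries.append(_parse_entry(rec, f"{path} entry {i}"))
    else:
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise CatalogError(f"{path}: empty catalog")
        header = [c.strip() for c in lines[0].split("\t")]
        if header[:2] != ["drug_name", "risk_category"]:
            raise CatalogError(
                f"{path}: TSV header must start with drug_name<TAB>risk_category"
            )
        for row_no, line in enumerate(lines[1:], start=2):
            cells = line.split("\t")
            if len(cells) < 2:
                raise CatalogError(f"{path} row {row_no}: expected at least 2 columns")
            record: dict[str, object] = {
                "drug_name": cells[0],
                "risk_category": cells[1],
            }
            if len(cells) > 2 and cells[2].strip():
                record["synonyms"] = [s for s in cells[2].split(";") if s.strip()]
            entries.append(_parse_entry(record, f"{path} row {row_no}"))
    try:
        return RiskCatalog(
            entries=tuple(entries),
            source_label=source_label or str(path),
            version_tag=version_tag,
        )
    except ValueError as exc:
        if "duplicate" in str(exc):
            raise CatalogError(f"{path}: duplicate drug name or synonym") from exc
        raise


def load_default_catalog() -> RiskCatalog:
    """Load the illustrative fixture catalog bundled with the package.

    The fixture is a synthetic example resembling the public TdP risk
    classification; it is not a clinically complete or authoritative list.
    """
    ref = resources.files("qtcipa.data").joinpath("fixture_catalog.tsv")
    with resources.as_file(ref) as p:
        return load_catalog(p, source_label="qtcipa fixture (synthetic)", version_tag="fixture-1")


def classify_drug(catalog: RiskCatalog, name: str) -> RiskCategory:
    """Classify a drug by name; case-insensitive and synonym-aware.

    Absent drugs return ``NOT_LISTED`` and never raise; an empty query is
    a data-entry error and does raise.
    """
    return catalog.lookup(name)


def count_qt_drugs(
    catalog: RiskCatalog, medications: Iterable[str]
) -> dict[RiskCategory, int]:
    """Count a medication list by risk category.

    Counts partition the list: every medication lands in exactly one
    category and repeated listings are counted each time.
    """
    counts: Counter[RiskCategory] = Counter()
    for med in medications:
        counts[classify_drug(catalog, med)] += 1
    return {cat: counts.get(cat, 0) for cat in RiskCategory}
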