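"""Item banks and symptom catalogs.

An :class:`ItemBank` holds the pooled items of all questionnaires of one
diagnostic domain; a :class:`SymptomCatalog` holds the ordered list of core
symptom labels for that domain.  All downstream stages (embedding, expert
consensus, prompted assignment, agreement, overlap) consume these two types.

File formats
------------
Item bank CSV/TSV columns (header required, UTF-8)::

    domain, questionnaire_id, questionnaire_name, item_id, text,
    rating_type, excluded

``rating_type`` is one of ``SR``, ``OR``, ``SR+OR`` (``SR, OR`` is also
accepted); ``excluded`` is 0/1.  ``item_id`` and ``questionnaire_name`` may
be omitted: item ids are generated as ``<questionnaire_id>:<ordinal>`` with
1-based ordinals, names default to the id.  A JSON item bank is a list of
records with the same keys.  A symptom catalog is a one-column CSV (header
``symptom``) or a JSON array of strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._text import normalize_label
from .errors import EmptyResultError, ValidationError

RATING_TYPES = frozenset({"SR", "OR"})

_BANK_COLUMNS = ["domain", "questionnaire_id", "questionnaire_name",
                 "item_id", "text", "rating_type", "excluded"]


@dataclass(frozen=True)
class Item:
    """One element of a questionnaire a respondent or observer answers."""

    item_id: str
    questionnaire_id: str
    text: str
    rating_types: frozenset[str] = frozenset({"SR"})
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.rating_types or not self.rating_types <= RATING_TYPES:
            raise ValidationError(
                f"item {self.item_id!r}: rating_types must be a non-empty "
                f"subset of {sorted(RATING_TYPES)}, got {sorted(self.rating_types)}")
        if not self.excluded and not self.text.strip():
            raise ValidationError(f"item {self.item_id!r}: empty text on a non-excluded item")


@dataclass(frozen=True)
class Questionnaire:
    """Per-questionnaire metadata."""

    questionnaire_id: str
    name: str
    rating_types: frozenset[str]


@dataclass
class SymptomCatalog:
    """Ordered list of core-symptom labels for one diagnostic domain."""

    domain: str
    symptoms: list[str]

    def __post_init__(self) -> None:
        if not self.symptoms:
            raise ValidationError(f"symptom catalog for {self.domain!r} is empty")
        seen: dict[str, str] = {}
        for label in self.symptoms:
            key = normalize_label(label)
            if key in seen:
                raise ValidationError(
                    f"symptom labels {seen[key]!r} and {label!r} collide after normalization")
            seen[key] = label

    def __len__(self) -> int:
        return len(self.symptoms)

    def canonical(self, label: str) -> str | None:
        """Return the catalog spelling matching *label* after normalization, or None."""
        key = normalize_label(label)
        for s in self.symptoms:
            if normalize_label(s) == key:
                return s
        return None

    def __contains__(self, label: str) -> bool:
        return self.canonical(label) is not None


@dataclass
class ItemBank:
    """The item corpus of one diagnostic domain."""

    domain: str
    items: list[Item]
    questionnaires: dict[str, Questionnaire] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise ValidationError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
            if item.questionnaire_id not in self.questionnaires:
                raise ValidationError(
                    f"item {item.item_id!r} references unknown questionnaire "
                    f"{item.questionnaire_id!r}")
        if not any(not i.excluded for i in self.items):
            raise ValidationError(f"item bank for {self.domain!r} has no non-excluded items")

    @property
    def analyzed_items(self) -> list[Item]:
        """Items entering the analysis (exclusion flag off), in bank order."""
        return [i for i in self.items if not i.excluded]

    @property
    def analyzed_ids(self) -> list[str]:
        return [i.item_id for i in self.analyzed_items]

    def item(self, item_id: str) -> Item:
        for i in self.items:
            if i.item_id == item_id:
                return i
        raise KeyError(item_id)


def _parse_rating_type(raw: str, row: int) -> frozenset[str]:
    parts = [p.strip().upper() for p in str(raw).replace("+", ",").split(",") if p.strip()]
    types = frozenset(parts)
    if not types or not types <= RATING_TYPES:
        raise ValidationError(f"row {row}: unrecognized rating_type {raw!r}")
    return types


def _parse_excluded(raw, row: int) -> bool:
    s = str(raw).strip().lower()
    if s in {"0", "false", "", "nan"}:
        return False
    if s in {"1", "true"}:
        return True
    raise ValidationError(f"row {row}: unrecognized excluded flag {raw!r}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    return {"csv": "csv", "tsv": "tsv", "json": "json"}.get(suffix, "csv")


def read_item_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Load and validate an item bank from CSV, TSV, or JSON.

    Row order is preserved as item order.  Raises :class:`ValidationError`
    on a missing column, duplicate item_id, or empty file, naming the
    offending row where possible.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        frame = pd.DataFrame.from_records(records)
    else:
        sep = "\t" if fmt == "tsv" else ","
        try:
            frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise ValidationError(f"{path}: empty item bank file") from None
    if frame.empty:
        raise ValidationError(f"{path}: item bank file has no rows")

    required = {"domain", "questionnaire_id", "text"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")

    domains = frame["domain"].astype(str).unique()
    if len(domains) != 1:
        raise ValidationError(f"{path}: expected a single domain, got {sorted(domains)}")

    items: list[Item] = []
    questionnaires: dict[str, Questionnaire] = {}
    ordinals: dict[str, int] = {}
    for row_no, rec in enumerate(frame.to_dict("records"), start=2):
        qid = str(rec["questionnaire_id"]).strip()
        ordinals[qid] = ordinals.get(qid, 0) + 1
        item_id = str(rec.get("item_id", "") or "").strip() or f"{qid}:{ordinals[qid]}"
        rating = _parse_rating_type(rec.get("rating_type", "SR") or "SR", row_no)
        item = Item(
            item_id=item_id,
            questionnaire_id=qid,
            text=str(rec.get("text", "")),
            rating_types=rating,
            excluded=_parse_excluded(rec.get("excluded", "0"), row_no),
        )
        items.append(item)
        name = str(rec.get("questionnaire_name", "") or "").strip() or qid
        if qid in questionnaires:
            prev = questionnaires[qid]
            questionnaires[qid] = Questionnaire(qid, prev.name,
                                                prev.rating_types | rating)
        else:
            questionnaires[qid] = Questionnaire(qid, name, rating)

    dupes = pd.Series([i.item_id for i in items])
    dup_mask = dupes.duplicated()
    if dup_mask.any():
        first = dupes[dup_mask].iloc[0]
        row = int(dup_mask.idxmax()) + 2
        raise ValidationError(f"{path}: duplicate item_id {first!r} at row {row}")

    return ItemBank(domain=str(domains[0]), items=items, questionnaires=questionnaires)


def write_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Serialize a bank so that ``read_item_bank`` round-trips it field-by-field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = [
        {
            "domain": bank.domain,
            "questionnaire_id": i.questionnaire_id,
            "questionnaire_name": bank.questionnaires[i.questionnaire_id].name,
            "item_id": i.item_id,
            "text": i.text,
            "rating_type": "+".join(sorted(i.rating_types, reverse=True)),
            "excluded": int(i.excluded),
        }
        for i in bank.items
    ]
    if fmt == "json":
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    else:
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame.from_records(records, columns=_BANK_COLUMNS).to_csv(
            path, sep=sep, index=False)


def read_symptom_catalog(path: str | Path, format: str | None = None,
                         domain: str = "") -> SymptomCatalog:
    """Load a symptom catalog (one label per record), preserving order."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        labels = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(labels, list):
            raise ValidationError(f"{path}: JSON catalog must be an array of strings")
        labels = [str(x) for x in labels]
    else:
        sep = "\t" if fmt == "tsv" else ","
        try:
            frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise ValidationError(f"{path}: empty symptom catalog") from None
        labels = [str(x) for x in frame.iloc[:, 0].tolist()]
    if not labels:
        raise ValidationError(f"{path}: empty symptom catalog")
    return SymptomCatalog(domain=domain or path.stem, symptoms=labels)


def write_symptom_catalog(catalog: SymptomCatalog, path: str | Path,
                          format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(catalog.symptoms, indent=1), encoding="utf-8")
    else:
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame({"symptom": catalog.symptoms}).to_csv(path, sep=sep, index=False)


def filter_items(bank: ItemBank, rating_type: str | None = None,
                 drop_excluded: bool = True) -> ItemBank:
    """Restrict a bank to one rating-type stratum and/or drop excluded items.

    Items tagged with both SR and OR appear in BOTH strata (dual-mode
    questionnaires are never split, they are duplicated into each stratum).
    Questionnaires left with zero items are removed from the metadata.
    Raises :class:`EmptyResultError` when nothing survives the filter.
    """
    if rating_type is not None and rating_type not in RATING_TYPES:
        raise ValidationError(f"unknown rating_type {rating_type!r}")
    items = [
        i for i in bank.items
        if (rating_type is None or rating_type in i.rating_types)
        and not (drop_excluded and i.excluded)
    ]
    if not items:
        raise EmptyResultError(
            f"filter (rating_type={rating_type!r}, drop_excluded={drop_excluded}) "
            f"left no items in domain {bank.domain!r}")
    kept = {i.questionnaire_id for i in items}
    questionnaires = {qid: q for qid, q in bank.questionnaires.items() if qid in kept}
    return ItemBank(domain=bank.domain, items=items, questionnaires=questionnaires)
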