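"""The expert arm (three raters + consensus) and the prompted-LLM arm.

The LLM arm talks to an :class:`AssignmentBackend` that returns free text;
the pipeline — never the backend — enforces catalog membership, using exact
normalized matching first and a unique case-insensitive substring match as
fallback.  Fuzzy-distance matching is deliberately absent: a silently wrong
assignment is worse than a reported failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import pandas as pd

from ._text import normalize_label
from .clustering import Clustering
from .errors import BackendError, ValidationError
from .item_bank import Item, ItemBank, SymptomCatalog

#: Default prompt; overridable via config and logged verbatim per run.
DEFAULT_PROMPT_TEMPLATE = (
    "You are given one questionnaire item and a list of symptoms. "
    "Reply with exactly one symptom from the list that best matches the item.\n"
    "Item: {item_text}\n"
    "Symptoms:\n{symptom_list}"
)


@dataclass
class RaterLabeling:
    """One expert rater's item → symptom assignments."""

    rater_id: str
    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError(f"rater {self.rater_id!r} has no assignments")

    def validate_against(self, catalog: SymptomCatalog) -> None:
        bad = [(iid, lab) for iid, lab in self.assignments.items()
               if lab not in catalog]
        if bad:
            raise ValidationError(
                f"rater {self.rater_id!r} used off-catalog labels: {bad[:5]}")


@runtime_checkable
class AssignmentBackend(Protocol):
    """Contract for prompted symptom assignment: one response string per item."""

    name: str
    deterministic: bool

    def respond(self, item: Item, prompt: str) -> str: ...


@dataclass
class ConsensusResult:
    """Majority labels plus the items that need human adjudication."""

    clustering: Clustering
    unresolved: set[str] = field(default_factory=set)


@dataclass
class TranscriptRecord:
    """One backend call, persisted to JSONL for auditability."""

    item_id: str
    prompt: str
    response: str
    label: str | None
    failure_reason: str | None = None


def render_prompt(item: Item, catalog: SymptomCatalog, template: str) -> str:
    """Substitute the item text and the catalog (one label per line, catalog
    order) into *template*; raises if a placeholder is missing."""
    for placeholder in ("{item_text}", "{symptom_list}"):
        if placeholder not in template:
            raise ValidationError(f"prompt template lacks placeholder {placeholder}")
    return template.format(item_text=item.text,
                           symptom_list="\n".join(catalog.symptoms))


def match_response(response: str, catalog: SymptomCatalog) -> str | None:
    """Map a raw backend response onto a catalog label, or None.

    Order: exact match after normalization (ignoring trailing punctuation),
    then unique case-insensitive substring (the one catalog label contained
    in the response). Ambiguity or no match → None.
    """
    cleaned = normalize_label(response).strip(".!?,;: \"'")
    for label in catalog.symptoms:
        if normalize_label(label) == cleaned:
            return label
    contained = [label for label in catalog.symptoms
                 if normalize_label(label) in cleaned]
    if len(contained) == 1:
        return contained[0]
    return None


def assign_items(
    bank: ItemBank,
    catalog: SymptomCatalog,
    backend: AssignmentBackend,
    max_retries: int = 2,
    template: str = DEFAULT_PROMPT_TEMPLATE,
) -> tuple[Clustering, set[str], list[TranscriptRecord]]:
    """Prompt the backend for every non-excluded item and validate responses.

    Returns the clustering over validated items, the set of item ids whose
    responses never validated (after ``max_retries`` retries), and the full
    call transcript.  A non-empty failure set is a reported condition, not
    an exception.
    """
    items = bank.analyzed_items
    if not items:
        raise ValidationError("bank has no items to assign")
    assignments: dict[str, str | int] = {}
    failures: set[str] = set()
    transcript: list[TranscriptRecord] = []
    for item in items:
        prompt = render_prompt(item, catalog, template)
        label = None
        for _attempt in range(max_retries + 1):
            try:
                response = backend.respond(item, prompt)
            except Exception as exc:  # noqa: BLE001 - transport boundary
                transcript.append(TranscriptRecord(
                    item.item_id, prompt, "", None, f"transport: {exc}"))
                continue
            label = match_response(response, catalog)
            transcript.append(TranscriptRecord(
                item.item_id, prompt, response, label,
                None if label else "response not a catalog label"))
            if label is not None:
                break
        if label is None:
            failures.add(item.item_id)
        else:
            assignments[item.item_id] = label
    if not assignments:
        raise BackendError(
            f"backend {backend.name!r} produced no valid assignment for any item")
    return Clustering(assignments=assignments, method="llm"), failures, transcript


def write_transcript(transcript: list[TranscriptRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in transcript:
            fh.write(json.dumps({
                "item_id": rec.item_id, "prompt": rec.prompt,
                "response": rec.response, "label": rec.label,
                "failure_reason": rec.failure_reason}) + "\n")


def consensus_labeling(labelings: list[RaterLabeling],
                       catalog: SymptomCatalog) -> ConsensusResult:
    """Per-item majority (2 of 3) label; full three-way disagreement → unresolved.

    Symmetric in rater order.  All three labelings must cover the same item
    set; differences are reported explicitly.
    """
    if len(labelings) != 3:
        raise ValidationError(f"consensus requires exactly 3 raters, got {len(labelings)}")
    for lab in labelings:
        lab.validate_against(catalog)
    item_sets = [set(lab.assignments) for lab in labelings]
    common = item_sets[0]
    if any(s != common for s in item_sets[1:]):
        diff = (item_sets[0] | item_sets[1] | item_sets[2]) - (
            item_sets[0] & item_sets[1] & item_sets[2])
        raise ValidationError(f"raters cover different item sets; difference: {sorted(diff)}")

    assignments: dict[str, str | int] = {}
    unresolved: set[str] = set()
    for item_id in labelings[0].assignments:
        votes = [normalize_label(lab.assignments[item_id]) for lab in labelings]
        majority = None
        for i, vote in enumerate(votes):
            if votes.count(vote) >= 2:
                majority = labelings[i].assignments[item_id]
                break
        if majority is None:
            unresolved.add(item_id)
        else:
            assignments[item_id] = catalog.canonical(majority) or majority
    clustering = (Clustering(assignments=assignments, method="expert")
                  if assignments else None)
    if clustering is None:
        raise ValidationError("no item reached a 2-of-3 majority")
    return ConsensusResult(clustering=clustering, unresolved=unresolved)


def apply_adjudication(result: ConsensusResult,
                       adjudication: dict[str, str],
                       catalog: SymptomCatalog) -> Clustering:
    """Resolve the unresolved items with discussed labels, yielding a complete
    expert clustering.  Adjudicated labels must be catalog members."""
    uncovered = result.unresolved - set(adjudication)
    if uncovered:
        raise ValidationError(f"unresolved items without adjudication: {sorted(uncovered)}")
    assignments = dict(result.clustering.assignments)
    for item_id in result.unresolved:
        label = adjudication[item_id]
        canonical = catalog.canonical(label)
        if canonical is None:
            raise ValidationError(
                f"adjudicated label {label!r} for item {item_id!r} is not in the catalog")
        assignments[item_id] = canonical
    return Clustering(assignments=assignments, method="expert")


def read_rater_labelings(path: str | Path) -> list[RaterLabeling]:
    """Load the rater CSV (rater_id, item_id, symptom) into per-rater labelings."""
    frame = pd.read_csv(path, dtype=str)
    missing = {"rater_id", "item_id", "symptom"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    labelings = []
    for rater_id, group in frame.groupby("rater_id", sort=True):
        labelings.append(RaterLabeling(
            rater_id=str(rater_id),
            assignments=dict(zip(group["item_id"], group["symptom"]))))
    return labelings


def write_rater_labelings(labelings: list[RaterLabeling], path: str | Path) -> None:
    rows = [(lab.rater_id, iid, sym)
            for lab in labelings for iid, sym in lab.assignments.items()]
    pd.DataFrame(rows, columns=["rater_id", "item_id", "symptom"]).to_csv(
        path, index=False)


def read_adjudication(path: str | Path) -> dict[str, str]:
    """Load the adjudication CSV (item_id, symptom)."""
    frame = pd.read_csv(path, dtype=str)
    missing = {"item_id", "symptom"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(frame["item_id"], frame["symptom"]))
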