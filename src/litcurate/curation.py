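"""Record lifecycle state machine and typed metadata annotation.

Every record lives in exactly one of five triage collections: accessible
articles land in Evaluate, articles whose PDF could not be fetched land in
Inaccessible (and are retried on every future run), and curators move
Evaluate/Review records to Positive, Negative or Review.  The metadata
service attaches typed category/value pairs to records; unlike a system
that trusts a GUI to keep the database coherent, type and vocabulary checks
are enforced here at the operation boundary, so every entry path is safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

from .enrichment import DoiRegistryClient, PdfTransport, TransportFailure, attempt_download, resolve_pdf_url
from .records import (
    ArticleRecord,
    PdfStatus,
    RecordStore,
    TriageState,
    ValidationError,
    utcnow_iso,
)

__all__ = [
    "MetadataCategory",
    "MetadataAnnotation",
    "StateError",
    "ConflictError",
    "LEGAL_TRANSITIONS",
    "ingest",
    "triage",
    "retriage",
    "recheck_inaccessible",
    "define_metadata_category",
    "annotate",
    "get_annotations",
    "unfinished_records",
]


class StateError(RuntimeError):
    """An illegal triage transition was requested."""


class ConflictError(ValueError):
    """A metadata category name is already taken."""


_VALUE_TYPES = ("integer", "string", "boolean", "list", "set", "nested_list")

#: verdicts a curator may request, per current state
LEGAL_TRANSITIONS: dict[TriageState, set[TriageState]] = {
    TriageState.EVALUATE: {TriageState.POSITIVE, TriageState.NEGATIVE, TriageState.REVIEW},
    TriageState.REVIEW: {TriageState.POSITIVE, TriageState.NEGATIVE},
    TriageState.INACCESSIBLE: set(),  # leaves only via recheck_inaccessible
    TriageState.POSITIVE: set(),  # leaves only via privileged retriage
    TriageState.NEGATIVE: set(),
}


@dataclass(frozen=True)
class MetadataCategory:
    """A user-defined annotation dimension, optionally vocabulary-constrained."""

    name: str
    value_type: str = "string"
    vocabulary: Optional[frozenset[str]] = None
    required: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("name", "empty category name")
        if self.value_type not in _VALUE_TYPES:
            raise ValidationError("value_type", f"unknown type {self.value_type!r}")
        if self.vocabulary is not None and self.value_type not in ("string", "list", "set"):
            raise ValidationError(
                "vocabulary", f"vocabulary not meaningful for type {self.value_type!r}"
            )

    def to_json(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "value_type": self.value_type,
            "vocabulary": sorted(self.vocabulary) if self.vocabulary is not None else None,
            "required": self.required,
        }

    @classmethod
    def from_json(cls, d: dict[str, Any]) -> "MetadataCategory":
        vocab = d.get("vocabulary")
        return cls(
            name=d["name"],
            value_type=d.get("value_type", "string"),
            vocabulary=frozenset(vocab) if vocab is not None else None,
            required=bool(d.get("required", False)),
        )


@dataclass(frozen=True)
class MetadataAnnotation:
    record_id: str
    category: str
    value: Any


def _check_value(category: MetadataCategory, value: Any) -> Any:
    """Validate (and canonicalize) a value against its category."""
    vt = category.value_type
    vocab = category.vocabulary

    def check_atom(atom: Any) -> None:
        if not isinstance(atom, str):
            raise ValidationError(category.name, f"atom {atom!r} is not a string")
        if vocab is not None and atom not in vocab:
            raise ValidationError(category.name, f"value {atom!r} not in vocabulary")

    if vt == "integer":
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValidationError(category.name, f"{value!r} is not an integer")
        return value
    if vt == "boolean":
        if not isinstance(value, bool):
            raise ValidationError(category.name, f"{value!r} is not a boolean")
        return value
    if vt == "string":
        check_atom(value)
        return value
    if vt == "list":
        if not isinstance(value, (list, tuple)):
            raise ValidationError(category.name, f"{value!r} is not a list")
        for atom in value:
            check_atom(atom)
        return list(value)
    if vt == "set":
        if not isinstance(value, (set, frozenset, list, tuple)):
            raise ValidationError(category.name, f"{value!r} is not a set")
        atoms = list(value)
        for atom in atoms:
            check_atom(atom)
        if len(set(atoms)) != len(atoms):
            raise ValidationError(category.name, "duplicate atoms in set value")
        return sorted(atoms)
    # nested_list: list of lists of strings
    if not isinstance(value, (list, tuple)):
        raise ValidationError(category.name, f"{value!r} is not a nested list")
    out = []
    for inner in value:
        if not isinstance(inner, (list, tuple)):
            raise ValidationError(category.name, f"inner value {inner!r} is not a list")
        for atom in inner:
            if not isinstance(atom, str):
                raise ValidationError(category.name, f"atom {atom!r} is not a string")
        out.append(list(inner))
    return out


# ---------------------------------------------------------------------------
# lifecycle operations
# ---------------------------------------------------------------------------


def ingest(
    store: RecordStore,
    record: ArticleRecord,
    target_collection: str = "default",
) -> ArticleRecord:
    """Place a (deduplicated, merged) record into its triage collection.

    Downloaded records go to Evaluate; records whose PDF could not be
    fetched go to Inaccessible.  A merged duplicate of an already-triaged
    record keeps its triage untouched.
    """
    placed = record.copy()
    placed.target_collection = target_collection
    if placed.record_id in store:
        # merge path: placement of an existing record is never changed here
        prior = store.get(placed.record_id)
        placed.triage = prior.triage
        placed.triage_note = prior.triage_note
        placed.evaluated_date = prior.evaluated_date
    else:
        placed.triage = (
            TriageState.EVALUATE
            if placed.pdf_status is PdfStatus.DOWNLOADED
            else TriageState.INACCESSIBLE
        )
    store.put(placed)
    return placed


def triage(
    store: RecordStore,
    record_id: str,
    verdict: TriageState | str,
    note: Optional[str] = None,
    user: str = "curator",
) -> ArticleRecord:
    """Apply a curator verdict (Positive / Negative / Review).

    Only records in Evaluate or Review may be triaged; Review requires a
    note; Positive/Negative set the evaluated date.  The transition is
    recorded in the record's note trail with the acting user.
    """
    verdict = TriageState(verdict)
    if verdict not in (TriageState.POSITIVE, TriageState.NEGATIVE, TriageState.REVIEW):
        raise StateError(f"{verdict.value} is not a curator verdict")
    record = store.get(record_id)
    if verdict not in LEGAL_TRANSITIONS[record.triage]:
        raise StateError(f"cannot triage a record in state {record.triage.value}")
    if verdict is TriageState.REVIEW and not note:
        raise ValidationError("note", "Review verdict requires a note")
    record.triage = verdict
    if verdict is TriageState.REVIEW:
        record.triage_note = f"{note} [{user}]"
        record.evaluated_date = None
    else:
        record.evaluated_date = utcnow_iso()
        if note:
            record.triage_note = f"{note} [{user}]"
    store.put(record)
    return record


def retriage(
    store: RecordStore,
    record_id: str,
    verdict: TriageState | str,
    note: str,
    user: str,
) -> ArticleRecord:
    """Privileged reversal of a Positive/Negative verdict; always logged.

    The latest verdict timestamp is recorded and the reversal reason kept
    as a note.
    """
    verdict = TriageState(verdict)
    if not note:
        raise ValidationError("note", "retriage requires a justification note")
    record = store.get(record_id)
    if record.triage not in (TriageState.POSITIVE, TriageState.NEGATIVE):
        raise StateError("retriage applies only to Positive/Negative records")
    record.triage_note = f"re-triaged {record.triage.value} -> {verdict.value}: {note} [{user}]"
    record.triage = verdict
    if verdict in (TriageState.POSITIVE, TriageState.NEGATIVE):
        record.evaluated_date = utcnow_iso()
    else:
        record.evaluated_date = None
    store.put(record)
    return record


def recheck_inaccessible(
    store: RecordStore,
    registry: DoiRegistryClient,
    pdf_client: PdfTransport,
    pdf_dir: str | Path,
) -> list[ArticleRecord]:
    """Retry every Inaccessible record; promote successes to Evaluate.

    Runs as part of every search run: paywalled articles may become
    accessible later from the same or different sources.  Per-record
    failures are swallowed and the loop continues; promoted records keep
    all their prior search hits and metadata.
    """
    promoted: list[ArticleRecord] = []
    for record in store.query(collection=TriageState.INACCESSIBLE):
        if not record.doi:
            continue
        try:
            url = resolve_pdf_url(record.doi, registry)
        except TransportFailure:
            continue
        updated = attempt_download(record, url, pdf_client, pdf_dir)
        if updated.pdf_status is PdfStatus.DOWNLOADED:
            updated.triage = TriageState.EVALUATE
            store.put(updated)
            promoted.append(updated)
    return promoted


# ---------------------------------------------------------------------------
# metadata service
# ---------------------------------------------------------------------------


def define_metadata_category(store: RecordStore, category: MetadataCategory) -> None:
    """Register a new annotation dimension; names are unique."""
    if category.name in store.categories:
        raise ConflictError(f"metadata category {category.name!r} already defined")
    store.categories[category.name] = category.to_json()
    store.save_categories()


def get_category(store: RecordStore, name: str) -> MetadataCategory:
    if name not in store.categories:
        raise KeyError(f"metadata category {name!r} not defined")
    return MetadataCategory.from_json(store.categories[name])


def annotate(store: RecordStore, record_id: str, category: str, value: Any) -> MetadataAnnotation:
    """Attach a typed value to a record, overwriting any previous value.

    The value is checked against the category's type, and every atomic
    value against the controlled vocabulary when one is configured.
    """
    if record_id not in store:
        raise KeyError(f"no record {record_id!r}")
    cat = get_category(store, category)
    canon = _check_value(cat, value)
    store.annotations.setdefault(record_id, {})[category] = canon
    store.save_annotations()
    return MetadataAnnotation(record_id=record_id, category=category, value=canon)


def get_annotations(store: RecordStore, record_id: str) -> dict[str, Any]:
    return dict(store.annotations.get(record_id, {}))


def unfinished_records(store: RecordStore) -> list[ArticleRecord]:
    """Records whose metadata annotation is not yet marked finished."""
    out = []
    for record in store.all_records():
        ann = store.annotations.get(record.record_id, {})
        if not ann.get("IsMetadataFinished", False):
            out.append(record)
    return out
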