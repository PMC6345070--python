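"""Domain types and the persistent record store.

The store keeps three logical databases — portal/keyword configuration,
the literature records themselves, and metadata annotations — plus an
activity log of search runs.  Everything is persisted as plain JSON files
inside a store directory, written atomically, so a store survives process
restarts and can be inspected or versioned as text.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import uuid
from dataclasses import dataclass, field, replace, asdict
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

__all__ = [
    "PartialDate",
    "SearchHit",
    "TriageState",
    "PdfStatus",
    "ArticleRecord",
    "ActivityLogEntry",
    "RecordStore",
    "ValidationError",
    "UsageError",
    "export_ris",
]


class ValidationError(ValueError):
    """An invariant violation; ``field`` names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class UsageError(ValueError):
    """Bad arguments to a store operation (unknown sort key, filter field...)."""


_DAYS_IN_MONTH = [31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


@dataclass(frozen=True)
class PartialDate:
    """A publication date of variable granularity: year, year-month or full.

    Portals differ in how precisely they report publication dates, and
    date filters may themselves be coarse.  Comparison happens at the
    coarsest common granularity: a year-only date *overlaps* every finer
    date inside that year rather than preceding or following it.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.year, int) or self.year < 1:
            raise ValidationError("year", f"invalid year {self.year!r}")
        if self.day is not None and self.month is None:
            raise ValidationError("day", "day present without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValidationError("month", f"month {self.month} out of range")
        if self.day is not None:
            if not 1 <= self.day <= _DAYS_IN_MONTH[self.month - 1]:
                raise ValidationError("day", f"day {self.day} invalid for month {self.month}")
            if self.month is not None and self.day is not None:
                # full dates must be real calendar dates
                try:
                    datetime(self.year, self.month, self.day)
                except ValueError as exc:
                    raise ValidationError("day", str(exc)) from None

    # -- ordering at the coarsest common granularity -------------------

    def _bounds(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Inclusive (earliest, latest) fully-specified bounds of the span."""
        if self.month is None:
            return (self.year, 1, 1), (self.year, 12, 31)
        if self.day is None:
            return (self.year, self.month, 1), (self.year, self.month, 31)
        return (self.year, self.month, self.day), (self.year, self.month, self.day)

    def precedes(self, other: "PartialDate") -> bool:
        """True iff every date in self's span is before every date in other's."""
        return self._bounds()[1] < other._bounds()[0]

    def overlaps(self, other: "PartialDate") -> bool:
        a0, a1 = self._bounds()
        b0, b1 = other._bounds()
        return a0 <= b1 and b0 <= a1

    def in_range(self, start: Optional["PartialDate"], end: Optional["PartialDate"]) -> bool:
        """Inclusive range membership under overlap semantics."""
        if start is not None and self.precedes(start):
            return False
        if end is not None and end.precedes(self):
            return False
        return True

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def to_json(self) -> dict[str, int]:
        d: dict[str, int] = {"year": self.year}
        if self.month is not None:
            d["month"] = self.month
        if self.day is not None:
            d["day"] = self.day
        return d

    @classmethod
    def from_json(cls, d: dict[str, int]) -> "PartialDate":
        return cls(d["year"], d.get("month"), d.get("day"))

    def __str__(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"


@dataclass(frozen=True)
class SearchHit:
    """Provenance of one query hit: which portal and keyword query found a record."""

    portal: str
    query_id: str
    keywords: str = ""
    hit_date: str = ""  # ISO-8601 timestamp

    def __post_init__(self) -> None:
        if not self.portal:
            raise ValidationError("portal", "empty portal name")
        if not self.query_id:
            raise ValidationError("query_id", "empty query id")

    @property
    def key(self) -> tuple[str, str]:
        return (self.portal, self.query_id)


class TriageState(str, Enum):
    EVALUATE = "Evaluate"
    INACCESSIBLE = "Inaccessible"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    REVIEW = "Review"


class PdfStatus(str, Enum):
    NOT_ATTEMPTED = "not_attempted"
    DOWNLOADED = "downloaded"
    INACCESSIBLE = "inaccessible"


def utcnow_iso() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def compute_record_id(doi: Optional[str], pmid: Optional[str], title: Optional[str]) -> str:
    """Deterministic content hash, so re-ingesting the same article reproduces its key."""
    from .similarity import normalize_title  # local import avoids a cycle

    if doi:
        basis = "doi:" + doi.strip().lower()
    elif pmid:
        basis = "pmid:" + pmid.strip()
    elif title:
        basis = "title:" + normalize_title(title)
    else:
        raise ValidationError("record_id", "no identifier or title to hash")
    return hashlib.sha1(basis.encode("utf-8")).hexdigest()[:16]


@dataclass
class ArticleRecord:
    """One publication with its bibliography, provenance, PDF and triage state."""

    title: str
    record_id: str = ""
    pmid: Optional[str] = None
    pmcid: Optional[str] = None
    doi: Optional[str] = None
    journal: Optional[str] = None
    published: Optional[PartialDate] = None
    authors: list[str] = field(default_factory=list)
    contact_email: Optional[str] = None
    is_preprint: bool = False
    search_hits: list[SearchHit] = field(default_factory=list)
    found_date: str = field(default_factory=utcnow_iso)
    evaluated_date: Optional[str] = None
    pdf_status: PdfStatus = PdfStatus.NOT_ATTEMPTED
    pdf_path: Optional[str] = None
    triage: TriageState = TriageState.EVALUATE
    triage_note: Optional[str] = None
    target_collection: str = "default"

    def __post_init__(self) -> None:
        if isinstance(self.pdf_status, str) and not isinstance(self.pdf_status, PdfStatus):
            self.pdf_status = PdfStatus(self.pdf_status)
        if isinstance(self.triage, str) and not isinstance(self.triage, TriageState):
            self.triage = TriageState(self.triage)
        if not self.record_id:
            self.record_id = compute_record_id(self.doi, self.pmid, self.title)

    def validate(self) -> None:
        if not (self.pmid or self.pmcid or self.doi or (self.title and self.title.strip())):
            raise ValidationError("title", "record needs at least one of pmid/pmcid/doi/title")
        keys = [h.key for h in self.search_hits]
        if len(keys) != len(set(keys)):
            raise ValidationError("search_hits", "duplicate (portal, query_id) hit")
        if (self.pdf_status is PdfStatus.DOWNLOADED) != (self.pdf_path is not None):
            raise ValidationError("pdf_path", "pdf_path present iff pdf_status=downloaded")
        if (self.triage in (TriageState.POSITIVE, TriageState.NEGATIVE)) != (
            self.evaluated_date is not None
        ):
            raise ValidationError(
                "evaluated_date", "evaluated_date present iff triage is Positive/Negative"
            )
        if self.triage is TriageState.REVIEW and not self.triage_note:
            raise ValidationError("triage_note", "Review state requires a note")

    def identifier(self) -> str:
        """Primary display identifier used for the `identifier` sort."""
        return self.pmid or self.pmcid or self.doi or ""

    # -- JSON schema ---------------------------------------------------

    def to_json(self) -> dict[str, Any]:
        d = asdict(self)
        d["published"] = self.published.to_json() if self.published else None
        d["pdf_status"] = self.pdf_status.value
        d["triage"] = self.triage.value
        d["search_hits"] = [asdict(h) for h in self.search_hits]
        return d

    @classmethod
    def from_json(cls, d: dict[str, Any]) -> "ArticleRecord":
        d = dict(d)
        if d.get("published"):
            d["published"] = PartialDate.from_json(d["published"])
        d["pdf_status"] = PdfStatus(d.get("pdf_status", "not_attempted"))
        d["triage"] = TriageState(d.get("triage", "Evaluate"))
        d["search_hits"] = [SearchHit(**h) for h in d.get("search_hits", [])]
        return cls(**d)

    def copy(self) -> "ArticleRecord":
        return ArticleRecord.from_json(self.to_json())


@dataclass
class ActivityLogEntry:
    """Start/end bookkeeping for one search run."""

    run_id: str = field(default_factory=lambda: uuid.uuid4().hex[:12])
    started: str = field(default_factory=utcnow_iso)
    ended: Optional[str] = None
    status: str = "running"  # running | error | interrupted | success
    detail: str = ""

    def close(self, status: str, detail: str = "") -> None:
        if status not in ("error", "interrupted", "success"):
            raise ValidationError("status", f"not a terminal status: {status}")
        self.status = status
        self.ended = utcnow_iso()
        if detail:
            self.detail = detail

    def to_json(self) -> dict[str, Any]:
        return asdict(self)


_SORT_KEYS = ("published", "identifier", "title", "found_date")
_FILTER_FIELDS = ("pmid", "pmcid", "doi", "title", "author")


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class RecordStore:
    """Directory-backed store for records, config, annotations and the activity log.

    Layout::

        <root>/records.json      one JSON object per record, keyed by record_id
        <root>/categories.json   metadata category definitions
        <root>/annotations.json  {record_id: {category: value}}
        <root>/portals.json      portal & query configuration
        <root>/activity.json     list of run log entries
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._records: dict[str, ArticleRecord] = {}
        self._categories: dict[str, dict[str, Any]] = {}
        self._annotations: dict[str, dict[str, Any]] = {}
        self._portal_config: dict[str, Any] = {}
        self._activity: list[ActivityLogEntry] = []
        self._load()
        self._init_default_categories()

    # -- persistence ---------------------------------------------------

    def _file(self, name: str) -> Path:
        return self.root / name

    def _load(self) -> None:
        if self._file("records.json").exists():
            raw = json.loads(self._file("records.json").read_text("utf-8"))
            self._records = {k: ArticleRecord.from_json(v) for k, v in raw.items()}
        if self._file("categories.json").exists():
            self._categories = json.loads(self._file("categories.json").read_text("utf-8"))
        if self._file("annotations.json").exists():
            self._annotations = json.loads(self._file("annotations.json").read_text("utf-8"))
        if self._file("portals.json").exists():
            self._portal_config = json.loads(self._file("portals.json").read_text("utf-8"))
        if self._file("activity.json").exists():
            self._activity = [
                ActivityLogEntry(**e)
                for e in json.loads(self._file("activity.json").read_text("utf-8"))
            ]

    def _save_records(self) -> None:
        _atomic_write(
            self._file("records.json"),
            json.dumps({k: v.to_json() for k, v in self._records.items()}, indent=1),
        )

    def _save_categories(self) -> None:
        _atomic_write(self._file("categories.json"), json.dumps(self._categories, indent=1))

    def _save_annotations(self) -> None:
        _atomic_write(self._file("annotations.json"), json.dumps(self._annotations, indent=1))

    def _save_portal_config(self) -> None:
        _atomic_write(self._file("portals.json"), json.dumps(self._portal_config, indent=1))

    def _save_activity(self) -> None:
        _atomic_write(
            self._file("activity.json"), json.dumps([e.to_json() for e in self._activity], indent=1)
        )

    def _init_default_categories(self) -> None:
        # the two built-in metadata categories exist from initialization
        changed = False
        for name, vtype in (("IsMetadataFinished", "boolean"), ("Note", "string")):
            if name not in self._categories:
                self._categories[name] = {
                    "name": name,
                    "value_type": vtype,
                    "vocabulary": None,
                    "required": False,
                }
                changed = True
        if changed:
            self._save_categories()

    # -- records -------------------------------------------------------

    def put(self, record: ArticleRecord) -> str:
        record.validate()
        self._records[record.record_id] = record.copy()
        self._save_records()
        return record.record_id

    def get(self, record_id: str) -> ArticleRecord:
        if record_id not in self._records:
            raise KeyError(record_id)
        return self._records[record_id].copy()

    def all_records(self) -> list[ArticleRecord]:
        return [r.copy() for r in self._records.values()]

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def query(
        self,
        collection: Optional[str | TriageState] = None,
        sort_key: str = "found_date",
        filters: Optional[dict[str, str]] = None,
        page: Optional[tuple[int, int]] = None,
    ) -> list[ArticleRecord]:
        """Ordered, filtered, optionally paged view of one or all collections.

        Filters are conjunctive case-insensitive substring predicates over
        ``pmid``/``pmcid``/``doi``/``title``/``author``.  The order is total:
        ties under the sort key break by record_id.  ``page`` is
        (index, size) with half-open boundaries.
        """
        from .similarity import normalize_title

        if sort_key not in _SORT_KEYS:
            raise UsageError(f"unknown sort_key {sort_key!r}; expected one of {_SORT_KEYS}")
        filters = filters or {}
        for f in filters:
            if f not in _FILTER_FIELDS:
                raise UsageError(f"unknown filter field {f!r}; expected one of {_FILTER_FIELDS}")

        records = self.all_records()
        if collection is not None:
            want = collection.value if isinstance(collection, TriageState) else str(collection)
            if want in [t.value for t in TriageState]:
                records = [r for r in records if r.triage.value == want]
            else:
                records = [r for r in records if r.target_collection == want]

        def matches(r: ArticleRecord) -> bool:
            for fld, needle in filters.items():
                n = needle.lower()
                if fld == "author":
                    if not any(n in a.lower() for a in r.authors):
                        return False
                else:
                    val = getattr(r, fld) or ""
                    if n not in val.lower():
                        return False
            return True

        records = [r for r in records if matches(r)]

        if sort_key == "published":
            # undated records sort last
            def key(r: ArticleRecord):
                return (r.published is None, r.published.sort_key() if r.published else (0, 0, 0), r.record_id)
        elif sort_key == "identifier":
            def key(r: ArticleRecord):
                return (r.identifier() == "", r.identifier(), r.record_id)
        elif sort_key == "title":
            def key(r: ArticleRecord):
                return (normalize_title(r.title), r.record_id)
        else:
            def key(r: ArticleRecord):
                return (r.found_date, r.record_id)

        records.sort(key=key)
        if page is not None:
            idx, size = page
            if idx < 0 or size < 1:
                raise UsageError(f"bad page spec {page!r}")
            records = records[idx * size : (idx + 1) * size]
        return records

    def counts(self) -> dict[str, int]:
        out = {t.value: 0 for t in TriageState}
        for r in self._records.values():
            out[r.triage.value] += 1
        return out

    def reset(self, confirm: bool) -> None:
        """Wipe all three databases.  Refused unless explicitly confirmed."""
        if not confirm:
            raise UsageError("reset requires confirm=True; store unchanged")
        self._records.clear()
        self._categories.clear()
        self._annotations.clear()
        self._portal_config.clear()
        self._save_records()
        self._save_annotations()
        self._save_portal_config()
        self._init_default_categories()
        entry = ActivityLogEntry(detail="store reset")
        entry.close("success")
        self.append_activity(entry)

    # -- categories / annotations (accessors used by curation module) --

    @property
    def categories(self) -> dict[str, dict[str, Any]]:
        return self._categories

    def save_categories(self) -> None:
        self._save_categories()

    @property
    def annotations(self) -> dict[str, dict[str, Any]]:
        return self._annotations

    def save_annotations(self) -> None:
        self._save_annotations()

    @property
    def portal_config(self) -> dict[str, Any]:
        return self._portal_config

    def save_portal_config(self) -> None:
        self._save_portal_config()

    # -- activity log --------------------------------------------------

    def append_activity(self, entry: ActivityLogEntry) -> None:
        if (entry.ended is None) != (entry.status == "running"):
            raise ValidationError("ended", "ended present iff status is terminal")
        self._activity = [e for e in self._activity if e.run_id != entry.run_id]
        self._activity.append(entry)
        self._save_activity()

    @property
    def activity_log(self) -> list[ActivityLogEntry]:
        return list(self._activity)


def export_ris(records: Iterable[ArticleRecord]) -> str:
    """RIS rendering of a collection (TY/TI/AU/JO/PY/DO/ER tags)."""
    lines: list[str] = []
    for r in records:
        lines.append("TY  - JOUR")
        lines.append(f"TI  - {r.title}")
        for a in r.authors:
            lines.append(f"AU  - {a}")
        if r.journal:
            lines.append(f"JO  - {r.journal}")
        if r.published:
            lines.append(f"PY  - {r.published.year}")
        if r.doi:
            lines.append(f"DO  - {r.doi}")
        lines.append("ER  - ")
        lines.append("")
    return "\n".join(lines)
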