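"""Bibliographic enrichment and PDF retrieval behind injected transports.

The bibliographic-index client plays the role of a PubMed/PubMed Central
lookup: given a title it returns several candidates (term expansion makes
multiple returns the norm), and the best one is accepted only when its
Jaro–Winkler title similarity reaches the 0.9 hard threshold.  The DOI
registry client resolves a DOI to a full-text URL the way CrossRef does.
All network interaction goes through these contracts, so every code path
runs offline against the mock implementations shipped here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Protocol, Sequence

from .records import ArticleRecord, PartialDate, PdfStatus, ValidationError
from .similarity import SimilarityConfig, best_title_match, normalize_title, jaro_winkler

__all__ = [
    "LookupResult",
    "BibIndexClient",
    "DoiRegistryClient",
    "PdfTransport",
    "TransportFailure",
    "NotFoundError",
    "AccessDenied",
    "MockBibIndex",
    "MockDoiRegistry",
    "MockPdfServer",
    "lookup_by_title",
    "lookup_by_id",
    "resolve_pdf_url",
    "attempt_download",
]


class TransportFailure(RuntimeError):
    """The remote service could not be reached (timeout, outage)."""


class NotFoundError(LookupError):
    """The identifier is well-formed but unknown to the index."""


class AccessDenied(RuntimeError):
    """The publisher refused the PDF (paywall, no subscription)."""


@dataclass
class LookupResult:
    """Bibliographic data returned by an index lookup."""

    pmid: Optional[str] = None
    pmcid: Optional[str] = None
    doi: Optional[str] = None
    title: str = ""
    journal: Optional[str] = None
    published: Optional[PartialDate] = None
    authors: list[str] = field(default_factory=list)
    contact_email: Optional[str] = None
    match_score: Optional[float] = None  # present when the lookup was by title


class BibIndexClient(Protocol):
    def search_title(self, title: str) -> Sequence[dict[str, Any]]: ...
    def fetch(self, kind: str, identifier: str) -> Optional[dict[str, Any]]: ...


class DoiRegistryClient(Protocol):
    def full_text_url(self, doi: str) -> Optional[str]: ...


class PdfTransport(Protocol):
    def fetch_pdf(self, url: str) -> bytes: ...


# ---------------------------------------------------------------------------
# identifier syntax
# ---------------------------------------------------------------------------

_PMID_RE = re.compile(r"^\d+$")
_PMCID_RE = re.compile(r"^PMC\d+$")
_DOI_RE = re.compile(r"^10\.\S+/\S+$")


def classify_identifier(identifier: str) -> str:
    """Return 'pmid' | 'pmcid' | 'doi', or raise ValidationError."""
    if _PMID_RE.match(identifier):
        return "pmid"
    if _PMCID_RE.match(identifier):
        return "pmcid"
    if _DOI_RE.match(identifier):
        return "doi"
    raise ValidationError("identifier", f"not a valid PMID/PMCID/DOI: {identifier!r}")


def _result_from_payload(payload: dict[str, Any]) -> LookupResult:
    pub = payload.get("published")
    if isinstance(pub, dict):
        pub = PartialDate.from_json(pub)
    elif isinstance(pub, str) and pub:
        pub = PartialDate(*[int(p) for p in pub.split("-")][:3])
    else:
        pub = None
    return LookupResult(
        pmid=payload.get("pmid") or None,
        pmcid=payload.get("pmcid") or None,
        doi=payload.get("doi") or None,
        title=payload.get("title") or "",
        journal=payload.get("journal") or None,
        published=pub,
        authors=list(payload.get("authors") or []),
        contact_email=payload.get("contact_email") or None,
    )


# ---------------------------------------------------------------------------
# lookups
# ---------------------------------------------------------------------------


def lookup_by_title(
    title: str,
    client: BibIndexClient,
    cfg: SimilarityConfig = SimilarityConfig(),
) -> Optional[LookupResult]:
    """Find a record's identifiers and extended bibliography by its title.

    The index typically returns multiple candidates; each is scored by
    Jaro–Winkler on normalized titles, and the best is returned only if it
    reaches ``cfg.pubmed_best_match_threshold`` (0.9 by default).
    """
    if not title:
        raise ValidationError("title", "empty title")
    candidates = list(client.search_title(title))
    if not candidates:
        return None
    # delegate ranking to the same argmax used everywhere
    as_records = [
        ArticleRecord(title=c.get("title") or "", doi=c.get("doi"), pmid=c.get("pmid"))
        for c in candidates
    ]
    best = best_title_match(title, as_records, cfg)
    if best is None:
        return None
    idx = as_records.index(best)
    result = _result_from_payload(candidates[idx])
    result.match_score = jaro_winkler(
        normalize_title(title), normalize_title(result.title), cfg
    )
    return result


def lookup_by_id(identifier: str, client: BibIndexClient) -> LookupResult:
    """Keyed retrieval by PMID, PMCID or DOI (the manual-add pathway).

    Syntax is validated before any transport call; an unknown id raises
    :class:`NotFoundError`.
    """
    kind = classify_identifier(identifier)
    payload = client.fetch(kind, identifier)
    if payload is None:
        raise NotFoundError(f"{kind} {identifier!r} not found in index")
    return _result_from_payload(payload)


def resolve_pdf_url(doi: str, client: DoiRegistryClient) -> Optional[str]:
    """Full-text URL registered for a DOI, or None when the registry lists none."""
    if not doi:
        raise ValidationError("doi", "empty doi")
    return client.full_text_url(doi)


def attempt_download(
    record: ArticleRecord,
    url: Optional[str],
    client: PdfTransport,
    pdf_dir: str | Path,
) -> ArticleRecord:
    """Try to fetch the PDF; update pdf_status/pdf_path accordingly.

    Accessibility depends on open-access status and subscriptions, so
    denial is an expected outcome, not an error: the record becomes (or
    stays) ``inaccessible`` and will be retried in future runs.  Retry-safe:
    a later success overwrites the same ``<record_id>.pdf`` path.
    """
    updated = record.copy()
    if url is None:
        updated.pdf_status = PdfStatus.INACCESSIBLE
        updated.pdf_path = None
        return updated
    try:
        blob = client.fetch_pdf(url)
    except (AccessDenied, TransportFailure):
        updated.pdf_status = PdfStatus.INACCESSIBLE
        updated.pdf_path = None
        return updated
    pdf_dir = Path(pdf_dir)
    pdf_dir.mkdir(parents=True, exist_ok=True)
    path = pdf_dir / f"{record.record_id}.pdf"
    path.write_bytes(blob)
    updated.pdf_status = PdfStatus.DOWNLOADED
    updated.pdf_path = str(path)
    return updated


def enrich_record(
    record: ArticleRecord,
    client: BibIndexClient,
    cfg: SimilarityConfig = SimilarityConfig(),
) -> ArticleRecord:
    """Fill missing identifiers/email from a title lookup; never overwrite.

    A non-empty stored field that disagrees with the index value is left
    alone (the same conflict rule merging follows).  Transport failures are
    swallowed: the record simply proceeds without enrichment.
    """
    if record.pmid and record.contact_email:
        return record
    try:
        result = lookup_by_title(record.title, client, cfg)
    except TransportFailure:
        return record
    if result is None:
        return record
    updated = record.copy()
    updated.pmid = updated.pmid or result.pmid
    updated.pmcid = updated.pmcid or result.pmcid
    updated.doi = updated.doi or result.doi
    updated.journal = updated.journal or result.journal
    updated.published = updated.published or result.published
    updated.contact_email = updated.contact_email or result.contact_email
    if not updated.authors:
        updated.authors = list(result.authors)
    return updated


# ---------------------------------------------------------------------------
# mock services
# ---------------------------------------------------------------------------


class MockBibIndex:
    """Offline bibliographic index.

    ``entries`` are payload dicts (title/pmid/pmcid/doi/journal/published/
    authors/contact_email).  A title search returns every entry sharing at
    least one word with the query plus the configured decoys, emulating
    synonym-expanded retrieval.
    """

    def __init__(self, entries: Sequence[dict[str, Any]], decoys: Sequence[dict[str, Any]] = (),
                 fail: bool = False):
        self.entries = list(entries)
        self.decoys = list(decoys)
        self.fail = fail

    def _check(self) -> None:
        if self.fail:
            raise TransportFailure("bibliographic index unreachable")

    def search_title(self, title: str) -> list[dict[str, Any]]:
        self._check()
        words = set(normalize_title(title).split())
        out = [
            e for e in self.entries
            if words & set(normalize_title(e.get("title", "")).split())
        ]
        return out + list(self.decoys)

    def fetch(self, kind: str, identifier: str) -> Optional[dict[str, Any]]:
        self._check()
        for e in self.entries + self.decoys:
            if e.get(kind) == identifier:
                return e
        return None


class MockDoiRegistry:
    """Offline DOI registry: a doi -> full-text-URL table; None when absent."""

    def __init__(self, urls: dict[str, str], fail: bool = False):
        self.urls = dict(urls)
        self.fail = fail

    def full_text_url(self, doi: str) -> Optional[str]:
        if self.fail:
            raise TransportFailure("doi registry unreachable")
        return self.urls.get(doi)


class MockPdfServer:
    """Offline publisher: serves bytes for open URLs, denies paywalled ones.

    Flipping a URL into ``open_urls`` later models an article becoming
    open access after first being inaccessible.
    """

    def __init__(self, open_urls: Optional[set[str]] = None, fail: bool = False):
        self.open_urls = set(open_urls or ())
        self.fail = fail

    def open_up(self, url: str) -> None:
        self.open_urls.add(url)

    def fetch_pdf(self, url: str) -> bytes:
        if self.fail:
            raise TransportFailure("publisher unreachable")
        if url not in self.open_urls:
            raise AccessDenied(url)
        return b"%PDF-1.4 synthetic stand-in for " + url.encode("utf-8")
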