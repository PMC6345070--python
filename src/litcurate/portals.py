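"""Portal adapters: response parsing, date filtering, and a mock portal.

Publisher portals differ in query dialect and in payload format (some APIs
return XML, others JSON; some sites would need HTML scraping, which is
disabled by default).  This module normalizes their responses into
:class:`RawPortalHit` objects, applies client-side date filtering at full
year/month/day granularity even when the portal itself only filters by
year, and provides a deterministic in-process mock portal that parses and
evaluates queries against a synthetic corpus — the offline stand-in used by
the whole test surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Optional, Protocol, Sequence

from lxml import etree

from .query import (
    CapabilityError,
    ParseError,
    PortalDialect,
    QueryNode,
    evaluate,
    parse_query,
    validate_for_portal,
)
from .records import PartialDate

__all__ = [
    "RawPortalHit",
    "PortalError",
    "PayloadError",
    "PortalTransport",
    "MockPortal",
    "parse_response",
    "serialize_hits",
    "filter_by_date",
    "run_portal_search",
    "register_portal",
    "make_portal",
    "DEFAULT_JSON_MAPPING",
    "DEFAULT_XML_MAPPING",
]


class PortalError(RuntimeError):
    """Transport-level failure talking to a portal."""


class PayloadError(ValueError):
    """Malformed portal payload; names the portal and the byte offset."""

    def __init__(self, portal: str, offset: int, message: str):
        self.portal = portal
        self.offset = offset
        super().__init__(f"portal {portal!r}: {message} (byte offset {offset})")


@dataclass
class RawPortalHit:
    """One search result as delivered by a portal — untrusted, possibly partial."""

    source_portal: str
    title: str = ""
    pmid: Optional[str] = None
    pmcid: Optional[str] = None
    doi: Optional[str] = None
    journal: Optional[str] = None
    published: Optional[PartialDate] = None
    authors: list[str] = field(default_factory=list)
    is_preprint: bool = False
    paywalled: bool = False
    undated: bool = False  # set when date filtering keeps a hit that has no date

    def has_identity(self) -> bool:
        return bool(self.title or self.pmid or self.pmcid or self.doi)


class PortalTransport(Protocol):
    """Minimal transport contract an adapter speaks.

    ``search`` returns one page of raw payload bytes for a translated query;
    ``offset`` pages through results until the adapter sees a short page.
    """

    def search(self, query: str, offset: int = 0) -> bytes: ...


# ---------------------------------------------------------------------------
# payload parsing
# ---------------------------------------------------------------------------

#: canonical field paths for JSON payloads: {"records": [{...}, ...]}
DEFAULT_JSON_MAPPING = {
    "root": "records",
    "title": "title",
    "pmid": "pmid",
    "pmcid": "pmcid",
    "doi": "doi",
    "journal": "journal",
    "published": "published",
    "authors": "authors",
    "is_preprint": "is_preprint",
    "paywalled": "paywalled",
}

#: canonical element paths for XML payloads: <records><record>...</record></records>
DEFAULT_XML_MAPPING = {
    "root": ".//record",
    "title": "title",
    "pmid": "pmid",
    "pmcid": "pmcid",
    "doi": "doi",
    "journal": "journal",
    "published": "published",
    "authors": "authors/author",
    "is_preprint": "is_preprint",
    "paywalled": "paywalled",
}


def _parse_partial_date(value: Any) -> Optional[PartialDate]:
    if value is None or value == "":
        return None
    if isinstance(value, dict):
        return PartialDate.from_json(value)
    parts = [int(p) for p in str(value).split("-")]
    return PartialDate(*parts[:3])


def parse_response(
    payload: bytes,
    format: str,
    mapping: Optional[dict[str, str]] = None,
    portal: str = "unknown",
) -> list[RawPortalHit]:
    """Decode a portal payload into normalized hits.

    Missing optional fields become empty; encodings are normalized to
    Unicode.  A syntactically broken payload raises :class:`PayloadError`
    naming the portal and the byte offset of the failure.  No field value
    is invented: everything in the output is decoded from the payload.
    """
    if format == "json":
        mapping = mapping or DEFAULT_JSON_MAPPING
        try:
            doc = json.loads(payload.decode("utf-8"))
        except json.JSONDecodeError as exc:
            raise PayloadError(portal, exc.pos, f"invalid JSON: {exc.msg}") from None
        if isinstance(doc, dict) and doc.get("error"):
            raise PortalError(f"portal {portal!r} returned error: {doc['error']}")
        rows = doc.get(mapping["root"], []) if isinstance(doc, dict) else doc
        hits = []
        for row in rows:
            hit = RawPortalHit(
                source_portal=portal,
                title=str(row.get(mapping["title"]) or ""),
                pmid=row.get(mapping["pmid"]) or None,
                pmcid=row.get(mapping["pmcid"]) or None,
                doi=row.get(mapping["doi"]) or None,
                journal=row.get(mapping["journal"]) or None,
                published=_parse_partial_date(row.get(mapping["published"])),
                authors=[str(a) for a in row.get(mapping["authors"]) or []],
                is_preprint=bool(row.get(mapping["is_preprint"], False)),
                paywalled=bool(row.get(mapping["paywalled"], False)),
            )
            if hit.has_identity():
                hits.append(hit)
        return hits
    if format == "xml":
        mapping = mapping or DEFAULT_XML_MAPPING
        try:
            root = etree.fromstring(payload)
        except etree.XMLSyntaxError as exc:
            offset = getattr(exc, "position", (0, 0))
            raise PayloadError(portal, offset[1] if offset else 0, f"invalid XML: {exc}") from None

        def text(el: etree._Element, path: str) -> str:
            node = el.find(path)
            return (node.text or "") if node is not None else ""

        hits = []
        for rec in root.findall(mapping["root"]):
            hit = RawPortalHit(
                source_portal=portal,
                title=text(rec, mapping["title"]),
                pmid=text(rec, mapping["pmid"]) or None,
                pmcid=text(rec, mapping["pmcid"]) or None,
                doi=text(rec, mapping["doi"]) or None,
                journal=text(rec, mapping["journal"]) or None,
                published=_parse_partial_date(text(rec, mapping["published"])),
                authors=[(a.text or "") for a in rec.findall(mapping["authors"])],
                is_preprint=text(rec, mapping["is_preprint"]).lower() == "true",
                paywalled=text(rec, mapping["paywalled"]).lower() == "true",
            )
            if hit.has_identity():
                hits.append(hit)
        return hits
    raise ValueError(f"unknown payload format {format!r}")


def _hit_row(h: RawPortalHit) -> dict[str, Any]:
    return {
        "title": h.title,
        "pmid": h.pmid or "",
        "pmcid": h.pmcid or "",
        "doi": h.doi or "",
        "journal": h.journal or "",
        "published": h.published.to_json() if h.published else None,
        "authors": list(h.authors),
        "is_preprint": h.is_preprint,
        "paywalled": h.paywalled,
    }


def serialize_hits(hits: Sequence[RawPortalHit], format: str) -> bytes:
    """Render hits in a portal payload format (the mock portal's writer)."""
    if format == "json":
        return json.dumps({"records": [_hit_row(h) for h in hits]}, sort_keys=True).encode("utf-8")
    if format == "xml":
        root = etree.Element("records")
        for h in hits:
            rec = etree.SubElement(root, "record")
            row = _hit_row(h)
            for key in ("title", "pmid", "pmcid", "doi", "journal"):
                etree.SubElement(rec, key).text = row[key]
            etree.SubElement(rec, "published").text = str(h.published) if h.published else ""
            authors = etree.SubElement(rec, "authors")
            for a in h.authors:
                etree.SubElement(authors, "author").text = a
            etree.SubElement(rec, "is_preprint").text = "true" if h.is_preprint else "false"
            etree.SubElement(rec, "paywalled").text = "true" if h.paywalled else "false"
        return etree.tostring(root, encoding="utf-8", xml_declaration=True)
    raise ValueError(f"unknown payload format {format!r}")


# ---------------------------------------------------------------------------
# date filtering
# ---------------------------------------------------------------------------


def filter_by_date(
    hits: Iterable[RawPortalHit],
    date_range: tuple[Optional[PartialDate], Optional[PartialDate]],
) -> list[RawPortalHit]:
    """Keep hits whose published date overlaps the inclusive range.

    Partial dates use overlap semantics: a year-only 2016 date overlaps any
    range touching 2016.  Hits with no published date are retained but
    flagged ``undated`` rather than silently dropped.
    """
    start, end = date_range
    if start is not None and end is not None and end.precedes(start):
        raise ValueError("date range start must not follow end")
    out = []
    for h in hits:
        if h.published is None:
            h.undated = True
            out.append(h)
        elif h.published.in_range(start, end):
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# mock portal
# ---------------------------------------------------------------------------


class MockPortal:
    """In-process portal: parses queries in its dialect and evaluates them
    against each stored article's full text, with lemma expansion, then
    serializes the matches in the dialect's payload format.  Deterministic:
    the same query always yields byte-identical payloads.
    """

    def __init__(self, corpus: Sequence[Any], dialect: PortalDialect, fail: bool = False):
        # corpus entries need .full_text plus the bibliographic attrs of RawPortalHit
        self.corpus = list(corpus)
        self.dialect = dialect
        self.fail = fail  # simulate a transport outage

    def _match(self, raw_query: str) -> list[RawPortalHit]:
        ast = parse_query(raw_query)
        validate_for_portal(ast, self.dialect)
        hits = []
        for art in self.corpus:
            if evaluate(ast, art.full_text, lemma_expansion=True):
                hits.append(
                    RawPortalHit(
                        source_portal=self.dialect.name,
                        title=art.title,
                        pmid=getattr(art, "pmid", None),
                        pmcid=getattr(art, "pmcid", None),
                        doi=getattr(art, "doi", None),
                        journal=getattr(art, "journal", None),
                        published=getattr(art, "published", None),
                        authors=list(getattr(art, "authors", [])),
                        is_preprint=getattr(art, "is_preprint", False),
                        paywalled=getattr(art, "paywalled", False),
                    )
                )
        return hits

    def serve(self, raw_query: str) -> bytes:
        """Full (unpaged) response for a raw query string."""
        fmt = "json" if self.dialect.payload_format == "html_scrape" else self.dialect.payload_format
        try:
            hits = self._match(raw_query)
        except (ParseError, CapabilityError) as exc:
            # portal-style error payload
            return json.dumps({"error": str(exc)}).encode("utf-8")
        return serialize_hits(hits, fmt)

    # PortalTransport contract
    def search(self, query: str, offset: int = 0) -> bytes:
        if self.fail:
            raise PortalError(f"portal {self.dialect.name!r} unreachable")
        fmt = "json" if self.dialect.payload_format == "html_scrape" else self.dialect.payload_format
        hits = self._match(query)[offset : offset + self.dialect.page_size]
        return serialize_hits(hits, fmt)


# ---------------------------------------------------------------------------
# search driver + factory registry
# ---------------------------------------------------------------------------


def run_portal_search(
    dialect: PortalDialect,
    ast: QueryNode,
    date_range: tuple[Optional[PartialDate], Optional[PartialDate]],
    client: PortalTransport,
    notice: Optional[Callable[[str], None]] = None,
) -> list[RawPortalHit]:
    """Translate, search (following pagination), parse and date-filter.

    An empty result list is a normal outcome.  A scraping-only dialect with
    scraping disabled is skipped with a logged notice and zero hits.
    Transport failures surface as :class:`PortalError` for the orchestrator
    to record; the multi-query run continues with the next query.
    """
    from .query import translate

    if dialect.payload_format == "html_scrape" and not dialect.scraping_enabled:
        if notice:
            notice(f"portal {dialect.name!r}: scraping disabled, query skipped")
        return []
    validate_for_portal(ast, dialect)
    raw_query = translate(ast, dialect)
    fmt = "json" if dialect.payload_format == "html_scrape" else dialect.payload_format
    hits: list[RawPortalHit] = []
    offset = 0
    while True:
        try:
            payload = client.search(raw_query, offset=offset)
        except PortalError:
            raise
        except Exception as exc:  # transport contract violated
            raise PortalError(f"portal {dialect.name!r} transport failure: {exc}") from exc
        page = parse_response(payload, fmt, portal=dialect.name)
        hits.extend(page)
        if len(page) < dialect.page_size:
            break
        offset += len(page)
    return filter_by_date(hits, date_range)


_PORTAL_REGISTRY: dict[str, Callable[..., PortalTransport]] = {}


def register_portal(name: str, factory: Callable[..., PortalTransport]) -> None:
    """Register an adapter factory under a portal name (factory pattern)."""
    _PORTAL_REGISTRY[name] = factory


def make_portal(name: str, *args: Any, **kwargs: Any) -> PortalTransport:
    if name not in _PORTAL_REGISTRY:
        raise KeyError(f"no portal adapter registered under {name!r}")
    return _PORTAL_REGISTRY[name](*args, **kwargs)


register_portal("mock", MockPortal)
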