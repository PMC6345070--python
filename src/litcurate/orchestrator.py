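"""The search-run orchestrator: portals x queries -> deduplicated store.

One run walks every active portal and every configured query: validate and
translate the query for the portal's dialect, search (empty results are
normal), date-filter, deduplicate against *all* stored collections, merge
or create records, enrich from the bibliographic index, resolve and fetch
PDFs, and place each record in its query's target collection.  Previously
inaccessible records are rechecked at the end of every run.  The run is
bracketed by an activity-log entry whose terminal status distinguishes
success, error and user interruption, and partially completed work is
always persisted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import curation, enrichment
from .curation import ingest, recheck_inaccessible
from .enrichment import (
    BibIndexClient,
    DoiRegistryClient,
    NotFoundError,
    PdfTransport,
    TransportFailure,
    attempt_download,
    enrich_record,
    lookup_by_id,
    resolve_pdf_url,
)
from .portals import PortalError, PortalTransport, RawPortalHit, run_portal_search
from .query import CapabilityError, ParseError, PortalDialect, parse_query
from .records import (
    ActivityLogEntry,
    ArticleRecord,
    PartialDate,
    PdfStatus,
    RecordStore,
    SearchHit,
    TriageState,
    utcnow_iso,
)
from .similarity import SimilarityConfig, find_duplicate, merge_records

__all__ = ["QuerySpec", "RunConfig", "Services", "run_search", "add_manual", "show_status"]


@dataclass(frozen=True)
class QuerySpec:
    query_id: str
    text: str
    target_collection: str = "default"
    active: bool = True


@dataclass
class RunConfig:
    portals: list[PortalDialect]
    queries: list[QuerySpec]
    start_date: Optional[PartialDate] = None
    end_date: Optional[PartialDate] = None
    schedule_days: Optional[int] = None
    #: when no explicit start_date is given, begin at the month of the last
    #: successful run so periodic runs cover the gap since the previous one
    auto_advance: bool = True

    def validate(self) -> None:
        if not any(p.active for p in self.portals):
            raise ValueError("run needs at least one active portal")
        active_queries = [q for q in self.queries if q.active]
        if not active_queries:
            raise ValueError("run needs at least one active query")
        for q in active_queries:
            parse_query(q.text)  # raises ParseError on bad config


@dataclass
class Services:
    """Injected transports; every member has an offline mock implementation."""

    portal_clients: dict[str, PortalTransport]
    bib_index: Optional[BibIndexClient] = None
    doi_registry: Optional[DoiRegistryClient] = None
    pdf_client: Optional[PdfTransport] = None
    pdf_dir: str | Path = "pdfs"
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)


def _record_from_hit(hit: RawPortalHit, query: QuerySpec) -> ArticleRecord:
    rec = ArticleRecord(
        title=hit.title,
        pmid=hit.pmid,
        pmcid=hit.pmcid,
        doi=hit.doi,
        journal=hit.journal,
        published=hit.published,
        authors=list(hit.authors),
        is_preprint=hit.is_preprint,
        search_hits=[
            SearchHit(
                portal=hit.source_portal,
                query_id=query.query_id,
                keywords=query.text,
                hit_date=utcnow_iso(),
            )
        ],
        target_collection=query.target_collection,
    )
    return rec


def _process_hit(
    store: RecordStore,
    hit: RawPortalHit,
    query: QuerySpec,
    services: Services,
    notices: list[str],
) -> ArticleRecord:
    incoming = _record_from_hit(hit, query)
    if services.bib_index is not None and incoming.title:
        incoming = enrich_record(incoming, services.bib_index, services.similarity)

    existing = find_duplicate(incoming, store.all_records(), services.similarity)
    if existing is not None:
        merged = merge_records(existing, incoming, on_conflict=notices.append)
        # keep the stored record's identity and placement
        merged.record_id = existing.record_id
        if merged.pdf_status is not PdfStatus.DOWNLOADED:
            merged = _try_download(merged, services)
        placed = ingest(store, merged, target_collection=existing.target_collection)
        return placed

    incoming = _try_download(incoming, services)
    return ingest(store, incoming, target_collection=query.target_collection)


def _try_download(record: ArticleRecord, services: Services) -> ArticleRecord:
    if services.doi_registry is None or services.pdf_client is None:
        return record
    if not record.doi:
        record = record.copy()
        record.pdf_status = PdfStatus.INACCESSIBLE
        return record
    try:
        url = resolve_pdf_url(record.doi, services.doi_registry)
    except TransportFailure:
        record = record.copy()
        record.pdf_status = PdfStatus.INACCESSIBLE
        return record
    return attempt_download(record, url, services.pdf_client, services.pdf_dir)


def run_search(cfg: RunConfig, store: RecordStore, services: Services) -> ActivityLogEntry:
    """Execute one full search run; returns the closed activity-log entry."""
    cfg.validate()
    entry = ActivityLogEntry(detail="search run")
    notices: list[str] = []
    failed_portals: set[str] = set()
    start_date = cfg.start_date
    if start_date is None and cfg.auto_advance:
        last = store.portal_config.get("last_successful_run")
        if last:
            start_date = PartialDate(int(last[:4]), int(last[5:7]))
    try:
        for dialect in cfg.portals:
            if not dialect.active:
                continue
            client = services.portal_clients.get(dialect.name)
            if client is None:
                notices.append(f"portal {dialect.name!r}: no transport configured")
                failed_portals.add(dialect.name)
                continue
            portal_ok = False
            for query in cfg.queries:
                if not query.active:
                    continue
                try:
                    ast = parse_query(query.text)
                    hits = run_portal_search(
                        dialect,
                        ast,
                        (start_date, cfg.end_date),
                        client,
                        notice=notices.append,
                    )
                except CapabilityError as exc:
                    notices.append(f"query {query.query_id!r}: {exc}")
                    portal_ok = True  # capability mismatch is a config note, not an outage
                    continue
                except (PortalError, ParseError) as exc:
                    notices.append(f"portal {dialect.name!r} query {query.query_id!r}: {exc}")
                    continue
                portal_ok = True
                for hit in hits:
                    _process_hit(store, hit, query, services, notices)
            if not portal_ok:
                failed_portals.add(dialect.name)

        if services.doi_registry is not None and services.pdf_client is not None:
            promoted = recheck_inaccessible(
                store, services.doi_registry, services.pdf_client, services.pdf_dir
            )
            if promoted:
                notices.append(f"recheck promoted {len(promoted)} inaccessible record(s)")
    except KeyboardInterrupt:
        entry.close("interrupted", detail="; ".join(notices) or "user interrupt")
        store.append_activity(entry)
        raise
    status = "error" if failed_portals else "success"
    entry.close(status, detail="; ".join(notices))
    store.append_activity(entry)
    if status == "success":
        store.portal_config["last_successful_run"] = entry.ended
        store.save_portal_config()
    return entry


def add_manual(
    store: RecordStore,
    services: Services,
    identifier: Optional[str] = None,
    fields: Optional[dict] = None,
    target_collection: str = "default",
) -> ArticleRecord:
    """Add one publication by PMID/PMCID/DOI, or fully manually by fields.

    The record is enriched through the keyed index lookup, deduplicated
    against the whole store (a duplicate is merged, not an error), fetched
    if possible, and ingested with a portal="manual" provenance hit.
    """
    if identifier is not None:
        result = lookup_by_id(identifier, services.bib_index)
        incoming = ArticleRecord(
            title=result.title,
            pmid=result.pmid,
            pmcid=result.pmcid,
            doi=result.doi,
            journal=result.journal,
            published=result.published,
            authors=list(result.authors),
            contact_email=result.contact_email,
        )
    elif fields is not None:
        incoming = ArticleRecord(**fields)
        incoming.validate()
    else:
        raise ValueError("add_manual needs an identifier or explicit fields")

    incoming.search_hits = [
        SearchHit(portal="manual", query_id="manual", keywords=identifier or "", hit_date=utcnow_iso())
    ]
    incoming.target_collection = target_collection

    existing = find_duplicate(incoming, store.all_records(), services.similarity)
    if existing is not None:
        merged = merge_records(existing, incoming)
        merged.record_id = existing.record_id
        return ingest(store, merged, target_collection=existing.target_collection)
    incoming = _try_download(incoming, services)
    return ingest(store, incoming, target_collection=target_collection)


def show_status(store: RecordStore) -> dict:
    """Summary counts per collection plus the most recent runs.

    The per-state counts always sum to the store size (the five triage
    collections partition the records).
    """
    counts = store.counts()
    return {
        "counts": counts,
        "total": len(store),
        "last_runs": [e.to_json() for e in store.activity_log[-5:]],
    }
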