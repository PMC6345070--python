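"""Shared fixtures: stores, mock services, and the end-to-end scenario.

The `scenario` fixture builds the canonical two-portal setup: 6 unique
articles, two of which appear on both portals (8 portal placements in
total), one paywalled; three queries, each matching exactly two articles,
covering all six.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pytest

from litcurate.enrichment import MockBibIndex, MockDoiRegistry, MockPdfServer
from litcurate.orchestrator import QuerySpec, RunConfig, Services
from litcurate.portals import MockPortal
from litcurate.query import PortalDialect
from litcurate.records import ArticleRecord, PartialDate, RecordStore


@dataclass
class FakeArticle:
    """Minimal portal-side article the mock portal can serve."""

    title: str
    full_text: str
    pmid: Optional[str] = None
    pmcid: Optional[str] = None
    doi: Optional[str] = None
    journal: Optional[str] = None
    published: Optional[PartialDate] = None
    authors: list[str] = field(default_factory=list)
    is_preprint: bool = False
    paywalled: bool = False


@pytest.fixture
def store(tmp_path):
    return RecordStore(tmp_path / "store")


def _article(i: int, keyword: str, *, doi=True, pmid=True) -> FakeArticle:
    # distinct leading words keep cross-article title similarity low
    openers = ["Zebrafish", "Quantal", "Vestibular", "Microglial", "Oscillatory", "Thalamocortical"]
    tails = [
        "signalling gradients in early development",
        "release statistics at central synapses",
        "pathway integration during locomotion",
        "dynamics after peripheral injury",
        "coupling across cortical layers",
        "relay circuits under anesthesia",
    ]
    title = f"{openers[i]} {tails[i]}"
    return FakeArticle(
        title=title,
        full_text=f"{title}. In this study we examine {keyword} in detail. Data available.",
        pmid=str(1000 + i) if pmid else None,
        doi=f"10.5555/art.{i}" if doi else None,
        journal="Journal of Synthetic Results",
        published=PartialDate(2016, 1 + i, 10),
        authors=["Ascoli G.", "Example A."],
    )


@pytest.fixture
def scenario(tmp_path):
    """2 portals x 3 queries over 8 placements of 6 articles, 1 paywalled."""
    # queries: q1 morphology, q2 "neuronal reconstruction", q3 tracing
    arts = [
        _article(0, "morphology"),               # portals A+B (duplicate)
        _article(1, "neuronal reconstruction"),  # portals A+B (duplicate)
        _article(2, "morphology"),               # A only
        _article(3, "neuronal reconstruction"),  # B only
        _article(4, "tracing"),                  # A only
        _article(5, "tracing"),                  # B only, paywalled
    ]
    arts[5].paywalled = True
    portal_a = [arts[0], arts[1], arts[2], arts[4]]
    portal_b = [arts[0], arts[1], arts[3], arts[5]]

    dialect_a = PortalDialect(name="portalA", payload_format="json")
    dialect_b = PortalDialect(name="portalB", payload_format="xml")
    cfg = RunConfig(
        portals=[dialect_a, dialect_b],
        queries=[
            QuerySpec("q1", "morphology", "default"),
            QuerySpec("q2", '"neuronal reconstruction"', "default"),
            QuerySpec("q3", "tracing", "default"),
        ],
        auto_advance=False,  # reruns must re-cover the same window
    )
    registry = MockDoiRegistry({a.doi: f"https://pdf.example/{a.doi}" for a in arts})
    pdf_server = MockPdfServer(
        open_urls={f"https://pdf.example/{a.doi}" for a in arts if not a.paywalled}
    )
    services = Services(
        portal_clients={
            "portalA": MockPortal(portal_a, dialect_a),
            "portalB": MockPortal(portal_b, dialect_b),
        },
        doi_registry=registry,
        pdf_client=pdf_server,
        pdf_dir=tmp_path / "pdfs",
    )
    store = RecordStore(tmp_path / "store")
    return {
        "cfg": cfg,
        "store": store,
        "services": services,
        "articles": arts,
        "pdf_server": pdf_server,
        "paywalled": arts[5],
    }


@pytest.fixture
def evaluate_record(store):
    """A stored record sitting in the Evaluate collection."""
    rec = ArticleRecord(
        title="Microtubule dynamics in growing axons",
        doi="10.5555/eval.1",
        pdf_status="downloaded",
        pdf_path="/tmp/x.pdf",
    )
    store.put(rec)
    return rec
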