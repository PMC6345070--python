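"""Structured configuration file: portals, queries, thresholds, metadata.

One YAML document drives a run::

    similarity:
      title_match_threshold: 0.85
      pubmed_best_match_threshold: 0.9
    portals:
      - name: pubmed
        payload_format: xml
        supports_not: true
        date_granularity: year_month
        active: true
      - name: nature
        word_joiner: "+"
    queries:
      - query_id: q1
        text: '(morphology OR "neuromorpho.org") AND "neuronal reconstruction"'
        target_collection: reconstructions
    start_date: {year: 2016, month: 1}
    metadata_categories:
      - name: Species
        value_type: string
        vocabulary: [mouse, rat, human]
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

import yaml

from .curation import MetadataCategory
from .orchestrator import QuerySpec, RunConfig
from .query import PortalDialect
from .records import PartialDate
from .similarity import SimilarityConfig

__all__ = ["load_config", "LoadedConfig"]


class LoadedConfig:
    def __init__(
        self,
        run: RunConfig,
        similarity: SimilarityConfig,
        metadata_categories: list[MetadataCategory],
    ):
        self.run = run
        self.similarity = similarity
        self.metadata_categories = metadata_categories


def _dialect(d: dict[str, Any]) -> PortalDialect:
    known = {
        "name", "supports_not", "word_joiner", "phrase_delimiters", "date_granularity",
        "payload_format", "scraping_enabled", "api_root", "page_size", "active",
        "access_token_ref", "target_collection",
    }
    kwargs = {k: v for k, v in d.items() if k in known}
    if "phrase_delimiters" in kwargs:
        kwargs["phrase_delimiters"] = tuple(kwargs["phrase_delimiters"])
    return PortalDialect(**kwargs)


def _partial_date(v: Any) -> Optional[PartialDate]:
    if v is None:
        return None
    if isinstance(v, dict):
        return PartialDate.from_json(v)
    return PartialDate(*[int(p) for p in str(v).split("-")][:3])


def load_config(path: str | Path) -> LoadedConfig:
    doc = yaml.safe_load(Path(path).read_text("utf-8")) or {}
    sim = SimilarityConfig(**(doc.get("similarity") or {}))
    portals = [_dialect(p) for p in doc.get("portals", [])]
    queries = [QuerySpec(**q) for q in doc.get("queries", [])]
    run = RunConfig(
        portals=portals,
        queries=queries,
        start_date=_partial_date(doc.get("start_date")),
        end_date=_partial_date(doc.get("end_date")),
        schedule_days=doc.get("schedule_days"),
    )
    cats = []
    for c in doc.get("metadata_categories", []):
        vocab = c.get("vocabulary")
        cats.append(
            MetadataCategory(
                name=c["name"],
                value_type=c.get("value_type", "string"),
                vocabulary=frozenset(vocab) if vocab else None,
                required=bool(c.get("required", False)),
            )
        )
    return LoadedConfig(run=run, similarity=sim, metadata_categories=cats)
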