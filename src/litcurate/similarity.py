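"""Title normalization, Jaro / Jaro–Winkler similarity, and duplicate handling.

Recurrent searches return the same article from different portals (or from
the same portal at different times) with inconsistently rendered titles:
special characters differ across publishers and some portals truncate long
titles.  Duplicates are therefore detected with three parallel methods —
exact PMID/PMCID match, exact DOI match, and approximate title match under
the Jaro–Winkler similarity at a threshold of 0.85 — and merged so that no
information gathered by any search is lost.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

from .records import ArticleRecord, SearchHit

__all__ = [
    "SimilarityConfig",
    "normalize_title",
    "jaro",
    "jaro_winkler",
    "find_duplicate",
    "merge_records",
    "best_title_match",
    "PREPRINT_SERVERS",
]

#: journal strings that mark a record as coming from a preprint server
PREPRINT_SERVERS = {"biorxiv", "medrxiv", "arxiv", "preprints.org", "ssrn", "research square"}


@dataclass(frozen=True)
class SimilarityConfig:
    """Thresholds and Winkler parameters.

    ``title_match_threshold`` (0.85) gates approximate duplicate detection;
    ``pubmed_best_match_threshold`` (0.9) is the hard threshold when picking
    the best candidate among bibliographic-index results; ``winkler_prefix_scale``
    (p) and ``max_prefix_length`` (the cap on the common prefix l) parameterize
    the Winkler prefix boost sim = jaro + l*p*(1 - jaro).
    """

    title_match_threshold: float = 0.85
    pubmed_best_match_threshold: float = 0.9
    winkler_prefix_scale: float = 0.1
    max_prefix_length: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.title_match_threshold <= 1.0:
            raise ValueError("title_match_threshold must be in [0, 1]")
        if not 0.0 <= self.pubmed_best_match_threshold <= 1.0:
            raise ValueError("pubmed_best_match_threshold must be in [0, 1]")
        if not 0.0 <= self.winkler_prefix_scale <= 0.25:
            raise ValueError("winkler_prefix_scale must be in [0, 0.25]")
        if self.max_prefix_length < 0:
            raise ValueError("max_prefix_length must be >= 0")


def normalize_title(title: str) -> str:
    """Canonical form for title comparison.

    Case-folds, applies Unicode compatibility decomposition with combining
    marks stripped (so "café" and "cafe" compare equal), collapses runs of
    whitespace and trims.  Idempotent.
    """
    s = unicodedata.normalize("NFKD", title)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.casefold()
    return " ".join(s.split())


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1].

    Characters match if equal and within a sliding window of
    floor(max(|s1|,|s2|)/2) - 1 positions; with m matches and t
    transpositions (half the matched characters out of order), the
    similarity is (m/|s1| + m/|s2| + (m-t)/m) / 3, or 0 when m = 0.
    """
    if s1 == s2:
        return 1.0
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return 0.0
    window = max(max(n1, n2) // 2 - 1, 0)
    matched1 = [False] * n1
    matched2 = [False] * n2
    m = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(n2, i + window + 1)
        for j in range(lo, hi):
            if not matched2[j] and s2[j] == c:
                matched1[i] = True
                matched2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # count transpositions over the matched subsequences
    ms2 = [c for j, c in enumerate(s2) if matched2[j]]
    k = 0
    half_transpositions = 0
    for i, c in enumerate(s1):
        if matched1[i]:
            if c != ms2[k]:
                half_transpositions += 1
            k += 1
    t = half_transpositions / 2.0
    return (m / n1 + m / n2 + (m - t) / m) / 3.0


def jaro_winkler(
    s1: str, s2: str, cfg: SimilarityConfig = SimilarityConfig()
) -> float:
    """Jaro similarity boosted by the length of the common prefix.

    sim = jaro + l * p * (1 - jaro), where l is the common-prefix length
    capped at ``cfg.max_prefix_length`` and p = ``cfg.winkler_prefix_scale``.
    """
    base = jaro(s1, s2)
    l = 0
    for a, b in zip(s1, s2):
        if a != b or l >= cfg.max_prefix_length:
            break
        l += 1
    return base + l * cfg.winkler_prefix_scale * (1.0 - base)


def title_similarity(t1: str, t2: str, cfg: SimilarityConfig = SimilarityConfig()) -> float:
    return jaro_winkler(normalize_title(t1), normalize_title(t2), cfg)


def find_duplicate(
    incoming: ArticleRecord,
    records: Iterable[ArticleRecord],
    cfg: SimilarityConfig = SimilarityConfig(),
) -> Optional[ArticleRecord]:
    """Locate an already-stored duplicate of ``incoming``, if any.

    The search spans *all* collections, including Negative and Inaccessible,
    so that a previously rejected or paywalled article is never re-created.
    Exact identifier matches win over title similarity; PMID/PMCID is
    checked before DOI.  Failing both, the highest-scoring title match at or
    above ``cfg.title_match_threshold`` is returned.
    """
    candidates = list(records)
    for r in candidates:
        if incoming.pmid and r.pmid and incoming.pmid == r.pmid:
            return r
        if incoming.pmcid and r.pmcid and incoming.pmcid == r.pmcid:
            return r
    for r in candidates:
        if incoming.doi and r.doi and incoming.doi.lower() == r.doi.lower():
            return r
    norm_in = normalize_title(incoming.title) if incoming.title else ""
    if not norm_in:
        return None
    best: Optional[ArticleRecord] = None
    best_score = 0.0
    for r in candidates:
        if not r.title:
            continue
        score = jaro_winkler(norm_in, normalize_title(r.title), cfg)
        if score >= cfg.title_match_threshold and score > best_score:
            best, best_score = r, score
    return best


def _merge_hits(a: Sequence[SearchHit], b: Sequence[SearchHit]) -> list[SearchHit]:
    """Set-union keyed by (portal, query_id) — an addToSet-style update."""
    seen: dict[tuple[str, str], SearchHit] = {}
    for h in list(a) + list(b):
        seen.setdefault(h.key, h)
    return list(seen.values())


def merge_records(
    existing: ArticleRecord,
    incoming: ArticleRecord,
    on_conflict: Optional[Callable[[str], None]] = None,
) -> ArticleRecord:
    """Merge a detected duplicate into the stored record.

    Non-empty stored fields are preserved; empty ones are filled from the
    incoming record (this is how an article that receives its PMID months
    after publication gets completed).  Search-hit provenance is unioned by
    (portal, query_id).  When the stored record is a preprint and the
    incoming one is the peer-reviewed version, the bibliographic fields
    upgrade to the published values.  Triage state is never changed by a
    merge.  Two unequal non-empty DOIs are *not* auto-merged: the stored DOI
    is kept and the discrepancy is reported through ``on_conflict``.
    """
    merged = existing.copy()

    upgrade = existing.is_preprint and not incoming.is_preprint
    if upgrade:
        # published version supersedes preprint bibliography
        merged.journal = incoming.journal or merged.journal
        merged.published = incoming.published or merged.published
        merged.doi = incoming.doi or merged.doi
        merged.pmid = incoming.pmid or merged.pmid
        merged.pmcid = incoming.pmcid or merged.pmcid
        merged.is_preprint = False
    else:
        # the reverse pairing: stored record is already the published
        # version and the incoming hit is its preprint — the preprint DOI
        # neither fills nor conflicts with the published bibliography
        incoming_is_superseded_preprint = incoming.is_preprint and not existing.is_preprint
        if incoming.doi and not incoming_is_superseded_preprint:
            if merged.doi and merged.doi.lower() != incoming.doi.lower():
                if on_conflict is not None:
                    on_conflict(
                        f"record {merged.record_id}: conflicting DOIs "
                        f"{merged.doi!r} (stored) vs {incoming.doi!r} (incoming); kept stored"
                    )
            elif not merged.doi:
                merged.doi = incoming.doi
        merged.pmid = merged.pmid or incoming.pmid
        merged.pmcid = merged.pmcid or incoming.pmcid
        merged.journal = merged.journal or incoming.journal
        merged.published = merged.published or incoming.published

    merged.contact_email = merged.contact_email or incoming.contact_email
    if not merged.authors:
        merged.authors = list(incoming.authors)
    merged.search_hits = _merge_hits(merged.search_hits, incoming.search_hits)
    return merged


def best_title_match(
    title: str,
    candidates: Sequence[ArticleRecord],
    cfg: SimilarityConfig = SimilarityConfig(),
) -> Optional[ArticleRecord]:
    """Best candidate by Jaro–Winkler on normalized titles, or None.

    Used when a bibliographic index returns several articles for one title
    query (MeSH expansion makes this the norm on PubMed): the argmax is
    returned only if it reaches ``cfg.pubmed_best_match_threshold``; ties
    break toward the earliest candidate.
    """
    norm = normalize_title(title)
    best: Optional[ArticleRecord] = None
    best_score = -1.0
    for cand in candidates:
        score = jaro_winkler(norm, normalize_title(cand.title), cfg)
        if score > best_score:
            best, best_score = cand, score
    if best is not None and best_score >= cfg.pubmed_best_match_threshold:
        return best
    return None
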