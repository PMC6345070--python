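"""Deterministic synthetic corpora with known duplicate ground truth.

The generator emulates the phenomena that make literature deduplication
hard in practice: the same article surfacing on several portals with
special characters rendered differently, titles truncated above a length
limit, PMIDs that only appear months after publication, and manuscripts
first seen as a preprint and later as the peer-reviewed version.

Perturbations are similarity-bounded: every intra-group title pair scores
at or above the dedup threshold and every cross-group pair below it, and
this is *verified at generation time* (with bounded retries) so that
duplicate-recovery tests are sharp rather than probabilistic.  The same
(spec, seed) always yields an identical corpus.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .records import PartialDate
from .similarity import SimilarityConfig, jaro_winkler, normalize_title

__all__ = [
    "CorpusSpec",
    "CorpusVariant",
    "Corpus",
    "GenerationError",
    "generate_corpus",
    "perturb_title",
    "write_corpus",
]

PERTURBATION_KINDS = ("special_chars", "truncation", "whitespace", "case")

_ACCENT_MAP = {"a": "á", "e": "é", "i": "í", "o": "ó", "u": "ü", "c": "ç", "n": "ñ"}

_TITLE_OPENERS = [
    "dendritic", "axonal", "cortical", "hippocampal", "cerebellar", "thalamic",
    "retinal", "striatal", "pyramidal", "granule", "purkinje", "motor",
    "sensory", "olfactory", "amygdalar", "spinal", "callosal", "basal",
    "entorhinal", "subicular", "neocortical", "brainstem", "vestibular",
    "peripheral", "interneuron", "principal",
]
_TITLE_NOUNS = [
    "arborization", "morphology", "reconstruction", "topology", "branching",
    "complexity", "development", "plasticity", "connectivity", "geometry",
    "polarity", "maturation", "regeneration", "degeneration", "sprouting",
    "remodeling", "architecture", "organization",
]
_TITLE_TAILS = [
    "in the adult mouse brain", "across rodent species", "under chronic stress",
    "following sensory deprivation", "during postnatal development",
    "in a transgenic rat model", "after focal ischemia", "in aging primates",
    "revealed by sparse labeling", "quantified from confocal stacks",
    "mapped with digital tracing", "in organotypic slice cultures",
    "along the septotemporal axis", "under environmental enrichment",
    "in the developing zebrafish", "after targeted lesions",
]
_JOURNALS = [
    "Journal of Comparative Neurology", "Neural Development", "Brain Structure and Function",
    "Frontiers in Neuroanatomy", "Cerebral Cortex", "Journal of Neuroscience",
    "eLife", "PLoS Computational Biology",
]
_SURNAMES = [
    "Ascoli", "Ramirez", "Okafor", "Lindqvist", "Tanaka", "Moreau", "Petrov",
    "Silva", "Nakamura", "Fischer", "Oyelaran", "Kovacs", "Bianchi", "Larsen",
    "Dubois", "Castillo", "Weber", "Novak", "Haddad", "Johansson",
]
_KEYWORD_POOL = [
    "morphology", "neuronal reconstruction", "dendrite", "axon", "tracing",
    "neuromorpho.org", "microscopy", "electrophysiology", "branching pattern",
    "spine density",
]


class GenerationError(RuntimeError):
    """The spec cannot be satisfied within the similarity bounds."""


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus."""

    n_articles: int = 50
    portals: tuple[str, ...] = ("pubmed", "sciencedirect", "springer")
    duplicate_rate: float = 0.2
    perturbation_kinds: tuple[str, ...] = PERTURBATION_KINDS
    truncation_length: int = 60
    paywalled_rate: float = 0.1
    preprint_rate: float = 0.1
    delayed_pmid_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        for name in ("duplicate_rate", "paywalled_rate", "preprint_rate", "delayed_pmid_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for k in self.perturbation_kinds:
            if k not in PERTURBATION_KINDS:
                raise ValueError(f"unknown perturbation kind {k!r}")
        if len(self.portals) < 1:
            raise ValueError("at least one portal required")


@dataclass
class CorpusVariant:
    """One article as it appears on one portal."""

    variant_id: str
    group_id: str
    portal: str
    title: str
    authors: list[str]
    journal: str
    published: Optional[PartialDate]
    pmid: Optional[str]
    pmcid: Optional[str]
    doi: Optional[str]
    is_preprint: bool
    paywalled: bool
    full_text: str
    keywords: list[str] = field(default_factory=list)


@dataclass
class Corpus:
    spec: CorpusSpec
    variants: list[CorpusVariant]
    groups: dict[str, list[str]]          # group_id -> variant_ids (ground truth)
    paywalled_groups: list[str]
    preprint_groups: list[str]            # groups containing a preprint->published pair

    def for_portal(self, portal: str) -> list[CorpusVariant]:
        return [v for v in self.variants if v.portal == portal]

    def variant(self, variant_id: str) -> CorpusVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)


def perturb_title(
    title: str,
    kind: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> tuple[str, float]:
    """Apply one perturbation kind; returns (perturbed, similarity-to-original).

    ``special_chars`` swaps ASCII letters for accented counterparts,
    ``truncation`` keeps the first ``params['truncation_length']`` characters,
    ``whitespace`` doubles random inter-word gaps, ``case`` uppercases random
    words.  Deterministic for a given seed.
    """
    params = params or {}
    rng = random.Random(seed)
    if kind == "truncation":
        n = int(params.get("truncation_length", 60))
        out = title[:n].rstrip()
    elif kind == "special_chars":
        chars = list(title)
        candidates = [i for i, c in enumerate(chars) if c.lower() in _ACCENT_MAP]
        for i in rng.sample(candidates, k=min(3, len(candidates))):
            repl = _ACCENT_MAP[chars[i].lower()]
            chars[i] = repl.upper() if chars[i].isupper() else repl
        out = "".join(chars)
    elif kind == "whitespace":
        words = title.split(" ")
        out = ""
        for w in words:
            out += w + (" " * rng.choice((1, 1, 2, 3)))
        out = out.rstrip() + rng.choice(("", " ", "  "))
    elif kind == "case":
        words = title.split(" ")
        for i in rng.sample(range(len(words)), k=min(2, len(words))):
            words[i] = words[i].upper()
        out = " ".join(words)
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    sim = jaro_winkler(normalize_title(title), normalize_title(out))
    return out, sim


def _make_title(rng: random.Random) -> str:
    return (
        f"{rng.choice(_TITLE_OPENERS).capitalize()} {rng.choice(_TITLE_OPENERS)} "
        f"{rng.choice(_TITLE_NOUNS)} and {rng.choice(_TITLE_NOUNS)} "
        f"{rng.choice(_TITLE_TAILS)}"
    )


def _make_full_text(title: str, keywords: Sequence[str], rng: random.Random) -> str:
    kw = ", ".join(keywords)
    return (
        f"{title}. Abstract: we investigate {keywords[0]} using quantitative "
        f"analysis. Methods: samples were processed and {kw} were measured. "
        f"Digital data sets were archived for reuse. Results are discussed in "
        f"the context of {rng.choice(_TITLE_NOUNS)}."
    )


def _make_date(rng: random.Random) -> Optional[PartialDate]:
    year = rng.randint(2014, 2018)
    r = rng.random()
    if r < 0.15:
        return PartialDate(year)  # year-only, as some portals report
    if r < 0.4:
        return PartialDate(year, rng.randint(1, 12))
    return PartialDate(year, rng.randint(1, 12), rng.randint(1, 28))


def generate_corpus(spec: CorpusSpec, max_retries: int = 60) -> Corpus:
    """Build a multi-portal corpus plus its duplicate ground truth.

    Each of the ``n_articles`` underlying articles is placed on one portal,
    or — with probability ``duplicate_rate`` — on two or more portals with a
    perturbed title per extra portal.  Similarity bounds (intra-group >=
    0.85, cross-group < 0.85 after normalization) are enforced by a
    verify-and-retry loop; an unsatisfiable spec raises
    :class:`GenerationError` after bounded retries.
    """
    rng = random.Random(spec.seed)
    cfg = SimilarityConfig()
    threshold = cfg.title_match_threshold

    # every accepted title (base or perturbed) with its group; candidates are
    # admitted only while all cross-group similarities stay below threshold
    accepted: list[tuple[str, int]] = []

    def clashes(norm: str, group: int) -> bool:
        return any(
            g != group and jaro_winkler(norm, t, cfg) >= threshold for t, g in accepted
        )

    titles: list[str] = []
    for i in range(spec.n_articles):
        for attempt in range(max_retries):
            cand = _make_title(rng)
            if not clashes(normalize_title(cand), i):
                titles.append(cand)
                accepted.append((normalize_title(cand), i))
                break
        else:
            raise GenerationError(f"could not draw a distinct title for article {i}")

    variants: list[CorpusVariant] = []
    groups: dict[str, list[str]] = {}
    paywalled_groups: list[str] = []
    preprint_groups: list[str] = []

    for i, title in enumerate(titles):
        group_id = f"g{i:04d}"
        keywords = rng.sample(_KEYWORD_POOL, k=rng.randint(2, 4))
        authors = [
            f"{rng.choice(_SURNAMES)} {chr(rng.randint(65, 90))}." for _ in range(rng.randint(1, 4))
        ]
        journal = rng.choice(_JOURNALS)
        published = _make_date(rng)
        pmid = str(30000000 + i)
        doi = f"10.{1000 + i % 50}/synth.{i:05d}"
        paywalled = rng.random() < spec.paywalled_rate
        as_preprint_pair = rng.random() < spec.preprint_rate
        duplicated = as_preprint_pair or (
            len(spec.portals) >= 2 and rng.random() < spec.duplicate_rate
        )
        n_portals = (
            rng.randint(2, min(3, len(spec.portals))) if duplicated and len(spec.portals) >= 2 else 1
        )
        portals = rng.sample(list(spec.portals), k=n_portals)
        full_text = _make_full_text(title, keywords, rng)

        if paywalled:
            paywalled_groups.append(group_id)
        if as_preprint_pair and n_portals >= 2:
            preprint_groups.append(group_id)

        group_variants: list[str] = []
        for p_idx, portal in enumerate(portals):
            variant_id = f"{group_id}.{portal}"
            v_title = title
            if p_idx > 0 and spec.perturbation_kinds:
                # perturb until the variant stays within the dedup threshold
                # of its own group and below it for every other group
                for attempt in range(max_retries):
                    kind = rng.choice(list(spec.perturbation_kinds))
                    cand, sim = perturb_title(
                        title,
                        kind,
                        {"truncation_length": spec.truncation_length},
                        seed=rng.randrange(2**31),
                    )
                    if sim >= threshold and not clashes(normalize_title(cand), i):
                        v_title = cand
                        accepted.append((normalize_title(cand), i))
                        break
                else:
                    raise GenerationError(
                        f"perturbations of {title!r} cannot stay above {threshold}"
                    )
            preprint_here = as_preprint_pair and n_portals >= 2 and p_idx == 0
            delayed = rng.random() < spec.delayed_pmid_rate
            variants.append(
                CorpusVariant(
                    variant_id=variant_id,
                    group_id=group_id,
                    portal=portal,
                    title=v_title,
                    authors=authors,
                    journal="bioRxiv" if preprint_here else journal,
                    published=PartialDate(published.year - 1) if preprint_here and published else published,
                    pmid=None if (delayed or preprint_here) else pmid,
                    pmcid=None,
                    doi=f"10.1101/{i:06d}" if preprint_here else (None if delayed and p_idx > 0 else doi),
                    is_preprint=preprint_here,
                    paywalled=paywalled,
                    full_text=full_text,
                    keywords=list(keywords),
                )
            )
            group_variants.append(variant_id)
        groups[group_id] = group_variants

    corpus = Corpus(
        spec=spec,
        variants=variants,
        groups=groups,
        paywalled_groups=paywalled_groups,
        preprint_groups=preprint_groups,
    )
    _verify_bounds(corpus, cfg)
    return corpus


def _verify_bounds(corpus: Corpus, cfg: SimilarityConfig) -> None:
    """Check the similarity bounds the ground truth promises."""
    threshold = cfg.title_match_threshold
    norms = {v.variant_id: normalize_title(v.title) for v in corpus.variants}
    for gid, members in corpus.groups.items():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sim = jaro_winkler(norms[a], norms[b], cfg)
                if sim < threshold:
                    raise GenerationError(
                        f"intra-group pair {a}/{b} scores {sim:.3f} < {threshold}"
                    )
    items = list(norms.items())
    by_group = {v.variant_id: v.group_id for v in corpus.variants}
    for i, (a, na) in enumerate(items):
        for b, nb in items[i + 1 :]:
            if by_group[a] != by_group[b]:
                sim = jaro_winkler(na, nb, cfg)
                if sim >= threshold:
                    raise GenerationError(
                        f"cross-group pair {a}/{b} scores {sim:.3f} >= {threshold}"
                    )


def write_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Emit per-portal payload files plus ground_truth.json.

    Portals alternate between JSON and XML payloads, mirroring the mix of
    real publisher APIs.
    """
    from .portals import RawPortalHit, serialize_hits

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for idx, portal in enumerate(corpus.spec.portals):
        fmt = "json" if idx % 2 == 0 else "xml"
        hits = [
            RawPortalHit(
                source_portal=portal,
                title=v.title,
                pmid=v.pmid,
                pmcid=v.pmcid,
                doi=v.doi,
                journal=v.journal,
                published=v.published,
                authors=v.authors,
                is_preprint=v.is_preprint,
                paywalled=v.paywalled,
            )
            for v in corpus.for_portal(portal)
        ]
        (out / f"{portal}.{fmt}").write_bytes(serialize_hits(hits, fmt))
    truth = {
        "groups": corpus.groups,
        "paywalled_groups": corpus.paywalled_groups,
        "preprint_groups": corpus.preprint_groups,
        "variants": {
            v.variant_id: {"portal": v.portal, "title": v.title, "keywords": v.keywords}
            for v in corpus.variants
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1), "utf-8")
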