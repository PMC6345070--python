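# Methods

This note documents the models, rules and design choices behind
`litcurate`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish about behaviour on real publisher data.

## Problem setting

A curation team tracks the literature of a domain by running a fixed
battery of keyword queries against several publisher portals on a schedule.
The same article routinely surfaces more than once — on different portals,
at different times, with its title rendered differently, and sometimes
first as a preprint — so the central technical problems are (1) expressing
one query battery against heterogeneous search dialects and (2) linking
records that denote the same publication. Everything downstream (triage,
annotation) is workflow bookkeeping that must never lose information
gathered by any search.

## Query language and dialects

The query grammar is: case-insensitive terms; exact phrases in double
quotes; uppercase `AND`, `OR`, `NOT`; parentheses for priority. Precedence
is `NOT > AND > OR`, left-associative, with same-operator chains flattened
into n-ary nodes — the convention of mainstream Boolean retrieval engines.
Two points the grammar leaves open were decided as follows:

- **Adjacent atoms** with no operator (`neuron morphology`) are joined by
  an implicit `AND`, as search engines conventionally do. Lowercase
  `and`/`or`/`not` are ordinary terms.
- **Serialization** parenthesizes every non-leaf child, so
  `parse(translate(ast))` is the identity on canonical (flattened) ASTs for
  the default dialect — a fuzzed invariant in the test suite.

A portal dialect declares its capabilities rather than its implementation:
whether `NOT` is supported (one major scholar search engine lacks it), the
word joiner inside phrases (`+` for one publisher), phrase delimiters,
payload format (XML/JSON/HTML-scrape), date-filter granularity, and a page
size (default 100) for response pagination. Scrape-only dialects run only
when scraping is explicitly enabled; it is off by default and the query is
skipped with a logged notice.

Evaluation against full text (used by the mock portal and by tests)
case-folds and whitespace-normalizes the document, requires contiguous
matches for phrases (punctuation inside a phrase is literal), and matches
terms at word boundaries. Lemma expansion is a deliberately small
singular/plural suffix table (`-s`/`-es`/`-ies` and their inverses) that
only fires on recognised suffixes — `neurons ↔ neuron`, `branches ↔
branch`, but `sheep → sheep`. Real portals lemmatize (and one index expands
terms through a controlled synonym vocabulary) server-side; that behaviour
is intentionally **not** emulated, so mock-portal recall is a lower bound
on what a synonym-expanding portal would return.

## Record linkage

Titles are normalized by case-folding, Unicode NFKD decomposition with
combining marks removed, and whitespace collapsing; this makes the two
dominant portal artefacts — special-character variants and spacing noise —
similarity-neutral by construction. The Jaro similarity is implemented from
its standard definition (matching window `⌊max(|s1|,|s2|)/2⌋ − 1`,
transpositions = half the out-of-order matches), and the Winkler variant
adds `l·p·(1 − sim_J)` with prefix cap `l ≤ 4` and scale `p = 0.1`. The
hand-checkable values 0.9444 (Jaro, MARTHA/MARHTA), 0.9611 (Winkler, same
pair) and 0.7667 (Jaro, DIXON/DICKSONX) are asserted in the tests, and the
implementation is compared to an independently written quadratic reference
matcher on 10,000 random pairs at 1e−12.

Duplicate detection uses three parallel methods — exact PMID/PMCID, exact
DOI, approximate title at **threshold 0.85** — over *all* collections,
including Negative and Inaccessible, so a rejected or paywalled article is
never re-created. When methods disagree, identifiers win over title
similarity, PMID/PMCID before DOI (the identifier registries are
authoritative; titles are noisy). When a bibliographic index returns
several candidates for one title, the best is accepted only at the harder
**0.9** threshold, reflecting that an enrichment mismatch (attaching the
wrong PMID) is costlier than a missed enrichment.

Merging preserves every non-empty stored field, fills empty ones from the
incoming record (how an article acquires its PMID months after
publication), and unions search-hit provenance keyed by (portal, query id)
— an add-to-set update, so redelivery of the same hit is a no-op. A stored
preprint whose peer-reviewed version arrives is upgraded: journal, date and
identifiers switch to the published values and the preprint flag clears.
The reverse arrival order is recognised by the incoming record's preprint
flag, and the preprint DOI then neither fills nor conflicts with the
published one. Two unequal non-empty DOIs outside the preprint pairing are
never auto-merged; the stored value is kept and the discrepancy surfaced
through a conflict callback for human review. Triage state is never changed
by a merge.

## Lifecycle and metadata

States: Evaluate (PDF on disk, awaiting a curator), Inaccessible (PDF could
not be fetched), Positive, Negative, Review (deferred, note required). The
transition table is closed: `Inaccessible → Evaluate` only via the
automatic recheck that runs at the end of every search run (accessibility
changes as articles turn open access); `Evaluate → {Positive, Negative,
Review}`; `Review → {Positive, Negative}`. Anything else errors, except an
explicit privileged re-triage of Positive/Negative records that logs the
reversal and records the latest verdict timestamp. The five states
partition the store at all times — an exhaustively enumerated test.

Metadata categories are typed (integer, string, boolean, list, set,
nested list) with an optional closed vocabulary checked per atomic value.
Two categories exist from initialization: `IsMetadataFinished` (boolean)
and `Note` (free text). The Review-state note and the `Note` category are
distinct storage: the former is part of the triage trail, the latter a
curator annotation. Validation happens at the operation boundary in the
library, since no GUI exists to be trusted with coherence.

## Storage

Records, portal/query configuration, annotations and the activity log live
as JSON files in a store directory, written atomically (temp file +
rename). At desk scale (thousands of records) this keeps the store
greppable, diffable and dependency-free; the repository interface would
admit an embedded database without touching callers. Record ids are
16-hex-digit content hashes of DOI, else PMID, else the normalized title,
so re-ingestion is reproducible. PDFs are written to a configured directory
as `<record_id>.pdf` with only the path stored. Partial publication dates
(year / year-month / full) compare at the coarsest common granularity: a
year-only date *overlaps* any finer date in that year, and range filters
use inclusive overlap semantics; hits with no date at all are kept and
flagged rather than dropped.

## Synthetic corpora

The generator emulates exactly the phenomena the dedup layer exists for:
cross-portal duplicates (`duplicate_rate`, default 0.2), special-character
substitution, title truncation at a configurable length (default 60
characters — the per-portal truncation point varies in the wild, so it is a
parameter, not a constant), whitespace/case noise, delayed PMID assignment
(default 0.2 of variants), preprint→published pairs (default 0.1 of
articles, the preprint dated a year earlier with a preprint-server DOI),
and paywalled articles (default 0.1). Titles are assembled from a
domain-flavoured vocabulary; full texts embed known keywords so query
evaluation has exact expected answers.

Perturbations are **similarity-bounded by construction**: a candidate title
(base or perturbed) is admitted only if it scores ≥ 0.85 against its own
group and < 0.85 against every already-accepted title of every other
group, with bounded retries (an unsatisfiably aggressive spec — e.g.
truncation to 8 characters — raises a generation error). Duplicate-recovery
tests on such corpora are therefore sharp: 100% precision and recall is the
*correct* outcome, not a lucky one. The flip side is stated plainly: these
corpora do not probe the borderline pairs real portals produce (truncations
that land near 0.85, translated titles, subtitle swaps), so the threshold
itself is calibrated by operational experience, not by these tests. What
the tests do establish is that the machinery — normalization, scoring,
three-method matching, merge semantics, idempotence — behaves exactly as
specified at the operating point.

Problem sizes used by the shipped checks: 10,000 string pairs for oracle
equivalence; a 200-article corpus at duplicate rate 0.3 (≈ 320 portal
variants) for duplicate recovery; 200 fuzzed ASTs and 500 (query, document)
pairs for the query engine; a 6-article, 2-portal, 3-query scenario for the
end-to-end lifecycle. All are regenerated from the acceptance script's
`--seed`.

## Mock services and what they stand for

All network interaction goes through protocol contracts: a portal transport
(`search(query, offset) → bytes`), a bibliographic index (title search and
keyed fetch), a DOI registry (DOI → full-text URL) and a PDF transport. The
bundled mocks are synthetic stand-ins that implement the contracts exactly
— the mock portal parses and evaluates real queries over its corpus and
serializes genuine XML/JSON payloads — so every pipeline path executes
offline and deterministically. Live publisher adapters share the dialect
and translation code but are out of the tested surface by design
(reproducibility and terms-of-service); writing one means implementing the
transport contract and registering it in the portal factory.

## Known limitations

- Lemma expansion is plural-only; no stemming, no synonym vocabulary.
- Author names are not used for matching; two distinct articles sharing a
  near-identical title (errata, part I/part II series) would merge if their
  titles score ≥ 0.85 and identifiers are absent.
- The scheduler is a configuration field, not a daemon; periodic execution
  is expected to come from cron or an operator.
- Between periodic runs the search window auto-advances: when no explicit
  start date is configured, a run begins at the month of the last
  successful run (recorded in the store). An explicit start date, or
  `auto_advance=False`, overrides this — reruns over a fixed window are how
  dedup idempotence is exercised.
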