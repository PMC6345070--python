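"""Lifecycle state machine and the metadata service."""

import itertools

import pytest

from litcurate.curation import (
    ConflictError,
    LEGAL_TRANSITIONS,
    MetadataCategory,
    StateError,
    annotate,
    define_metadata_category,
    get_annotations,
    ingest,
    recheck_inaccessible,
    retriage,
    triage,
    unfinished_records,
)
from litcurate.enrichment import MockDoiRegistry, MockPdfServer
from litcurate.records import ArticleRecord, PdfStatus, RecordStore, SearchHit, TriageState, ValidationError


def _rec(title="Lifecycle subject", **kw):
    return ArticleRecord(title=title, **kw)


def _put_in_state(store, state: TriageState, title: str) -> ArticleRecord:
    rec = _rec(title)
    if state in (TriageState.POSITIVE, TriageState.NEGATIVE):
        rec.evaluated_date = "2018-01-01T00:00:00"
    if state is TriageState.REVIEW:
        rec.triage_note = "pending decision"
    rec.triage = state
    store.put(rec)
    return rec


class TestIngest:
    def test_downloaded_record_lands_in_evaluate(self, store, tmp_path):
        rec = _rec(pdf_status=PdfStatus.DOWNLOADED, pdf_path=str(tmp_path / "x.pdf"))
        placed = ingest(store, rec, target_collection="recon")
        assert placed.triage is TriageState.EVALUATE
        assert placed.target_collection == "recon"

    def test_undownloadable_record_lands_in_inaccessible(self, store):
        placed = ingest(store, _rec(pdf_status=PdfStatus.INACCESSIBLE))
        assert placed.triage is TriageState.INACCESSIBLE

    def test_merge_of_positive_record_keeps_placement(self, store):
        first = _rec("Already positive", doi="10.1/pos")
        ingest(store, first)
        triage_ok = store.get(first.record_id)
        triage_ok.triage = TriageState.EVALUATE
        store.put(triage_ok)
        triage(store, first.record_id, TriageState.POSITIVE)
        again = _rec("Already positive", doi="10.1/pos", pmid="5")
        placed = ingest(store, again)
        assert placed.triage is TriageState.POSITIVE


class TestTriage:
    def test_positive_sets_evaluated_date(self, store, evaluate_record):
        out = triage(store, evaluate_record.record_id, "Positive", user="kate")
        assert out.triage is TriageState.POSITIVE and out.evaluated_date is not None

    def test_review_requires_and_stores_note(self, store, evaluate_record):
        with pytest.raises(ValidationError):
            triage(store, evaluate_record.record_id, "Review")
        out = triage(store, evaluate_record.record_id, "Review", note="needs a second look")
        assert out.triage is TriageState.REVIEW
        assert "needs a second look" in out.triage_note
        assert out.evaluated_date is None

    def test_review_to_negative_allowed(self, store, evaluate_record):
        triage(store, evaluate_record.record_id, "Review", note="unsure")
        out = triage(store, evaluate_record.record_id, "Negative")
        assert out.triage is TriageState.NEGATIVE and out.evaluated_date is not None

    def test_exhaustive_transition_table(self, store):
        """Every (state, verdict) pair behaves exactly as the table says."""
        verdicts = (TriageState.POSITIVE, TriageState.NEGATIVE, TriageState.REVIEW)
        for i, (state, verdict) in enumerate(itertools.product(TriageState, verdicts)):
            rec = _put_in_state(store, state, f"Transition probe {i}")
            if verdict in LEGAL_TRANSITIONS[state]:
                out = triage(store, rec.record_id, verdict, note="n")
                assert out.triage is verdict
            else:
                with pytest.raises(StateError):
                    triage(store, rec.record_id, verdict, note="n")
                assert store.get(rec.record_id).triage is state  # unchanged

    def test_states_partition_the_store(self, store):
        for i, state in enumerate(TriageState):
            _put_in_state(store, state, f"Partition member {i}")
        counts = store.counts()
        assert sum(counts.values()) == len(store) == 5
        assert all(v == 1 for v in counts.values())

    def test_retriage_is_privileged_and_logged(self, store, evaluate_record):
        triage(store, evaluate_record.record_id, "Positive")
        with pytest.raises(ValidationError):
            retriage(store, evaluate_record.record_id, "Negative", note="", user="pi")
        out = retriage(store, evaluate_record.record_id, "Negative",
                       note="dataset withdrawn", user="pi")
        assert out.triage is TriageState.NEGATIVE
        assert "re-triaged Positive -> Negative" in out.triage_note


class TestRecheck:
    def _inaccessible(self, store, i, doi):
        rec = _rec(f"Blocked article {i}", doi=doi, pdf_status=PdfStatus.INACCESSIBLE)
        rec.triage = TriageState.INACCESSIBLE
        rec.search_hits = [SearchHit("portalA", f"q{i}", "kw", "t")]
        store.put(rec)
        return rec

    def test_flipped_record_promoted_others_remain(self, store, tmp_path):
        recs = [self._inaccessible(store, i, f"10.1/block.{i}") for i in range(3)]
        registry = MockDoiRegistry({f"10.1/block.{i}": f"u{i}" for i in range(3)})
        server = MockPdfServer(open_urls={"u1"})
        promoted = recheck_inaccessible(store, registry, server, tmp_path)
        assert [p.record_id for p in promoted] == [recs[1].record_id]
        assert store.get(recs[1].record_id).triage is TriageState.EVALUATE
        for i in (0, 2):
            assert store.get(recs[i].record_id).triage is TriageState.INACCESSIBLE

    def test_no_inaccessible_records_empty_promotion(self, store, tmp_path):
        assert recheck_inaccessible(store, MockDoiRegistry({}), MockPdfServer(), tmp_path) == []

    def test_promotion_preserves_hits_and_metadata(self, store, tmp_path):
        rec = self._inaccessible(store, 0, "10.1/block.0")
        annotate(store, rec.record_id, "Note", "seen at conference")
        registry = MockDoiRegistry({"10.1/block.0": "u0"})
        recheck_inaccessible(store, registry, MockPdfServer(open_urls={"u0"}), tmp_path)
        after = store.get(rec.record_id)
        assert after.search_hits == rec.search_hits
        assert get_annotations(store, rec.record_id)["Note"] == "seen at conference"


class TestMetadata:
    def test_fresh_store_has_exactly_the_default_categories(self, store):
        assert set(store.categories) == {"IsMetadataFinished", "Note"}
        assert store.categories["IsMetadataFinished"]["value_type"] == "boolean"
        assert store.categories["Note"]["value_type"] == "string"

    def test_define_vocabulary_category_and_annotate(self, store, evaluate_record):
        define_metadata_category(
            store, MetadataCategory("Species", "string", frozenset({"mouse", "rat", "human"}))
        )
        ann = annotate(store, evaluate_record.record_id, "Species", "mouse")
        assert ann.value == "mouse"
        with pytest.raises(ValidationError) as exc:
            annotate(store, evaluate_record.record_id, "Species", "gerbil")
        assert "gerbil" in str(exc.value)

    def test_redefining_existing_category_conflicts(self, store):
        with pytest.raises(ConflictError):
            define_metadata_category(store, MetadataCategory("Note", "string"))

    @pytest.mark.parametrize(
        "vtype, good, bad",
        [
            ("integer", 7, "seven"),
            ("boolean", True, 1),
            ("list", ["a", "b"], "a"),
            ("set", {"a", "b"}, ["a", "a"]),
            ("nested_list", [["a"], ["b", "c"]], ["a", ["b"]]),
        ],
    )
    def test_value_type_enforcement(self, store, evaluate_record, vtype, good, bad):
        name = f"Cat_{vtype}"
        define_metadata_category(store, MetadataCategory(name, vtype))
        assert annotate(store, evaluate_record.record_id, name, good) is not None
        with pytest.raises(ValidationError):
            annotate(store, evaluate_record.record_id, name, bad)

    def test_vocabulary_checked_per_atom_in_lists(self, store, evaluate_record):
        define_metadata_category(
            store, MetadataCategory("Regions", "list", frozenset({"cortex", "hippocampus"}))
        )
        annotate(store, evaluate_record.record_id, "Regions", ["cortex"])
        with pytest.raises(ValidationError) as exc:
            annotate(store, evaluate_record.record_id, "Regions", ["cortex", "spleen"])
        assert "spleen" in str(exc.value)

    def test_annotation_overwrites_previous_value(self, store, evaluate_record):
        annotate(store, evaluate_record.record_id, "Note", "first")
        annotate(store, evaluate_record.record_id, "Note", "second")
        assert get_annotations(store, evaluate_record.record_id)["Note"] == "second"

    def test_finished_flag_filters_unfinished_listing(self, store, evaluate_record):
        other = _rec("Still unfinished")
        store.put(other)
        annotate(store, evaluate_record.record_id, "IsMetadataFinished", True)
        ids = {r.record_id for r in unfinished_records(store)}
        assert evaluate_record.record_id not in ids and other.record_id in ids

    def test_vocabulary_meaningless_for_integer_type(self):
        with pytest.raises(ValidationError):
            MetadataCategory("Bad", "integer", frozenset({"1"}))
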