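"""Similarity and dedup: Jaro/Winkler values, normalization, matching, merging."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from litcurate.records import ArticleRecord, PartialDate, SearchHit, TriageState
from litcurate.similarity import (
    SimilarityConfig,
    best_title_match,
    find_duplicate,
    jaro,
    jaro_winkler,
    merge_records,
    normalize_title,
)
from oracles import random_string_pairs, ref_jaro, ref_jaro_winkler


class TestNormalizeTitle:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Neuronal  Morphology", "neuronal morphology"),
            ("Dendritic café", "dendritic cafe"),
            ("  Ünïcode – stays\tcollapsed  ", "unicode – stays collapsed"),
        ],
    )
    def test_known_normalizations(self, raw, expected):
        assert normalize_title(raw) == expected

    @given(st.text(max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_idempotent(self, s):
        once = normalize_title(s)
        assert normalize_title(once) == once


class TestJaro:
    def test_hand_computed_values(self):
        assert jaro("MARTHA", "MARHTA") == pytest.approx(0.944444, abs=1e-4)
        assert jaro("DIXON", "DICKSONX") == pytest.approx(0.766667, abs=1e-4)
        assert jaro_winkler("MARTHA", "MARHTA") == pytest.approx(0.961111, abs=1e-4)

    def test_identity_and_empty(self):
        assert jaro("soma", "soma") == 1.0
        assert jaro("", "x") == 0.0 and jaro("x", "") == 0.0
        assert jaro("", "") == 1.0

    def test_zero_prefix_pair_winkler_equals_jaro(self):
        assert jaro_winkler("XYZ", "ABXYZ") == jaro("XYZ", "ABXYZ")

    def test_agreement_with_brute_force_reference(self):
        cfg = SimilarityConfig()
        for a, b in random_string_pairs(2000, seed=11):
            assert jaro(a, b) == pytest.approx(ref_jaro(a, b), abs=1e-12)
            assert jaro_winkler(a, b, cfg) == pytest.approx(
                ref_jaro_winkler(a, b), abs=1e-12
            )

    @given(st.text(alphabet="abcdef", max_size=15), st.text(alphabet="abcdef", max_size=15))
    @settings(max_examples=300, deadline=None)
    def test_symmetry_bounds_and_winkler_dominance(self, a, b):
        ja, jw = jaro(a, b), jaro_winkler(a, b)
        assert jaro(b, a) == pytest.approx(ja, abs=1e-12)
        assert 0.0 <= ja <= 1.0 and 0.0 <= jw <= 1.0
        assert jw >= ja - 1e-12
        if a != b:
            assert jw < 1.0

    def test_longer_common_prefix_never_lowers_score_at_fixed_jaro(self):
        # pairs sharing the same base jaro but differing in common-prefix
        # length: the Winkler boost must be non-decreasing in the prefix
        rng = random.Random(5)
        cfg = SimilarityConfig()
        for _ in range(300):
            a, b = random_string_pairs(1, seed=rng.randrange(2**31))[0]
            base = jaro(a, b)
            l = 0
            while l < min(len(a), len(b), cfg.max_prefix_length) and a[l] == b[l]:
                l += 1
            # the implementation follows the formula exactly...
            assert jaro_winkler(a, b, cfg) == pytest.approx(
                base + l * cfg.winkler_prefix_scale * (1 - base), abs=1e-12
            )
            # ...and the formula is non-decreasing in l at fixed base jaro
            boosts = [base + k * cfg.winkler_prefix_scale * (1 - base) for k in range(5)]
            assert boosts == sorted(boosts)


class TestConfig:
    def test_defaults_match_operating_thresholds(self):
        cfg = SimilarityConfig()
        assert cfg.title_match_threshold == 0.85
        assert cfg.pubmed_best_match_threshold == 0.9
        assert cfg.winkler_prefix_scale == 0.1 and cfg.max_prefix_length == 4

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            SimilarityConfig(title_match_threshold=1.2)
        with pytest.raises(ValueError):
            SimilarityConfig(winkler_prefix_scale=0.3)


def _rec(title, **kw):
    return ArticleRecord(title=title, **kw)


class TestFindDuplicate:
    def test_doi_match_found_even_in_negative_collection(self):
        stored = _rec("Stored and rejected", doi="10.1/neg.1")
        stored.triage = TriageState.NEGATIVE
        stored.evaluated_date = "2018-01-01T00:00:00"
        incoming = _rec("A very different looking title", doi="10.1/NEG.1")
        assert find_duplicate(incoming, [stored]) is stored

    def test_pmid_beats_title_similarity(self):
        by_id = _rec("Totally unrelated words here", pmid="123")
        by_title = _rec("Shared phrasing of the incoming title")
        incoming = _rec("Shared phrasing of the incoming title", pmid="123")
        assert find_duplicate(incoming, [by_title, by_id]) is by_id

    def test_accent_and_space_variant_matches_above_threshold(self):
        stored = _rec("Dendritic cafe culture in the  rodent cortex")
        incoming = _rec("Dendritic café culture in the rodent cortex")
        assert find_duplicate(incoming, [stored]) is stored

    def test_unrelated_record_matches_nothing(self):
        stored = _rec("Olfactory bulb interneuron diversity", doi="10.1/a")
        incoming = _rec("Quantum chemistry of small molecules", doi="10.1/b", pmid="9")
        assert find_duplicate(incoming, [stored]) is None


class TestMerge:
    def test_missing_fields_filled_from_incoming(self):
        existing = _rec("Fill me in")
        incoming = _rec(
            "Fill me in",
            pmid="42",
            journal="eLife",
            published=PartialDate(2017, 2),
            contact_email="author@example.org",
        )
        merged = merge_records(existing, incoming)
        assert merged.pmid == "42" and merged.journal == "eLife"
        assert merged.published == PartialDate(2017, 2)
        assert merged.contact_email == "author@example.org"

    def test_non_empty_fields_never_overwritten(self):
        existing = _rec("Keep me", pmid="1", journal="Old Journal")
        incoming = _rec("Keep me", pmid="2", journal="New Journal")
        merged = merge_records(existing, incoming)
        assert merged.pmid == "1" and merged.journal == "Old Journal"

    def test_merge_with_itself_is_identity(self):
        rec = _rec("Self merge", doi="10.1/self", search_hits=[SearchHit("p", "q", "k", "t")])
        merged = merge_records(rec, rec)
        assert merged.to_json() == rec.to_json()

    def test_merge_is_absorbing(self):
        a = _rec("Absorb test", search_hits=[SearchHit("pa", "q1", "k", "t")])
        b = _rec("Absorb test", pmid="7", search_hits=[SearchHit("pb", "q2", "k", "t")])
        once = merge_records(a, b)
        twice = merge_records(once, b)
        assert twice.to_json() == once.to_json()

    def test_same_portal_query_hit_delivered_twice_not_duplicated(self):
        a = _rec("Hit union", search_hits=[SearchHit("pubmed", "q1", "k", "t1")])
        b = _rec("Hit union", search_hits=[SearchHit("pubmed", "q1", "k", "t2")])
        merged = merge_records(a, b)
        assert len(merged.search_hits) == 1
        assert merged.search_hits[0].hit_date == "t1"  # first sighting kept

    def test_preprint_upgraded_to_published_version(self):
        preprint = _rec(
            "From server to journal",
            doi="10.1101/000123",
            journal="bioRxiv",
            published=PartialDate(2016),
            is_preprint=True,
        )
        published = _rec(
            "From server to journal",
            doi="10.1016/j.neuro.2017.01",
            pmid="777",
            journal="Neuron",
            published=PartialDate(2017, 3),
        )
        merged = merge_records(preprint, published)
        assert merged.is_preprint is False
        assert merged.doi == "10.1016/j.neuro.2017.01"
        assert merged.journal == "Neuron" and merged.pmid == "777"
        assert merged.published == PartialDate(2017, 3)

    def test_reverse_preprint_pairing_keeps_published_bibliography(self):
        published = _rec("Order independent", doi="10.1016/j.x", journal="Neuron")
        preprint = _rec("Order independent", doi="10.1101/999", journal="bioRxiv",
                        is_preprint=True)
        conflicts = []
        merged = merge_records(published, preprint, on_conflict=conflicts.append)
        assert merged.doi == "10.1016/j.x" and merged.journal == "Neuron"
        assert merged.is_preprint is False
        assert conflicts == []  # superseded preprint DOI is not a conflict

    def test_conflicting_dois_flagged_not_merged(self):
        existing = _rec("Conflict case", doi="10.1/a")
        incoming = _rec("Conflict case", doi="10.1/b")
        conflicts = []
        merged = merge_records(existing, incoming, on_conflict=conflicts.append)
        assert merged.doi == "10.1/a"
        assert len(conflicts) == 1 and "10.1/b" in conflicts[0]

    def test_triage_state_untouched_by_merge(self):
        existing = _rec("Stay positive", doi="10.1/p")
        existing.triage = TriageState.POSITIVE
        existing.evaluated_date = "2018-01-01T00:00:00"
        merged = merge_records(existing, _rec("Stay positive", pmid="3"))
        assert merged.triage.value == "Positive"


class TestBestTitleMatch:
    def test_exact_candidate_wins_among_decoys(self):
        target = _rec("Exact target title for matching")
        decoys = [_rec("Noise one entirely different"), _rec("Other noise candidate")]
        assert best_title_match("Exact target title for matching", decoys + [target]) is target

    def test_all_below_hard_threshold_gives_none(self):
        decoys = [_rec("Wholly unrelated entry"), _rec("Nothing in common at all")]
        assert best_title_match("Cerebellar granule cell topology", decoys) is None

    def test_tie_breaks_to_earliest_candidate(self):
        a, b = _rec("Twin title"), _rec("Twin title")
        assert best_title_match("Twin title", [a, b]) is a

    def test_agreement_with_exhaustive_argmax(self):
        rng = random.Random(3)
        cfg = SimilarityConfig()
        pool = [
            "dendritic arborization in cortex",
            "dendritic arborizations in cortex",
            "axonal projection mapping atlas",
            "synaptic vesicle release dynamics",
            "glial support of axonal transport",
        ]
        for _ in range(100):
            cands = [_rec(rng.choice(pool) + " " + str(rng.randint(0, 9))) for _ in range(4)]
            query = rng.choice(pool)
            got = best_title_match(query, cands, cfg)
            scores = [
                ref_jaro_winkler(normalize_title(query), normalize_title(c.title))
                for c in cands
            ]
            best_score = max(scores)
            if best_score >= cfg.pubmed_best_match_threshold:
                assert got is cands[scores.index(best_score)]
            else:
                assert got is None
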