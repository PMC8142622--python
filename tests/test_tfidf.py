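"""Inverted index, TF-IDF cosine scoring, query modes, schedule fall-through."""

import math
import random
from collections import Counter

import numpy as np
import pytest

from vinculo.tfidf import InvertedIndex, Query, build_index, candidates_by_index, link_by_index, tokenize

from conftest import make_clean


def corpus(names):
    return [make_clean(f"D{i}", full_name=name) for i, name in enumerate(names)]


class TestTokenize:
    def test_field_prefixes(self):
        rec = make_clean("A", full_name="ANA MARIA", mother_name="RITA",
                         birth_date="1980-01-01", sex="F", municipality_code="2927408")
        toks = tokenize(rec)
        assert toks == Counter(
            {"ANA": 1, "MARIA": 1, "M:RITA": 1, "D:1980-01-01": 1, "S:F": 1, "C:2927408": 1}
        )

    def test_only_attribute_tokens_when_names_missing(self):
        rec = make_clean("A", birth_date="1980-01-01", sex="M")
        assert set(tokenize(rec)) == {"D:1980-01-01", "S:M"}

    def test_repeated_word_term_frequency(self):
        assert tokenize(make_clean("A", full_name="JOSE JOSE"))["JOSE"] == 2


class TestBuildIndex:
    def test_document_frequency_invariant(self):
        index = build_index(corpus(["ANA X", "ANA Y", "ANA Z"]))
        assert index.df["ANA"] == 3
        assert all(index.df[t] == len(index.postings[t]) for t in index.df)
        assert index.N == 3

    def test_absent_token_not_in_vocabulary(self):
        index = build_index(corpus(["ANA"]))
        assert "ZZZ" not in index.df

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_index([])

    def test_duplicate_ids_rejected(self):
        rec = make_clean("A", full_name="ANA")
        with pytest.raises(ValueError, match="duplicate"):
            build_index([rec, rec])


class TestTfidfScore:
    def test_self_similarity_is_one(self):
        index = build_index(corpus(["ANA MARIA", "JOSE SILVA"]))
        assert index.tfidf_score(tokenize(index.records["D0"]), "D0") == pytest.approx(1.0)

    def test_no_shared_tokens_is_zero(self):
        index = build_index(corpus(["ANA", "JOSE"]))
        assert index.tfidf_score(Counter({"XYZ": 1}), "D0") == 0.0

    def test_three_document_hand_computation(self):
        """Corpus {A B}, {A C}, {D}; probe {A B} against doc {A C}: the
        only shared token is A, so the score is the product of A's
        normalized weights in the two vectors."""
        index = build_index(corpus(["A B", "A C", "D"]))
        n = 3
        w_a = (1 + math.log(1)) * math.log(1 + n / 2)  # df(A)=2
        w_b = (1 + math.log(1)) * math.log(1 + n / 1)  # df(B)=1
        expected = (w_a / math.hypot(w_a, w_b)) ** 2  # doc {A C} mirrors probe {A B}
        got = index.tfidf_score(Counter({"A": 1, "B": 1}), "D1")
        assert got == pytest.approx(expected)

    def test_unseen_probe_tokens_drop_out(self):
        index = build_index(corpus(["A B", "C"]))
        full = index.tfidf_score(Counter({"A": 1, "B": 1}), "D0")
        extra = index.tfidf_score(Counter({"A": 1, "B": 1, "NOVEL": 7}), "D0")
        assert full == pytest.approx(1.0)
        assert extra == pytest.approx(1.0)

    def test_matches_brute_force_all_pairs_cosine(self):
        """Index scores equal an independent dense TF-IDF cosine
        computation on a random 50-document corpus."""
        rng = random.Random(4)
        vocab = [f"W{i}" for i in range(30)]
        docs = [" ".join(rng.choices(vocab, k=rng.randint(1, 8))) for _ in range(50)]
        registry = corpus(docs)
        index = build_index(registry)

        tokens = [tokenize(r) for r in registry]
        vocab_used = sorted({t for toks in tokens for t in toks})
        df = {t: sum(t in toks for toks in tokens) for t in vocab_used}
        dense = np.zeros((len(docs), len(vocab_used)))
        for i, toks in enumerate(tokens):
            for j, t in enumerate(vocab_used):
                if toks[t]:
                    dense[i, j] = (1 + math.log(toks[t])) * math.log(1 + len(docs) / df[t])
            dense[i] /= np.linalg.norm(dense[i])
        expected = dense @ dense.T

        for i in range(len(docs)):
            for j in range(len(docs)):
                got = index.tfidf_score(tokens[i], f"D{j}")
                assert got == pytest.approx(min(1.0, expected[i, j]), abs=1e-9)

    def test_symmetric_in_probe_and_candidate(self):
        index = build_index(corpus(["ANA MARIA SILVA", "ANA SOUZA", "RITA SILVA"]))
        for i in range(3):
            for j in range(3):
                a = index.tfidf_score(tokenize(index.records[f"D{i}"]), f"D{j}")
                b = index.tfidf_score(tokenize(index.records[f"D{j}"]), f"D{i}")
                assert a == pytest.approx(b)

    def test_unknown_candidate_rejected(self):
        index = build_index(corpus(["ANA"]))
        with pytest.raises(KeyError):
            index.tfidf_score(Counter({"ANA": 1}), "NOPE")


def full_record(rid, name, mother, date, sex, muni):
    return make_clean(rid, full_name=name, mother_name=mother, birth_date=date,
                      sex=sex, municipality_code=muni)


@pytest.fixture()
def small_index():
    return build_index(
        [
            full_record("R1", "ANA MARIA SILVA", "RITA SILVA", "1980-01-01", "F", "1111111"),
            full_record("R2", "ANA SOUZA", "VERA SOUZA", "1990-05-05", "F", "2222222"),
            full_record("R3", "JOSE SILVA", "RITA SILVA", "1980-01-01", "M", "1111111"),
        ]
    )


class TestQueryModes:
    def test_self_retrieval_rank_one_every_mode(self, small_index):
        for rid, rec in small_index.records.items():
            for mode in ("exact", "semi_exact", "fuzzy"):
                res = small_index.query(Query(record=rec, mode=mode, top_n=5))
                assert res.hits[0][0] == rid
                assert res.hits[0][1] == pytest.approx(1.0)

    def test_exact_requires_agreement_on_probe_fields(self, small_index):
        probe = full_record("P", "ANA MARIA SILVA", "RITA SILVA", "1980-01-01", "F", "1111111")
        res = small_index.query(Query(record=probe, mode="exact"))
        assert [h[0] for h in res.hits] == ["R1"]
        probe_partial = make_clean("P", full_name="ANA MARIA SILVA")
        res = small_index.query(Query(record=probe_partial, mode="exact"))
        assert [h[0] for h in res.hits] == ["R1"]

    def test_semi_exact_empty_when_no_date_agrees(self, small_index):
        probe = full_record("P", "ANA MARIA SILVA", "RITA SILVA", "1985-12-31", "F", "1111111")
        assert not small_index.query(Query(record=probe, mode="semi_exact"))

    def test_semi_exact_ranks_block_by_name(self, small_index):
        probe = full_record("P", "ANA MARIA SILVA", "RITA SILVA", "1980-01-01", "F", "1111111")
        res = small_index.query(Query(record=probe, mode="semi_exact", top_n=5))
        assert [h[0] for h in res.hits] == ["R1", "R3"]  # R3 shares mother + surname

    def test_fuzzy_no_shared_tokens_empty(self, small_index):
        probe = make_clean("P", full_name="XAVIER QUEIROZ")
        assert not small_index.query(Query(record=probe, mode="fuzzy"))

    def test_fuzzy_candidates_are_exactly_token_sharers(self, small_index):
        probe = full_record("P", "ANA BARBOSA", "", "1980-01-01", "M", "9999999")
        res = small_index.query(Query(record=probe, mode="fuzzy", top_n=10))
        got = {h[0] for h in res.hits}
        ptoks = set(tokenize(probe))
        expected = {
            rid for rid, rec in small_index.records.items() if ptoks & set(tokenize(rec))
        }
        assert got == expected

    def test_mode_ordering_exact_subset_semi_subset_fuzzy(self, small_index):
        for rec in small_index.records.values():
            exact = {h[0] for h in small_index.query(Query(record=rec, mode="exact", top_n=10)).hits}
            semi = {h[0] for h in small_index.query(Query(record=rec, mode="semi_exact", top_n=10)).hits}
            fuzzy = {h[0] for h in small_index.query(Query(record=rec, mode="fuzzy", top_n=10)).hits}
            assert exact <= semi <= fuzzy

    def test_invalid_query_parameters_rejected(self, small_index):
        rec = next(iter(small_index.records.values()))
        with pytest.raises(ValueError, match="mode"):
            Query(record=rec, mode="approximate")
        with pytest.raises(ValueError, match="top_n"):
            Query(record=rec, top_n=0)


class TestLinkByIndex:
    def test_exact_schedule_on_identical_registries(self, zero_noise_pair):
        left, right, gold = zero_noise_pair
        result = link_by_index(left, right, schedule=("exact",), cutoff=0.99)
        assert result.linked_pairs == gold.pairs

    def test_fall_through_to_fuzzy_for_corrupted_records(self):
        target = [
            full_record("R1", "ANA MARIA SILVA", "RITA SILVA", "1980-01-01", "F", "1111111"),
            full_record("R2", "JOSE SANTOS", "VERA SANTOS", "1990-05-05", "M", "2222222"),
        ]
        probes = [
            # identical: resolved by exact mode
            full_record("P1", "ANA MARIA SILVA", "RITA SILVA", "1980-01-01", "F", "1111111"),
            # corrupted name token + corrupted date: only fuzzy can find it
            full_record("P2", "JOSE SANTQS", "VERA SANTOS", "1990-05-06", "M", "2222222"),
        ]
        index = build_index(target)
        exact_only = candidates_by_index(probes, index, schedule=("exact",))
        assert {p.left_id for p in exact_only} == {"P1"}
        scheduled = candidates_by_index(probes, index, schedule=("exact", "fuzzy"))
        by_left = {p.left_id: p.right_id for p in scheduled}
        assert by_left == {"P1": "R1", "P2": "R2"}

    def test_unreachable_cutoff_yields_zero_links(self, zero_noise_pair):
        left, right, _ = zero_noise_pair
        result = link_by_index(left, right, cutoff=1.01)
        assert result.links == []

    def test_unknown_mode_in_schedule_rejected(self, zero_noise_pair):
        left, right, _ = zero_noise_pair
        with pytest.raises(ValueError, match="mode"):
            link_by_index(left, right, schedule=("sloppy",))

    def test_deterministic(self, noisy_pair):
        left, right, _ = noisy_pair
        a = link_by_index(left, right, cutoff=0.4)
        b = link_by_index(left, right, cutoff=0.4)
        assert a.links == b.links
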