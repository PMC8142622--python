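"""Bigram Bloom encoding, Dice similarity, blocking, composite scoring."""

import hashlib
import itertools
import random

import pytest

from vinculo.bloom import (
    BloomParams,
    BloomVector,
    BlockingPredicate,
    bigrams,
    build_blocks,
    classify,
    default_predicates,
    dice,
    encode_bloom,
    link_bloom,
    score_candidates,
)
from vinculo.records import LINKAGE_FIELDS

from conftest import make_clean


class TestBigrams:
    @pytest.mark.parametrize(
        "token,padding,expected",
        [
            ("ANA", True, ["_A", "AN", "NA", "A_"]),
            ("ANA", False, ["AN", "NA"]),
            ("", True, []),
            ("A", False, []),
        ],
    )
    def test_examples(self, token, padding, expected):
        assert bigrams(token, padding) == expected


class TestEncodeBloom:
    def test_deterministic(self):
        params = BloomParams(m=64, k=2)
        assert encode_bloom("ANA", params, "s") == encode_bloom("ANA", params, "s")

    def test_salt_separates_fields(self):
        params = BloomParams(m=64, k=2)
        assert encode_bloom("ANA", params, "full_name") != encode_bloom("ANA", params, "mother_name")

    def test_empty_is_zero_vector(self):
        vec = encode_bloom("", BloomParams(), "s")
        assert vec.bits == 0 and vec.set_count == 0

    def test_matches_independent_index_enumeration(self):
        """Brute-force the documented double-hashing scheme with hashlib
        directly and compare the resulting bit sets."""
        m, k, salt = 64, 2, "full_name"
        expected_bits = set()
        for bg in ["_A", "AN", "NA", "A_"]:
            digest = hashlib.blake2b(bg.encode(), key=salt.encode(), digest_size=16).digest()
            h1 = int.from_bytes(digest[:8], "big")
            h2 = int.from_bytes(digest[8:], "big")
            for i in range(k):
                expected_bits.add((h1 + i * h2) % m)
        vec = encode_bloom("ANA", BloomParams(m=m, k=k), salt)
        assert {b for b in range(m) if vec.bits >> b & 1} == expected_bits
        assert vec.set_count <= 8  # 4 padded bigrams x 2 hashes, collisions may reduce

    def test_rejects_degenerate_params(self):
        with pytest.raises(ValueError, match="m must be"):
            BloomParams(m=4)
        with pytest.raises(ValueError, match="k must be"):
            BloomParams(k=0)
        with pytest.raises(ValueError, match="non-negative"):
            BloomParams(weights={"full_name": -1.0})


class TestDice:
    def test_exhaustive_four_bit_oracle(self):
        """All 256 pairs of 4-bit vectors against a hand popcount oracle."""
        for a_bits, b_bits in itertools.product(range(16), repeat=2):
            a, b = BloomVector(a_bits, 4), BloomVector(b_bits, 4)
            na = bin(a_bits).count("1")
            nb = bin(b_bits).count("1")
            inter = bin(a_bits & b_bits).count("1")
            expected = 2 * inter / (na + nb) if na + nb else 0.0
            assert dice(a, b) == pytest.approx(expected)
            assert dice(a, b) == pytest.approx(dice(b, a))  # symmetry
            assert 0.0 <= dice(a, b) <= 1.0

    def test_identity_and_disjoint_and_hand_value(self):
        assert dice(BloomVector(0b1110, 4), BloomVector(0b1110, 4)) == 1.0
        assert dice(BloomVector(0b1100, 4), BloomVector(0b0011, 4)) == 0.0
        assert dice(BloomVector(0b1110, 4), BloomVector(0b0110, 4)) == pytest.approx(0.8)

    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="lengths differ"):
            dice(BloomVector(0, 8), BloomVector(0, 16))


class TestBuildBlocks:
    def test_single_predicate(self):
        left = [make_clean("A", municipality_code="1111111"),
                make_clean("B", municipality_code="2222222")]
        right = [make_clean("C", municipality_code="1111111")]
        pred = BlockingPredicate("muni", lambda r: r.municipality_code)
        assert build_blocks(left, right, [pred]) == {("A", "C")}

    def test_pair_counted_once_across_predicates(self):
        left = [make_clean("A", municipality_code="1111111", sex="M", full_name="JO SILVA")]
        right = [make_clean("C", municipality_code="1111111", sex="M", full_name="JO SOUZA")]
        pairs = build_blocks(left, right, default_predicates())
        assert pairs == {("A", "C")}

    def test_cross_product_count(self):
        left = [make_clean(f"L{i}", municipality_code="1111111") for i in range(10)]
        right = [make_clean(f"R{i}", municipality_code="1111111") for i in range(10)]
        pred = BlockingPredicate("muni", lambda r: r.municipality_code)
        assert len(build_blocks(left, right, [pred])) == 100

    def test_missing_predicate_input_gets_no_label(self):
        left = [make_clean("A")]  # everything missing
        right = [make_clean("C")]
        assert build_blocks(left, right, default_predicates()) == set()

    def test_empty_predicate_list_rejected(self):
        with pytest.raises(ValueError, match="predicate"):
            build_blocks([], [], [])

    def test_blocking_recall_on_uncorrupted_attributes(self, zero_noise_pair):
        left, right, gold = zero_noise_pair
        pairs = build_blocks(left, right, default_predicates())
        assert gold.pairs <= pairs


class TestScoring:
    def test_identical_records_score_one(self):
        rec = make_clean("A", full_name="ANA SILVA", sex="F", mother_name="RITA SILVA",
                         birth_date="1980-01-01", municipality_code="2927408")
        twin = make_clean("B", **{f: getattr(rec, f) for f in LINKAGE_FIELDS})
        (pair,) = score_candidates([rec], [twin], [("A", "B")], BloomParams())
        assert pair.composite == pytest.approx(1.0)
        assert all(s == pytest.approx(1.0) for s in pair.field_scores)

    def test_fully_disagreeing_records_score_near_zero(self):
        a = make_clean("A", full_name="XQZW VKJP", sex="F", mother_name="GHRT YULM",
                       birth_date="1980-01-01", municipality_code="1111111")
        b = make_clean("B", full_name="EEEE OOOO", sex="M", mother_name="IIII AAAA",
                       birth_date="1999-09-09", municipality_code="2222222")
        # disjoint bigram sets: name Dice is zero up to hash collisions,
        # which vanish as the filter grows sparse
        (pair,) = score_candidates([a], [b], [("A", "B")], BloomParams(m=4096))
        assert all(s == 0.0 for s in pair.field_scores[2:])  # categoricals disagree exactly
        assert pair.composite < 0.05

    def test_weights_renormalize_over_present_fields(self):
        a = make_clean("A", full_name="ANA SILVA", birth_date="1980-01-01")
        b = make_clean("B", full_name="ANA SILVA", birth_date="1980-01-01")
        (pair,) = score_candidates([a], [b], [("A", "B")], BloomParams())
        # only name and date present, both agree -> composite exactly 1
        assert pair.composite == pytest.approx(1.0)
        assert pair.field_score_map["mother_name"] is None
        assert pair.field_score_map["sex"] is None

    def test_composite_equals_brute_force_recomputation(self, noisy_pair):
        """Composite scores agree with an independent recomputation from
        the raw fields over >=1000 random candidate pairs."""
        left, right, gold = noisy_pair
        rng = random.Random(0)
        candidates = {
            (l.record_id, r.record_id)
            for l, r in zip(rng.choices(left, k=1200), rng.choices(right, k=1200))
        }
        params = BloomParams()
        scored = score_candidates(left, right, candidates, params)
        lmap = {r.record_id: r for r in left}
        rmap = {r.record_id: r for r in right}
        for pair in scored:
            a, b = lmap[pair.left_id], rmap[pair.right_id]
            num = den = 0.0
            for fld, w in params.weights.items():
                va, vb = getattr(a, fld), getattr(b, fld)
                if va in (None, "") or vb in (None, ""):
                    continue
                if fld in ("full_name", "mother_name"):
                    s = dice(encode_bloom(va, params, fld), encode_bloom(vb, params, fld))
                else:
                    s = 1.0 if va == vb else 0.0
                num += w * s
                den += w
            expected = num / den if den else 0.0
            assert pair.composite == pytest.approx(expected)

    def test_sorted_by_score_then_ids(self, noisy_pair):
        left, right, _ = noisy_pair
        pairs = build_blocks(left, right, default_predicates())
        scored = score_candidates(left, right, pairs, BloomParams())
        keys = [(-p.composite, p.left_id, p.right_id) for p in scored]
        assert keys == sorted(keys)

    def test_end_to_end_determinism(self, noisy_pair):
        left, right, _ = noisy_pair
        pairs = build_blocks(left, right, default_predicates())
        a = score_candidates(left, right, pairs, BloomParams())
        b = score_candidates(left, right, pairs, BloomParams())
        assert a == b


class TestClassify:
    def _pairs(self, specs):
        from vinculo.bloom import ScoredPair

        return [ScoredPair(l, r, (None,) * 5, s) for l, r, s in specs]

    def test_all_below_cutoff(self):
        result = classify(self._pairs([("A", "B", 0.4)]), 0.8)
        assert result.links == [] and result.n_above_cutoff == 0

    def test_greedy_one_to_one(self):
        scored = self._pairs([("A", "X", 0.95), ("A", "Y", 0.90)])
        result = classify(scored, 0.8)
        assert result.links == [("A", "X", 0.95)]
        assert result.n_above_cutoff == 2
        assert {p.classification for p in result.pairs} == {"linked", "not_linked"}

    def test_threshold_count_on_disjoint_pairs(self):
        scored = self._pairs([("A", "X", 0.95), ("B", "Y", 0.85), ("C", "Z", 0.40)])
        result = classify(scored, 0.8)
        assert len(result.links) == 2

    def test_lowering_cutoff_never_reduces_above_cutoff_count(self, noisy_pair):
        left, right, _ = noisy_pair
        scored = score_candidates(
            left, right, build_blocks(left, right, default_predicates()), BloomParams()
        )
        counts = [classify(scored, c).n_above_cutoff for c in (0.9, 0.7, 0.5, 0.3, 0.0)]
        assert counts == sorted(counts)

    def test_zero_noise_end_to_end(self, zero_noise_pair):
        left, right, gold = zero_noise_pair
        result = link_bloom(left, right, cutoff=0.9)
        assert result.linked_pairs == gold.pairs
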