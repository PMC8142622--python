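"""Bloom-filter probabilistic linkage.

Predicate blocking selects candidate pairs; name fields are encoded as
bigram Bloom filters (double hashing, per-field salts) and compared with
the Dice coefficient; categorical attributes (birth date, sex,
municipality code) contribute exact-agreement indicators.  The
composite score is a weighted mean over the fields present in both
records, with weights renormalized over present fields.  Classification
applies a score cut-off followed by greedy one-to-one resolution in
descending score order.

Encoding a field value never exposes it for plaintext comparison: the
bit vectors alone support similarity computation, which is what makes
this scheme usable for privacy-preserving linkage.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter, defaultdict
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

from .records import CleanRecord

#: Scoring order of linkage fields (names by Dice, the rest exact-agreement).
SCORED_FIELDS = ("full_name", "mother_name", "birth_date", "sex", "municipality_code")

DEFAULT_WEIGHTS = {
    "full_name": 0.40,
    "mother_name": 0.25,
    "birth_date": 0.15,
    "sex": 0.05,
    "municipality_code": 0.15,
}


@dataclass(frozen=True)
class BloomParams:
    """Bloom encoding and composite-scoring parameters.

    ``m`` is the filter length in bits, ``k`` the number of hash
    functions per bigram (realised by double hashing), ``padding`` wraps
    tokens in a boundary symbol before bigram extraction.  ``weights``
    must be non-negative over :data:`SCORED_FIELDS`; they are
    renormalized to sum to 1.
    """

    m: int = 128
    k: int = 3
    padding: bool = True
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        if self.m < 8:
            raise ValueError(f"Bloom length m must be >= 8, got {self.m}")
        if self.k < 1:
            raise ValueError(f"hash count k must be >= 1, got {self.k}")
        unknown = set(self.weights) - set(SCORED_FIELDS)
        if unknown:
            raise ValueError(f"weights for unknown fields: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("field weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("field weights must not all be zero")
        object.__setattr__(
            self, "weights", {f: w / total for f, w in self.weights.items()}
        )


@dataclass(frozen=True, slots=True)
class BloomVector:
    """Fixed-length binary vector; ``bits`` is an int bitmask of width ``m``."""

    bits: int
    m: int

    @property
    def set_count(self) -> int:
        return self.bits.bit_count()


def bigrams(token: str, padding: bool = True) -> list[str]:
    """Consecutive character pairs of ``token`` (a multiset, order kept).

    With ``padding`` the token is wrapped in the boundary symbol ``_``:
    ``bigrams("ANA")`` → ``['_A', 'AN', 'NA', 'A_']``.  Empty input
    yields an empty list.
    """
    if not token:
        return []
    text = f"_{token}_" if padding else token
    return [text[i : i + 2] for i in range(len(text) - 1)]


def _base_hashes(bigram: str, salt: str) -> tuple[int, int]:
    digest = hashlib.blake2b(
        bigram.encode("utf-8"), key=salt.encode("utf-8"), digest_size=16
    ).digest()
    return int.from_bytes(digest[:8], "big"), int.from_bytes(digest[8:], "big")


def encode_bloom(
    field_value: str,
    params: BloomParams,
    field_salt: str,
    _cache: dict | None = None,
) -> BloomVector:
    """Encode a normalized field value as a salted bigram Bloom filter.

    Each bigram sets ``k`` bits via double hashing: with base hashes
    h1, h2 of the salted bigram, bit ``(h1 + i*h2) mod m`` is set for
    i = 0..k-1.  Deterministic for fixed params and salt; the empty
    string encodes to the all-zero vector.
    """
    bits = 0
    m, k = params.m, params.k
    for bg in bigrams(field_value, params.padding):
        key = (bg, field_salt)
        pair = _cache.get(key) if _cache is not None else None
        if pair is None:
            pair = _base_hashes(bg, field_salt)
            if _cache is not None:
                _cache[key] = pair
        h1, h2 = pair
        for i in range(k):
            bits |= 1 << ((h1 + i * h2) % m)
    return BloomVector(bits=bits, m=m)


def dice(a: BloomVector, b: BloomVector) -> float:
    """Dice coefficient 2|a∧b| / (|a|+|b|) of two equal-length vectors.

    Two all-zero vectors are uninformative; the coefficient is defined
    as 0.0 there (callers treat such fields as missing when scoring).
    """
    if a.m != b.m:
        raise ValueError(f"Bloom vector lengths differ: {a.m} != {b.m}")
    total = a.set_count + b.set_count
    if total == 0:
        return 0.0
    return 2.0 * (a.bits & b.bits).bit_count() / total


# ---------------------------------------------------------------------------
# blocking


@dataclass(frozen=True)
class BlockingPredicate:
    """Named key function mapping a record to a block label (or None).

    Records with missing predicate inputs receive no label — they are
    never globbed into a shared catch-all block.
    """

    name: str
    key: Callable[[CleanRecord], str | None]

    def label(self, record: CleanRecord) -> str | None:
        return self.key(record)


def _municipality_key(r: CleanRecord) -> str | None:
    return r.municipality_code


def _birth_year_key(r: CleanRecord) -> str | None:
    return r.birth_date[:4] if r.birth_date else None


def _name2_sex_key(r: CleanRecord) -> str | None:
    if len(r.full_name) < 2 or not r.sex:
        return None
    return f"{r.full_name[:2]}|{r.sex}"


def default_predicates() -> list[BlockingPredicate]:
    """Municipality code, birth year, and first-two-letters-of-name + sex."""
    return [
        BlockingPredicate("municipality", _municipality_key),
        BlockingPredicate("birth_year", _birth_year_key),
        BlockingPredicate("name2_sex", _name2_sex_key),
    ]


def build_blocks(
    left: Sequence[CleanRecord],
    right: Sequence[CleanRecord],
    predicates: Sequence[BlockingPredicate],
) -> set[tuple[str, str]]:
    """Union over predicates of within-block cross pairs (each pair once).

    An empty predicate list is rejected: it would silently force an
    all-pairs comparison, which must be an explicit caller decision.
    """
    if not predicates:
        raise ValueError("at least one blocking predicate is required")
    candidates: set[tuple[str, str]] = set()
    for pred in predicates:
        right_blocks: dict[str, list[str]] = defaultdict(list)
        for rec in right:
            label = pred.label(rec)
            if label is not None:
                right_blocks[label].append(rec.record_id)
        for rec in left:
            label = pred.label(rec)
            if label is None:
                continue
            for rid in right_blocks.get(label, ()):
                candidates.add((rec.record_id, rid))
    return candidates


# ---------------------------------------------------------------------------
# encoding and scoring


def encode_registry(
    registry: Iterable[CleanRecord],
    params: BloomParams,
    _cache: dict | None = None,
) -> dict[str, tuple]:
    """Precompute per-record field encodings for scoring.

    Returns record_id → (name_bloom, mother_bloom, birth_date, sex,
    municipality_code); Bloom fields use per-field salts so identical
    values in different fields set different bits.
    """
    if _cache is None:
        _cache = {}
    encoded: dict[str, tuple] = {}
    for rec in registry:
        encoded[rec.record_id] = (
            encode_bloom(rec.full_name, params, "full_name", _cache),
            encode_bloom(rec.mother_name, params, "mother_name", _cache),
            rec.birth_date,
            rec.sex or None,
            rec.municipality_code,
        )
    return encoded


@dataclass(slots=True)
class ScoredPair:
    """Candidate pair with per-field and composite similarity scores.

    ``field_scores`` follows :data:`SCORED_FIELDS` order; ``None`` marks
    a field missing on either side (excluded from the composite, whose
    weights renormalize over present fields).  ``classification`` is
    one of ``linked`` / ``not_linked`` / ``unclassified`` and is set
    only once a cut-off has been applied.
    """

    left_id: str
    right_id: str
    field_scores: tuple[float | None, ...]
    composite: float
    classification: str = "unclassified"

    @property
    def field_score_map(self) -> dict[str, float | None]:
        return dict(zip(SCORED_FIELDS, self.field_scores))


def score_candidates(
    left: Sequence[CleanRecord],
    right: Sequence[CleanRecord],
    candidates: Iterable[tuple[str, str]],
    params: BloomParams,
) -> list[ScoredPair]:
    """Score every candidate pair; sorted by composite desc, ties by ids.

    Name fields score by Dice over Bloom encodings; birth date, sex and
    municipality score 1.0/0.0 by exact agreement.  A field empty or
    missing on either side is excluded and the remaining weights are
    renormalized; a pair with no informative field scores 0.0.
    """
    cache: dict = {}
    left_enc = encode_registry(left, params, cache)
    right_enc = encode_registry(right, params, cache)
    w = params.weights
    weights = tuple(w.get(f, 0.0) for f in SCORED_FIELDS)
    scored: list[ScoredPair] = []
    for lid, rid in candidates:
        le, re = left_enc[lid], right_enc[rid]
        fs: list[float | None] = [None] * 5
        # Dice over name Blooms (empty value -> all-zero vector -> missing)
        for slot, idx in ((0, 0), (1, 1)):
            a, b = le[idx], re[idx]
            if a.set_count and b.set_count:
                fs[slot] = dice(a, b)
        # exact-agreement indicators for birth_date, sex, municipality
        for slot, idx in ((2, 2), (3, 3), (4, 4)):
            a, b = le[idx], re[idx]
            if a is not None and b is not None:
                fs[slot] = 1.0 if a == b else 0.0
        wsum = num = 0.0
        for slot in range(5):
            s = fs[slot]
            if s is not None:
                num += weights[slot] * s
                wsum += weights[slot]
        composite = num / wsum if wsum > 0 else 0.0
        scored.append(ScoredPair(lid, rid, tuple(fs), composite))
    scored.sort(key=lambda p: (-p.composite, p.left_id, p.right_id))
    return scored


# ---------------------------------------------------------------------------
# classification


@dataclass(slots=True)
class LinkageResult:
    """Outcome of applying a cut-off plus one-to-one resolution.

    ``links`` holds the accepted (left_id, right_id, score) triples;
    ``n_above_cutoff`` counts pairs at or above the cut-off *before*
    resolution; ``pairs`` is the full scored list with classifications.
    """

    links: list[tuple[str, str, float]]
    n_above_cutoff: int
    pairs: list[ScoredPair]

    @property
    def linked_pairs(self) -> set[tuple[str, str]]:
        return {(l, r) for l, r, _ in self.links}


def classify(scored: Sequence[ScoredPair], cutoff: float) -> LinkageResult:
    """Threshold then greedily resolve to a one-to-one linked set.

    Pairs scoring at or above ``cutoff`` are provisionally linked; they
    are then accepted in descending score order (ties by ids), skipping
    any pair whose left or right record is already taken.  Skipped and
    sub-cutoff pairs are classified ``not_linked``.
    """
    ordered = sorted(scored, key=lambda p: (-p.composite, p.left_id, p.right_id))
    taken_left: set[str] = set()
    taken_right: set[str] = set()
    links: list[tuple[str, str, float]] = []
    n_above = 0
    for pair in ordered:
        if pair.composite >= cutoff:
            n_above += 1
            if pair.left_id not in taken_left and pair.right_id not in taken_right:
                pair.classification = "linked"
                taken_left.add(pair.left_id)
                taken_right.add(pair.right_id)
                links.append((pair.left_id, pair.right_id, pair.composite))
                continue
        pair.classification = "not_linked"
    return LinkageResult(links=links, n_above_cutoff=n_above, pairs=ordered)


def link_bloom(
    left: Sequence[CleanRecord],
    right: Sequence[CleanRecord],
    cutoff: float,
    params: BloomParams | None = None,
    predicates: Sequence[BlockingPredicate] | None = None,
) -> LinkageResult:
    """Full Bloom pipeline: block, score, classify at ``cutoff``."""
    params = params or BloomParams()
    candidates = build_blocks(left, right, predicates or default_predicates())
    scored = score_candidates(left, right, candidates, params)
    return classify(scored, cutoff)
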