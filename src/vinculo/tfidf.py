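"""TF-IDF inverted-index linkage.

The right-hand registry is indexed once: word tokens from the person's
and mother's names (mother tokens prefixed to keep the fields distinct)
plus single tokens for birth date, sex and municipality code.  Each
probe record is answered by one of three query modes — *exact* (full
agreement on every attribute the probe carries), *semi-exact* (exact
birth date + municipality, names ranked by TF-IDF) or *fuzzy*
(candidates gathered through shared postings, ranked by TF-IDF over all
tokens) — and a mode schedule falls through from cheapest to loosest.

Token weights follow w(t) = (1 + ln tf) · ln(1 + N/df); vectors are
L2-normalized so the score is a cosine in [0, 1].
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from collections.abc import Sequence
from dataclasses import dataclass, field

from .bloom import LinkageResult, ScoredPair, classify
from .records import CleanRecord

QUERY_MODES = ("exact", "semi_exact", "fuzzy")


def tokenize(record: CleanRecord) -> Counter[str]:
    """Token multiset of one record.

    Name words appear as-is, mother-name words carry an ``M:`` prefix,
    and present categorical attributes contribute one token each
    (``D:<date>``, ``S:<sex>``, ``C:<code>``).
    """
    tokens: Counter[str] = Counter()
    if record.full_name:
        tokens.update(record.full_name.split(" "))
    if record.mother_name:
        tokens.update(f"M:{w}" for w in record.mother_name.split(" "))
    if record.birth_date:
        tokens[f"D:{record.birth_date}"] += 1
    if record.sex:
        tokens[f"S:{record.sex}"] += 1
    if record.municipality_code:
        tokens[f"C:{record.municipality_code}"] += 1
    return tokens


@dataclass(frozen=True)
class Query:
    """One probe against the index."""

    record: CleanRecord
    mode: str = "fuzzy"
    top_n: int = 10
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in QUERY_MODES:
            raise ValueError(f"unknown query mode {self.mode!r}; expected one of {QUERY_MODES}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")


@dataclass
class QueryResult:
    """Ranked (record_id, score) hits, descending score, ties by id."""

    hits: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __bool__(self) -> bool:
        return bool(self.hits)

    @property
    def best(self) -> tuple[str, float] | None:
        return self.hits[0] if self.hits else None


class InvertedIndex:
    """Inverted index with TF-IDF weights over a cleaned registry."""

    def __init__(self, registry: Sequence[CleanRecord]):
        if not registry:
            raise ValueError("cannot index an empty registry")
        self.records: dict[str, CleanRecord] = {}
        self.doc_tokens: dict[str, Counter[str]] = {}
        self.df: dict[str, int] = defaultdict(int)
        for rec in registry:
            if rec.record_id in self.records:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            self.records[rec.record_id] = rec
            toks = tokenize(rec)
            self.doc_tokens[rec.record_id] = toks
            for t in toks:
                self.df[t] += 1
        self.df = dict(self.df)
        self.N = len(self.records)

        # normalized document vectors, stored token-major for
        # term-at-a-time accumulation: token -> [(record_id, weight)]
        self.postings: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.weighted_postings: dict[str, list[tuple[str, float]]] = defaultdict(list)
        for rid, toks in self.doc_tokens.items():
            vec = self._weigh(toks)
            for t, tf in toks.items():
                self.postings[t].append((rid, tf))
            for t, w in vec.items():
                self.weighted_postings[t].append((rid, w))
        self.postings = dict(self.postings)
        self.weighted_postings = dict(self.weighted_postings)

        # exact-mode fast path and semi-exact blocks
        self._by_full_key: dict[tuple, list[str]] = defaultdict(list)
        self._by_date_muni: dict[tuple[str, str], list[str]] = defaultdict(list)
        for rid, rec in self.records.items():
            self._by_full_key[rec.linkage_key()].append(rid)
            if rec.birth_date and rec.municipality_code:
                self._by_date_muni[(rec.birth_date, rec.municipality_code)].append(rid)

    # -- weighting ---------------------------------------------------------

    def _weigh(self, tokens: Counter[str], restrict_names: bool = False) -> dict[str, float]:
        """L2-normalized TF-IDF vector; tokens unseen in the corpus get
        weight zero and drop out."""
        vec: dict[str, float] = {}
        for t, tf in tokens.items():
            if restrict_names and t.startswith(("D:", "S:", "C:")):
                continue
            df = self.df.get(t, 0)
            if df == 0:
                continue
            vec[t] = (1.0 + math.log(tf)) * math.log(1.0 + self.N / df)
        norm = math.sqrt(sum(w * w for w in vec.values()))
        if norm > 0:
            vec = {t: w / norm for t, w in vec.items()}
        return vec

    def tfidf_score(
        self, probe_tokens: Counter[str], record_id: str, *, names_only: bool = False
    ) -> float:
        """Cosine TF-IDF similarity between a probe and an indexed record."""
        if record_id not in self.records:
            raise KeyError(f"record {record_id!r} is not indexed")
        doc = self.doc_tokens[record_id]
        pv = self._weigh(probe_tokens, restrict_names=names_only)
        dv = self._weigh(doc, restrict_names=names_only)
        if len(pv) > len(dv):
            pv, dv = dv, pv
        return min(1.0, sum(w * dv.get(t, 0.0) for t, w in pv.items()))

    # -- query modes -------------------------------------------------------

    def _gather(self, tokens: Counter[str]) -> set[str]:
        """Records sharing at least one token with the probe."""
        out: set[str] = set()
        for t in tokens:
            for rid, _ in self.postings.get(t, ()):
                out.add(rid)
        return out

    def _exact_candidates(self, probe: CleanRecord) -> list[str]:
        present = [
            (f, getattr(probe, f))
            for f in ("full_name", "sex", "mother_name", "birth_date", "municipality_code")
            if getattr(probe, f) not in (None, "")
        ]
        if not present:
            return []
        if len(present) == 5:
            return list(self._by_full_key.get(probe.linkage_key(), ()))
        hits = []
        for rid in self._gather(tokenize(probe)):
            cand = self.records[rid]
            if all(getattr(cand, f) == v for f, v in present):
                hits.append(rid)
        return hits

    def query(self, q: Query) -> QueryResult:
        """Answer one probe in the requested mode.

        *exact* returns, at score 1.0, candidates agreeing on every
        attribute the probe carries (a candidate missing one of those
        attributes does not agree).  *semi-exact* requires exact
        agreement on birth date and municipality code and ranks the
        block by name-token TF-IDF.  *fuzzy* gathers candidates sharing
        at least one token and ranks by TF-IDF over all tokens.  All
        modes drop scores below ``q.cutoff`` and keep the top
        ``q.top_n``.
        """
        probe = q.record
        if q.mode == "exact":
            scored = [(rid, 1.0) for rid in self._exact_candidates(probe)]
        elif q.mode == "semi_exact":
            if not probe.birth_date or not probe.municipality_code:
                return QueryResult([])
            block = self._by_date_muni.get((probe.birth_date, probe.municipality_code), [])
            ptoks = tokenize(probe)
            # a block member sharing no name token is a coincidence of
            # date+municipality, not a result: rank-zero hits are dropped
            # so the mode schedule can fall through
            scored = [
                (rid, s)
                for rid in block
                if (s := self.tfidf_score(ptoks, rid, names_only=True)) > 0.0
            ]
        else:  # fuzzy
            ptoks = tokenize(probe)
            pv = self._weigh(ptoks)
            acc: dict[str, float] = defaultdict(float)
            for t, w in pv.items():
                for rid, dw in self.weighted_postings.get(t, ()):
                    acc[rid] += w * dw
            scored = [(rid, min(1.0, s)) for rid, s in acc.items()]
        scored = [(rid, s) for rid, s in scored if s >= q.cutoff]
        scored.sort(key=lambda h: (-h[1], h[0]))
        return QueryResult(scored[: q.top_n])


def build_index(registry: Sequence[CleanRecord]) -> InvertedIndex:
    """Index a cleaned, deduplicated registry."""
    return InvertedIndex(registry)


# ---------------------------------------------------------------------------
# registry-against-registry linkage


def candidates_by_index(
    left: Sequence[CleanRecord],
    index: InvertedIndex,
    schedule: Sequence[str] = QUERY_MODES,
    top_n: int = 10,
    cutoff: float = 0.0,
) -> list[ScoredPair]:
    """Best candidate per probe under a fall-through mode schedule.

    Each left record is probed with the modes in order; sub-cutoff hits
    are dropped inside the query, so a mode whose survivors are empty
    falls through to the next.  The top-ranked surviving hit becomes
    the probe's tentative pair.  Run with ``cutoff=0.0`` to collect
    uncensored scores for calibration.
    """
    for mode in schedule:
        if mode not in QUERY_MODES:
            raise ValueError(f"unknown query mode {mode!r} in schedule")
    pairs: list[ScoredPair] = []
    for rec in left:
        for mode in schedule:
            res = index.query(Query(record=rec, mode=mode, top_n=top_n, cutoff=cutoff))
            if res:
                rid, score = res.hits[0]
                pairs.append(ScoredPair(rec.record_id, rid, (None,) * 5, score))
                break
    pairs.sort(key=lambda p: (-p.composite, p.left_id, p.right_id))
    return pairs


def link_by_index(
    left: Sequence[CleanRecord],
    right: Sequence[CleanRecord] | InvertedIndex,
    schedule: Sequence[str] = QUERY_MODES,
    top_n: int = 10,
    cutoff: float = 0.0,
) -> LinkageResult:
    """Index-based linkage with cut-off and one-to-one resolution."""
    index = right if isinstance(right, InvertedIndex) else build_index(right)
    tentative = candidates_by_index(left, index, schedule, top_n, cutoff=cutoff)
    return classify(tentative, cutoff)
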