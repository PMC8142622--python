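"""Deterministic linkage: unique-key joins and the two-stage birth strategy.

Social-programme registries share a unique social identification key
(NIS), so they link by exact key agreement; a key occurring more than
once on either side is a data-quality event that is *reported*, never
silently resolved.  Birth registries need the two-stage strategy:
newborns may be unnamed at registration, so their mothers are first
linked probabilistically to the target registry, and in a second stage
each child is attached deterministically through the linked mother plus
the child's own birth date (and sex when present) — the child's name is
never used.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

from .bloom import (
    BloomParams,
    BlockingPredicate,
    build_blocks,
    default_predicates,
    score_candidates,
)
from .records import CleanRecord
from .tfidf import InvertedIndex, Query, build_index

_KEY_FIELDS = ("nis", "municipality_code", "birth_date", "full_name", "mother_name", "sex")


@dataclass
class KeyJoinResult:
    """Outcome of an exact unique-key join.

    ``ambiguous`` maps each key occurring more than once on either side
    to the record ids carrying it; such keys contribute no pairs.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmatched_left: list[str] = field(default_factory=list)
    ambiguous: dict[str, dict[str, list[str]]] = field(default_factory=dict)


def link_by_key(
    left: Sequence[CleanRecord],
    right: Sequence[CleanRecord],
    key_field: str = "nis",
) -> KeyJoinResult:
    """Join two registries on exact agreement of a unique key.

    Pairs form only for keys present and unique on both sides; missing
    keys never match.  Left records without a pair are listed in
    ``unmatched_left`` in input order.
    """
    if key_field not in _KEY_FIELDS:
        raise ValueError(f"unknown key field {key_field!r}; expected one of {_KEY_FIELDS}")

    def key_map(registry: Sequence[CleanRecord]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for rec in registry:
            value = getattr(rec, key_field)
            if value not in (None, ""):
                out[value].append(rec.record_id)
        return out

    left_keys = key_map(left)
    right_keys = key_map(right)
    result = KeyJoinResult()
    for key in set(left_keys) | set(right_keys):
        lids = left_keys.get(key, [])
        rids = right_keys.get(key, [])
        if len(lids) > 1 or len(rids) > 1:
            result.ambiguous[key] = {"left": lids, "right": rids}
    matched_left: set[str] = set()
    for rec in left:
        value = getattr(rec, key_field)
        if value in (None, "") or value in result.ambiguous:
            continue
        rids = right_keys.get(value, [])
        if len(rids) == 1:
            result.pairs.append((rec.record_id, rids[0]))
            matched_left.add(rec.record_id)
    result.unmatched_left = [r.record_id for r in left if r.record_id not in matched_left]
    return result


# ---------------------------------------------------------------------------
# two-stage mother–child linkage

#: stage-1 linker: (mother probes, target registry, cutoff) -> {probe_id: (target_id, score)}
Stage1Linker = Callable[[Sequence[CleanRecord], Sequence[CleanRecord], float], dict[str, tuple[str, float]]]


def _mother_probe(birth: CleanRecord) -> CleanRecord:
    """Probe carrying the mother's attributes available on a birth record:
    her full name (the record's mother_name) and the municipality."""
    return CleanRecord(
        record_id=birth.record_id,
        full_name=birth.mother_name,
        sex="",
        mother_name="",
        birth_date=None,
        municipality_code=birth.municipality_code,
        nis=None,
    )


def _stage1_predicates() -> list[BlockingPredicate]:
    """Mother probes carry only name + municipality, so block on the
    municipality and on the first two letters of the name alone."""
    return [
        BlockingPredicate("municipality", lambda r: r.municipality_code),
        BlockingPredicate("name2", lambda r: r.full_name[:2] if len(r.full_name) >= 2 else None),
    ]


def bloom_stage1(params: BloomParams | None = None) -> Stage1Linker:
    """Stage-1 linker scoring mother probes with the Bloom machinery.

    Assignment is many-to-one by design: several births may share one
    mother, so each probe independently keeps its best target at or
    above the cut-off.
    """
    bloom_params = params or BloomParams()

    def linker(
        probes: Sequence[CleanRecord], target: Sequence[CleanRecord], cutoff: float
    ) -> dict[str, tuple[str, float]]:
        candidates = build_blocks(probes, target, _stage1_predicates())
        scored = score_candidates(probes, target, candidates, bloom_params)
        best: dict[str, tuple[str, float]] = {}
        for pair in scored:  # already sorted: first hit per probe is its best
            if pair.composite >= cutoff and pair.left_id not in best:
                best[pair.left_id] = (pair.right_id, pair.composite)
        return best

    return linker


def index_stage1(schedule: Sequence[str] = ("exact", "fuzzy"), top_n: int = 5) -> Stage1Linker:
    """Stage-1 linker probing a TF-IDF index of the target registry."""

    def linker(
        probes: Sequence[CleanRecord], target: Sequence[CleanRecord], cutoff: float
    ) -> dict[str, tuple[str, float]]:
        index = target if isinstance(target, InvertedIndex) else build_index(target)
        best: dict[str, tuple[str, float]] = {}
        for probe in probes:
            for mode in schedule:
                res = index.query(Query(record=probe, mode=mode, top_n=top_n, cutoff=0.0))
                if res:
                    rid, score = res.hits[0]
                    if score >= cutoff:
                        best[probe.record_id] = (rid, score)
                    break
        return best

    return linker


@dataclass
class TwoStageResult:
    """Child→target links plus the diagnostics of both stages."""

    links: list[tuple[str, str]] = field(default_factory=list)
    mother_links: dict[str, tuple[str, float]] = field(default_factory=dict)
    unlinked_children: list[str] = field(default_factory=list)
    ambiguous_children: list[str] = field(default_factory=list)

    @property
    def linked_pairs(self) -> set[tuple[str, str]]:
        return set(self.links)


def link_births_two_stage(
    births: Sequence[CleanRecord],
    target: Sequence[CleanRecord],
    stage1: Stage1Linker | str = "bloom",
    stage1_cutoff: float = 0.8,
) -> TwoStageResult:
    """Attach birth records to a target registry through their mothers.

    Stage 1 links each birth's mother attributes (name + municipality)
    probabilistically to a target person.  Stage 2 attaches the child
    deterministically via that target identifier plus the child's birth
    date (and sex when present); the child's own name is never used, so
    unnamed newborns are linkable.  Children whose mothers fail stage 1
    stay unlinked; same-mother children indistinguishable on
    (birth date, sex) — twins — are reported ambiguous and not linked.
    """
    if isinstance(stage1, str):
        if stage1 == "bloom":
            stage1 = bloom_stage1()
        elif stage1 == "index":
            stage1 = index_stage1()
        else:
            raise ValueError(f"unknown stage-1 linker {stage1!r}; expected 'bloom' or 'index'")

    probes = [_mother_probe(b) for b in births]
    mother_links = stage1(probes, target, stage1_cutoff)

    result = TwoStageResult(mother_links=mother_links)
    # stage 2: group same-mother births by the deterministic child key
    by_mother_key: dict[tuple, list[CleanRecord]] = defaultdict(list)
    for birth in births:
        hit = mother_links.get(birth.record_id)
        if hit is None:
            result.unlinked_children.append(birth.record_id)
            continue
        by_mother_key[(hit[0], birth.birth_date, birth.sex)].append(birth)
    for (target_id, _date, _sex), group in sorted(by_mother_key.items(), key=lambda kv: str(kv[0])):
        if len(group) > 1:
            result.ambiguous_children.extend(b.record_id for b in group)
            continue
        result.links.append((group[0].record_id, target_id))
    result.links.sort()
    return result
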