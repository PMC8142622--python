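"""Synthetic paired registries with known ground truth.

Real administrative registries (a social-programme population base on
one side, birth/death/notification registries on the other) cannot be
shipped, so every downstream linkage stage is exercised on synthetic
pairs of registries generated here: a base population with
Brazilian-style names, a derived registry containing corrupted copies
of a known subset of the base, and a gold standard listing exactly the
copied pairs.  The gold standard is bookkeeping, never re-matching.

All randomness flows from explicit integer seeds; identical arguments
reproduce byte-identical registries.
"""

from __future__ import annotations

import random
import string
import unicodedata
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

from .pools import DEFAULT_POOLS, NamePools
from .records import PersonRecord, GoldStandard

_EDIT_OPS = ("substitute", "delete", "insert", "transpose")


def strip_accents(text: str) -> str:
    """Fold accented characters to their ASCII base (NFKD strip)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


@dataclass(frozen=True)
class CorruptionConfig:
    """Error model applied when deriving a linked registry.

    ``field_probability`` gives, per attribute, the chance that the
    copied value receives 1..``max_edits_per_field`` single-character
    edits drawn from ``edit_ops``.  ``accent_loss_probability`` strips
    accents from name fields (a no-op after normalization — it exists to
    prove the cleaner neutralizes it).  ``date_digit_swap_probability``
    transposes two adjacent digits of the birth date, and
    ``missingness`` blanks a field outright.  All probabilities are
    per-record, per-field, independent.
    """

    field_probability: dict[str, float] = field(default_factory=dict)
    edit_ops: tuple[str, ...] = _EDIT_OPS
    max_edits_per_field: int = 1
    accent_loss_probability: float = 0.0
    missingness: dict[str, float] = field(default_factory=dict)
    date_digit_swap_probability: float = 0.0
    sex_flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            *self.field_probability.values(),
            *self.missingness.values(),
            self.accent_loss_probability,
            self.date_digit_swap_probability,
            self.sex_flip_probability,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all corruption probabilities must lie in [0, 1]")
        if self.max_edits_per_field < 0:
            raise ValueError("max_edits_per_field must be >= 0")
        unknown = set(self.edit_ops) - set(_EDIT_OPS)
        if unknown:
            raise ValueError(f"unknown edit operations: {sorted(unknown)}")

    @classmethod
    def none(cls, seed: int = 0) -> "CorruptionConfig":
        """Zero corruption: derived copies equal their sources exactly."""
        return cls(seed=seed)

    @classmethod
    def benchmark(cls, seed: int = 0) -> "CorruptionConfig":
        """The declared moderate-corruption benchmark profile.

        Per-field edit probability 0.2 on names and municipality code,
        accent loss 0.2, date digit swap 0.2, 5% missingness on mother's
        name, birth date and municipality code.
        """
        return cls(
            field_probability={
                "full_name": 0.2,
                "mother_name": 0.2,
                "municipality_code": 0.2,
            },
            max_edits_per_field=1,
            accent_loss_probability=0.2,
            missingness={
                "mother_name": 0.05,
                "birth_date": 0.05,
                "municipality_code": 0.05,
            },
            date_digit_swap_probability=0.2,
            seed=seed,
        )


def _compose_name(rng: random.Random, given: str, pools: NamePools) -> str:
    """given name + 0–2 particles + 1–2 surnames, e.g. 'José da Silva Santos'."""
    parts = [given]
    n_surnames = rng.choice((1, 2, 2))
    for _ in range(n_surnames):
        if rng.random() < 0.4:
            parts.append(rng.choice(pools.particles))
        parts.append(rng.choice(pools.surnames))
    return " ".join(parts)


def _random_date(rng: random.Random, year_lo: int, year_hi: int) -> str:
    """Valid calendar date in DD/MM/YYYY text form (28-day months for simplicity)."""
    year = rng.randint(year_lo, year_hi)
    month = rng.randint(1, 12)
    day = rng.randint(1, 28)
    return f"{day:02d}/{month:02d}/{year}"


def _unique_nis(rng: random.Random, taken: set[str]) -> str:
    while True:
        nis = f"{rng.randrange(10**11):011d}"
        if nis not in taken:
            taken.add(nis)
            return nis


def generate_population(
    n: int,
    seed: int,
    pools: NamePools = DEFAULT_POOLS,
    *,
    id_prefix: str = "P",
    mother_name_fraction: float = 0.95,
    birth_year_range: tuple[int, int] = (1945, 2005),
) -> list[PersonRecord]:
    """Generate ``n`` population records with unique record_id and NIS.

    Names carry accents, mixed case and particles so the preprocessing
    normalizer is genuinely exercised downstream.  Mothers share their
    child's final surname three times out of four, which reproduces the
    surname clustering that makes real registries hard to discriminate.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = random.Random(seed)
    taken_nis: set[str] = set()
    registry: list[PersonRecord] = []
    for i in range(n):
        sex = rng.choice(("M", "F"))
        given_pool = pools.given_m if sex == "M" else pools.given_f
        full_name = _compose_name(rng, rng.choice(given_pool), pools)
        if rng.random() < mother_name_fraction:
            mother = _compose_name(rng, rng.choice(pools.given_f), pools)
            if rng.random() < 0.75:
                mother = f"{mother.rsplit(' ', 1)[0]} {full_name.rsplit(' ', 1)[1]}"
        else:
            mother = ""
        registry.append(
            PersonRecord(
                record_id=f"{id_prefix}{i:06d}",
                full_name=full_name,
                sex=sex,
                mother_name=mother,
                birth_date=_random_date(rng, *birth_year_range),
                municipality_code=rng.choice(pools.municipality_codes),
                nis=_unique_nis(rng, taken_nis),
            )
        )
    return registry


# ---------------------------------------------------------------------------
# corruption primitives


def _edit_once(rng: random.Random, text: str, ops: Sequence[str]) -> str:
    """Apply one single-character edit; guaranteed to change the string
    whenever a changing edit exists."""
    if not text:
        return text
    alphabet = string.digits if text.isdigit() else string.ascii_letters
    for _ in range(8):  # retry no-op draws (e.g. transposing equal chars)
        op = rng.choice(tuple(ops))
        i = rng.randrange(len(text))
        if op == "substitute":
            new = rng.choice(alphabet)
            if new == text[i]:
                continue
            out = text[:i] + new + text[i + 1 :]
        elif op == "delete":
            out = text[:i] + text[i + 1 :]
        elif op == "insert":
            out = text[:i] + rng.choice(alphabet) + text[i:]
        else:  # transpose
            if len(text) < 2:
                continue
            i = min(i, len(text) - 2)
            if text[i] == text[i + 1]:
                continue
            out = text[:i] + text[i + 1] + text[i] + text[i + 2 :]
        if out != text:
            return out
    return text


def _swap_date_digits(rng: random.Random, date_text: str) -> str:
    """Transpose two adjacent, differing digits of a date string in place."""
    digit_pos = [i for i, ch in enumerate(date_text) if ch.isdigit()]
    candidates = [
        (a, b)
        for a, b in zip(digit_pos, digit_pos[1:])
        if b == a + 1 and date_text[a] != date_text[b]
    ]
    if not candidates:
        return date_text
    a, b = rng.choice(candidates)
    chars = list(date_text)
    chars[a], chars[b] = chars[b], chars[a]
    return "".join(chars)


def corrupt_record(
    rng: random.Random, source: PersonRecord, config: CorruptionConfig, new_id: str
) -> PersonRecord:
    """Produce a corrupted copy of ``source`` under ``config``."""
    values = {
        "full_name": source.full_name,
        "mother_name": source.mother_name,
        "birth_date": source.birth_date,
        "municipality_code": source.municipality_code,
        "sex": source.sex,
    }
    for fld in ("full_name", "mother_name"):
        if rng.random() < config.accent_loss_probability:
            values[fld] = strip_accents(values[fld])
        if values[fld] and rng.random() < config.field_probability.get(fld, 0.0):
            n_edits = rng.randint(1, config.max_edits_per_field) if config.max_edits_per_field else 0
            for _ in range(n_edits):
                values[fld] = _edit_once(rng, values[fld], config.edit_ops)
    if values["municipality_code"] and rng.random() < config.field_probability.get(
        "municipality_code", 0.0
    ):
        # keying errors in numeric codes: substitutions and transpositions
        code_ops = [op for op in config.edit_ops if op in ("substitute", "transpose")]
        if code_ops:
            values["municipality_code"] = _edit_once(rng, values["municipality_code"], code_ops)
    if values["birth_date"] and rng.random() < config.date_digit_swap_probability:
        values["birth_date"] = _swap_date_digits(rng, values["birth_date"])
    if values["sex"] and rng.random() < config.sex_flip_probability:
        values["sex"] = "F" if values["sex"] == "M" else "M"
    for fld, p_miss in config.missingness.items():
        if fld in values and rng.random() < p_miss:
            values[fld] = ""
    return PersonRecord(record_id=new_id, nis=source.nis, **values)


def derive_linked_registry(
    base: Sequence[PersonRecord],
    overlap_fraction: float,
    config: CorruptionConfig,
    *,
    total_size: int | None = None,
    drop_nis: bool = True,
    id_prefix: str = "R",
    pools: NamePools = DEFAULT_POOLS,
) -> tuple[list[PersonRecord], GoldStandard]:
    """Derive a second registry overlapping ``base`` with known truth.

    ``round(overlap_fraction * len(base))`` base records are copied with
    corruption and new record_ids; the remainder up to ``total_size``
    (default ``len(base)``) are fresh, non-overlapping individuals.  In
    health-registry mode (``drop_nis=True``) copies lose the NIS key so
    only probabilistic attributes remain; with ``drop_nis=False`` copies
    keep the source NIS, emulating a social-programme registry joinable
    by the deterministic key.

    Returns the derived registry (deterministically shuffled) and the
    :class:`GoldStandard` listing exactly the copied (base_id, new_id)
    pairs.
    """
    if not base:
        raise ValueError("base registry must be non-empty")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction must lie in [0, 1], got {overlap_fraction}")
    total = len(base) if total_size is None else total_size
    n_overlap = round(overlap_fraction * len(base))
    if total < n_overlap:
        raise ValueError("total_size smaller than the requested overlap count")

    rng = random.Random(config.seed)
    chosen = rng.sample(list(base), n_overlap)
    gold = GoldStandard()
    derived: list[PersonRecord] = []
    for j, src in enumerate(chosen):
        rec = corrupt_record(rng, src, config, new_id=f"{id_prefix}{j:06d}")
        if drop_nis:
            rec.nis = ""
        derived.append(rec)
        gold.pairs.add((src.record_id, rec.record_id))

    n_fresh = total - n_overlap
    if n_fresh:
        fresh = generate_population(
            n_fresh,
            seed=rng.randrange(2**31),
            pools=pools,
            id_prefix=f"{id_prefix}F",
        )
        if drop_nis:
            for rec in fresh:
                rec.nis = ""
        derived.extend(fresh)
    rng.shuffle(derived)
    return derived, gold


# ---------------------------------------------------------------------------
# birth scenario (mother–child two-stage linkage)

ChildCountSpec = int | Sequence[float] | Callable[[random.Random], int]


def _draw_child_count(rng: random.Random, spec: ChildCountSpec) -> int:
    if callable(spec):
        return int(spec(rng))
    if isinstance(spec, int):
        return spec
    # probability vector over 0, 1, 2, ... children
    u, acc = rng.random(), 0.0
    for k, p in enumerate(spec):
        acc += p
        if u < acc:
            return k
    return len(spec) - 1


def generate_birth_scenario(
    mothers: Sequence[PersonRecord],
    children_per_mother: ChildCountSpec,
    seed: int,
    *,
    unnamed_fraction: float = 0.25,
    birth_year_range: tuple[int, int] = (2010, 2018),
    pools: NamePools = DEFAULT_POOLS,
) -> tuple[list[PersonRecord], GoldStandard]:
    """Emit birth records carrying each mother's attributes.

    Each birth record holds the child's birth date and sex plus the
    mother's name and municipality; a configurable fraction of children
    are unnamed (empty ``full_name``), as newborns may not have received
    a name at registration time.  The gold standard lists every
    (child_id, mother_id) link.
    """
    if not mothers:
        raise ValueError("mothers registry must be non-empty")
    if not 0.0 <= unnamed_fraction <= 1.0:
        raise ValueError("unnamed_fraction must lie in [0, 1]")
    rng = random.Random(seed)
    births: list[PersonRecord] = []
    gold = GoldStandard()
    idx = 0
    for mother in mothers:
        for _ in range(_draw_child_count(rng, children_per_mother)):
            sex = rng.choice(("M", "F"))
            if rng.random() < unnamed_fraction:
                child_name = ""
            else:
                given_pool = pools.given_m if sex == "M" else pools.given_f
                surname = mother.full_name.rsplit(" ", 1)[-1] if mother.full_name else rng.choice(pools.surnames)
                child_name = f"{rng.choice(given_pool)} {surname}"
            child_id = f"B{idx:06d}"
            idx += 1
            births.append(
                PersonRecord(
                    record_id=child_id,
                    full_name=child_name,
                    sex=sex,
                    mother_name=mother.full_name,
                    birth_date=_random_date(rng, *birth_year_range),
                    municipality_code=mother.municipality_code,
                    nis="",
                )
            )
            gold.mother_child.add((child_id, mother.record_id))
    return births, gold
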