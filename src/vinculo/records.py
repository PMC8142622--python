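"""Core record containers shared across the linkage pipeline.

A registry is a plain ``list`` of records.  Raw registries (as generated
or ingested) hold free text in every field; cleaned registries hold the
normalized representation produced by :mod:`vinculo.preprocess`.
Missing values are empty strings on disk and ``None`` (or ``""`` for
text fields) in memory — the two encodings round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Registry CSV column order; empty string encodes a missing value.
REGISTRY_COLUMNS = (
    "record_id",
    "full_name",
    "sex",
    "mother_name",
    "birth_date",
    "municipality_code",
    "nis",
)

#: Attribute tuple used for matching, in scoring order.
LINKAGE_FIELDS = ("full_name", "sex", "mother_name", "birth_date", "municipality_code")


@dataclass(slots=True)
class PersonRecord:
    """One raw registry row: identifying attributes plus optional NIS key.

    ``sex`` is ``"M"``, ``"F"`` or ``""`` (unknown); ``birth_date`` is
    free text in the registry's declared dialect (e.g. DD/MM/YYYY).
    """

    record_id: str
    full_name: str = ""
    sex: str = ""
    mother_name: str = ""
    birth_date: str = ""
    municipality_code: str = ""
    nis: str = ""


@dataclass(slots=True)
class CleanRecord:
    """A preprocessed row: normalized names, ISO date, validated codes.

    ``quality_flags`` records every repair made (``invalid_date``,
    ``empty_name``, ``invalid_municipality_code``, ``invalid_nis``, ...).
    Invariants: normalized names contain only A–Z and single spaces; a
    record flagged ``invalid_date`` has ``birth_date is None``.
    """

    record_id: str
    full_name: str = ""
    sex: str = ""
    mother_name: str = ""
    birth_date: str | None = None
    municipality_code: str | None = None
    nis: str | None = None
    quality_flags: frozenset[str] = field(default_factory=frozenset)

    def linkage_key(self) -> tuple:
        """Ordered attribute tuple used for exact matching and dedup."""
        return (
            self.full_name,
            self.sex,
            self.mother_name,
            self.birth_date,
            self.municipality_code,
        )


@dataclass(slots=True)
class GoldStandard:
    """True links emitted by the synthetic generator, by construction.

    ``pairs`` holds (left record_id, right record_id) person links;
    ``mother_child`` holds (child record_id, mother record_id) links for
    the two-stage birth scenario.  Each record_id appears in at most one
    pair per side.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    mother_child: set[tuple[str, str]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.pairs)


__all__ = [
    "REGISTRY_COLUMNS",
    "LINKAGE_FIELDS",
    "PersonRecord",
    "CleanRecord",
    "GoldStandard",
    "replace",
]
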