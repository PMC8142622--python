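"""Cleaning, standardization, validation and deduplication of registries.

This is the first pipeline stage: raw registry rows become
:class:`~vinculo.records.CleanRecord` instances with normalized names
(uppercase ASCII, single spaces, particles retained), ISO-8601 dates,
validated 7-digit municipality codes and 11-digit NIS keys, and a set of
quality flags documenting every repair.  Invalidity is data, not
failure: a bad date becomes a missing date plus an ``invalid_date``
flag, never an exception.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from collections.abc import Iterable, Sequence
from datetime import datetime
from pathlib import Path

from .records import CleanRecord, PersonRecord
from .synthetic import strip_accents

_WS_RE = re.compile(r"\s+")
_NON_ALPHA_RE = re.compile(r"[^A-Z ]+")

#: Input date dialects; declared per file, never sniffed.
DATE_DIALECTS = {"DMY": "%d/%m/%Y", "ISO": "%Y-%m-%d"}


def normalize_name(raw: str, *, strip_particles: bool = False) -> str:
    """Normalize a personal name for matching.

    Uppercases, folds accents to ASCII, strips punctuation and digits,
    and collapses whitespace.  Linking particles (DA, DE, DO, DAS, DOS,
    E) are retained by default because they carry signal for bigram
    encodings; pass ``strip_particles=True`` to drop them.

    >>> normalize_name("José da Silva")
    'JOSE DA SILVA'
    """
    text = strip_accents(raw).upper()
    text = _NON_ALPHA_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    if strip_particles:
        kept = [w for w in text.split(" ") if w not in ("DA", "DE", "DO", "DAS", "DOS", "E")]
        text = " ".join(kept)
    return text


def standardize_date(raw: str, dialect: str = "DMY") -> str | None:
    """Parse ``raw`` under the declared dialect; return ISO date or None.

    Unparseable or impossible dates (e.g. 32/13/2003) yield ``None`` —
    the caller records an ``invalid_date`` quality flag.
    """
    if dialect not in DATE_DIALECTS:
        raise ValueError(f"unknown date dialect {dialect!r}; expected one of {sorted(DATE_DIALECTS)}")
    text = raw.strip()
    if not text:
        return None
    try:
        return datetime.strptime(text, DATE_DIALECTS[dialect]).strftime("%Y-%m-%d")
    except ValueError:
        return None


def clean_record(
    record: PersonRecord, *, date_dialect: str = "DMY", strip_particles: bool = False
) -> CleanRecord:
    """Clean one raw row into a :class:`CleanRecord` with quality flags."""
    flags: set[str] = set()

    full_name = normalize_name(record.full_name, strip_particles=strip_particles)
    mother_name = normalize_name(record.mother_name, strip_particles=strip_particles)
    if not full_name:
        flags.add("empty_name")

    sex = record.sex.strip().upper()
    if sex not in ("M", "F"):
        if sex:
            flags.add("invalid_sex")
        sex = ""

    birth_date = standardize_date(record.birth_date, date_dialect)
    if birth_date is None and record.birth_date.strip():
        flags.add("invalid_date")

    cleaned = CleanRecord(
        record_id=record.record_id,
        full_name=full_name,
        sex=sex,
        mother_name=mother_name,
        birth_date=birth_date,
        municipality_code=record.municipality_code.strip() or None,
        nis=record.nis.strip() or None,
        quality_flags=frozenset(flags),
    )
    return validate_codes(cleaned)


def validate_codes(record: CleanRecord) -> CleanRecord:
    """Enforce code shapes: municipality exactly 7 digits, NIS exactly 11.

    Violations set the field missing and add a quality flag; valid
    records pass through unchanged.
    """
    flags = set(record.quality_flags)
    muni = record.municipality_code
    if muni is not None and not (len(muni) == 7 and muni.isdigit()):
        muni = None
        flags.add("invalid_municipality_code")
    nis = record.nis
    if nis is not None and not (len(nis) == 11 and nis.isdigit()):
        nis = None
        flags.add("invalid_nis")
    return CleanRecord(
        record_id=record.record_id,
        full_name=record.full_name,
        sex=record.sex,
        mother_name=record.mother_name,
        birth_date=record.birth_date,
        municipality_code=muni,
        nis=nis,
        quality_flags=frozenset(flags),
    )


def clean_registry(
    registry: Iterable[PersonRecord], *, date_dialect: str = "DMY", strip_particles: bool = False
) -> list[CleanRecord]:
    """Clean every record, preserving input order and record_ids."""
    return [
        clean_record(r, date_dialect=date_dialect, strip_particles=strip_particles)
        for r in registry
    ]


def deduplicate(registry: Sequence[CleanRecord]) -> tuple[list[CleanRecord], int]:
    """Collapse records with identical full linkage keys.

    The first record of each key (by stable input order) is kept.
    Returns the deduplicated registry and the number of rows removed.
    """
    seen: set[tuple] = set()
    kept: list[CleanRecord] = []
    for rec in registry:
        key = rec.linkage_key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept, len(registry) - len(kept)


def preprocessing_report(
    cleaned: Sequence[CleanRecord], duplicates_removed: int = 0
) -> dict:
    """Counts of quality flags and duplicates, for the run's JSON report."""
    flag_counts: Counter[str] = Counter()
    for rec in cleaned:
        flag_counts.update(rec.quality_flags)
    return {
        "n_records": len(cleaned),
        "duplicates_removed": duplicates_removed,
        "flag_counts": dict(sorted(flag_counts.items())),
        "missing_birth_date": sum(r.birth_date is None for r in cleaned),
        "missing_municipality_code": sum(r.municipality_code is None for r in cleaned),
        "missing_nis": sum(r.nis is None for r in cleaned),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
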