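"""Registry CSV I/O, linked-pair output, pseudonymized extraction.

All on-disk formats are plain text: registries and gold standards are
CSV (empty string = missing), run parameters echo into JSON sidecars.
Extraction replaces record identifiers with keyed (salted) hashes so
tables remain joinable without exposing the original ids, and drops
identifying fields outright.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bloom import SCORED_FIELDS, ScoredPair
from .records import REGISTRY_COLUMNS, CleanRecord, GoldStandard, PersonRecord

#: Fields that identify a person; they never pass through extraction.
IDENTIFYING_FIELDS = frozenset({"full_name", "mother_name", "nis"})


# ---------------------------------------------------------------------------
# registries


def write_registry(registry: Iterable[PersonRecord | CleanRecord], path: str | Path) -> None:
    """Write a registry CSV in the canonical column order."""
    rows = []
    for rec in registry:
        rows.append({c: ("" if (v := getattr(rec, c)) is None else v) for c in REGISTRY_COLUMNS})
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(path, index=False)


def read_registry(path: str | Path) -> list[PersonRecord]:
    """Read a raw registry CSV; empty cells become empty strings."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry {path} lacks columns: {sorted(missing)}")
    return [PersonRecord(**{c: row[c] for c in REGISTRY_COLUMNS}) for row in df.to_dict("records")]


def write_clean_registry(registry: Iterable[CleanRecord], path: str | Path) -> None:
    write_registry(registry, path)


def read_clean_registry(path: str | Path) -> list[CleanRecord]:
    """Read a cleaned registry CSV back into CleanRecords.

    Quality flags are not persisted in the registry CSV (they live in
    the preprocessing report), so re-read records carry empty flags.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: list[CleanRecord] = []
    for row in df.to_dict("records"):
        out.append(
            CleanRecord(
                record_id=row["record_id"],
                full_name=row["full_name"],
                sex=row["sex"],
                mother_name=row["mother_name"],
                birth_date=row["birth_date"] or None,
                municipality_code=row["municipality_code"] or None,
                nis=row["nis"] or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# gold standard and linked pairs


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    pairs = sorted(gold.pairs) if gold.pairs else sorted(gold.mother_child)
    pd.DataFrame(pairs, columns=["left_id", "right_id"]).to_csv(path, index=False)


def read_gold_standard(path: str | Path) -> GoldStandard:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return GoldStandard(pairs={(r["left_id"], r["right_id"]) for _, r in df.iterrows()})


def write_linked_pairs(
    pairs: Sequence[ScoredPair], path: str | Path, params: dict | None = None
) -> None:
    """Linked-pair CSV plus a JSON parameter sidecar for provenance."""
    rows = []
    for p in pairs:
        row = {
            "left_id": p.left_id,
            "right_id": p.right_id,
            "score": f"{p.composite:.6f}",
            "classification": p.classification,
        }
        for fname, s in zip(SCORED_FIELDS, p.field_scores):
            row[f"score_{fname}"] = "" if s is None else f"{s:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if params is not None:
        Path(str(path) + ".params.json").write_text(json.dumps(params, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# pseudonymized extraction


def pseudonymize(record_id: str, salt: str) -> str:
    """Keyed hash of a record id: deterministic per salt, irreversible."""
    return hashlib.blake2b(
        record_id.encode("utf-8"), key=salt.encode("utf-8"), digest_size=16
    ).hexdigest()


@dataclass(frozen=True)
class ExtractionSpec:
    """What a research-ready extract may contain.

    ``variables`` name CleanRecord attributes to carry through (never
    identifying ones); ``aggregations`` coarsens sensitive fields, e.g.
    ``{"birth_date": "year"}``.
    """

    variables: tuple[str, ...] = ("sex", "birth_date", "municipality_code")
    salt: str = "vinculo"
    aggregations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        banned = IDENTIFYING_FIELDS & set(self.variables)
        if banned:
            raise ValueError(f"identifying fields may not be extracted: {sorted(banned)}")
        for fld, rule in self.aggregations.items():
            if rule != "year":
                raise ValueError(f"unknown aggregation rule {rule!r} for {fld!r}")


def _aggregate(value, rule: str):
    if value is None or value == "":
        return ""
    if rule == "year":
        return str(value)[:4]
    return value


def extract_dataset(
    links: Sequence[tuple[str, str]],
    left: Sequence[CleanRecord],
    right: Sequence[CleanRecord],
    spec: ExtractionSpec,
) -> pd.DataFrame:
    """Build a de-identified research table from a linked pair set.

    Record ids are replaced by keyed pseudonyms (same salt + id gives
    the same pseudonym in any table, preserving joinability);
    identifying fields are dropped and aggregation rules applied.
    """
    left_map = {r.record_id: r for r in left}
    right_map = {r.record_id: r for r in right}
    rows = []
    for lid, rid in links:
        row: dict = {
            "pid_left": pseudonymize(lid, spec.salt),
            "pid_right": pseudonymize(rid, spec.salt),
        }
        for side, rec in (("left", left_map.get(lid)), ("right", right_map.get(rid))):
            for var in spec.variables:
                value = getattr(rec, var) if rec is not None else ""
                if var in spec.aggregations:
                    value = _aggregate(value, spec.aggregations[var])
                row[f"{var}_{side}"] = "" if value is None else value
        rows.append(row)
    return pd.DataFrame(rows)
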