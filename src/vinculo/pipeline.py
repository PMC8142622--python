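"""End-to-end pipeline: preprocess → link → calibrate → classify.

A :class:`PipelineConfig` (from YAML or a dict; unknown keys are
rejected before any computation) drives one run and every parameter is
echoed verbatim into a provenance sidecar, so a run directory is
self-describing and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .bloom import BloomParams, classify, default_predicates, build_blocks, score_candidates
from .calibrate import cutoff_report, make_review_sample
from .deterministic import link_by_key, link_births_two_stage
from .io import read_gold_standard, read_registry, write_linked_pairs
from .preprocess import clean_registry, deduplicate, preprocessing_report, write_report
from .records import GoldStandard
from .tfidf import build_index, candidates_by_index

LINKERS = ("bloom", "index", "deterministic", "two_stage")


@dataclass
class PipelineConfig:
    """Everything one linkage run needs; unknown keys are rejected."""

    left_path: str
    right_path: str
    output_dir: str
    linker: str = "bloom"
    left_dialect: str = "DMY"
    right_dialect: str = "DMY"
    gold_path: str | None = None
    seed: int = 0
    cutoff: float | None = None  # None -> calibrate (requires gold labels)
    review_n: int = 2000
    review_strategy: str = "score_stratified"
    strip_particles: bool = False
    key_field: str = "nis"
    stage1_cutoff: float = 0.8
    bloom: dict[str, Any] = field(default_factory=dict)
    index: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.linker not in LINKERS:
            raise ValueError(f"unknown linker {self.linker!r}; expected one of {LINKERS}")
        if self.cutoff is None and self.gold_path is None and self.linker in ("bloom", "index"):
            raise ValueError("probabilistic linkage needs either a fixed cutoff or gold labels to calibrate one")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _evaluate(links: set[tuple[str, str]], gold: GoldStandard) -> dict:
    tp = len(links & gold.pairs)
    precision = tp / len(links) if links else None
    recall = tp / len(gold.pairs) if gold.pairs else None
    f1 = None
    if precision and recall:
        f1 = 2 * precision * recall / (precision + recall)
    return {"true_positives": tp, "precision": precision, "recall": recall, "f1": f1}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute one configured run; returns the summary written to disk."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **counts) -> None:
        log_fh.write(json.dumps({"stage": stage, **counts}) + "\n")

    left_raw = read_registry(config.left_path)
    right_raw = read_registry(config.right_path)
    log("ingest", left=len(left_raw), right=len(right_raw))

    left_clean = clean_registry(left_raw, date_dialect=config.left_dialect, strip_particles=config.strip_particles)
    right_clean = clean_registry(right_raw, date_dialect=config.right_dialect, strip_particles=config.strip_particles)
    left_clean, left_dupes = deduplicate(left_clean)
    right_clean, right_dupes = deduplicate(right_clean)
    write_report(preprocessing_report(left_clean, left_dupes), outdir / "preprocess_left.json")
    write_report(preprocessing_report(right_clean, right_dupes), outdir / "preprocess_right.json")
    log("preprocess", left=len(left_clean), right=len(right_clean),
        left_duplicates=left_dupes, right_duplicates=right_dupes)

    gold = read_gold_standard(config.gold_path) if config.gold_path else None
    summary: dict = {"linker": config.linker, "seed": config.seed}

    if config.linker in ("bloom", "index"):
        if config.linker == "bloom":
            params = BloomParams(**config.bloom)
            candidates = build_blocks(left_clean, right_clean, default_predicates())
            scored = score_candidates(left_clean, right_clean, candidates, params)
        else:
            index = build_index(right_clean)
            scored = candidates_by_index(
                left_clean,
                index,
                schedule=config.index.get("schedule", ("exact", "semi_exact", "fuzzy")),
                top_n=config.index.get("top_n", 10),
            )
        log("score", candidates=len(scored))

        cutoff = config.cutoff
        if cutoff is None:
            sample = make_review_sample(
                scored, gold, n=config.review_n, seed=config.seed, strategy=config.review_strategy
            )
            report = cutoff_report(sample)
            report.write_json(outdir / "cutoff_report.json")
            report.write_csv(outdir / "cutoff_report.csv")
            cutoff = report.selected_cutoff
            summary["auc"] = report.auc
            log("calibrate", sample=len(sample), selected_cutoff=cutoff)
        result = classify(scored, cutoff)
        write_linked_pairs(result.pairs, outdir / "linked_pairs.csv", params={"cutoff": cutoff, **asdict(config)})
        summary.update({"cutoff": cutoff, "links": len(result.links)})
        links = result.linked_pairs
        log("classify", links=len(result.links), above_cutoff=result.n_above_cutoff)
    elif config.linker == "deterministic":
        result = link_by_key(left_clean, right_clean, key_field=config.key_field)
        links = set(result.pairs)
        (outdir / "ambiguous_keys.json").write_text(json.dumps(result.ambiguous, indent=2) + "\n")
        pd_rows = [{"left_id": l, "right_id": r} for l, r in result.pairs]
        (outdir / "linked_pairs.csv").write_text(
            "left_id,right_id\n" + "".join(f"{r['left_id']},{r['right_id']}\n" for r in pd_rows)
        )
        summary.update({"links": len(result.pairs), "ambiguous_keys": len(result.ambiguous),
                        "unmatched_left": len(result.unmatched_left)})
        log("link_by_key", **{k: summary[k] for k in ("links", "ambiguous_keys")})
    else:  # two_stage
        result = link_births_two_stage(left_clean, right_clean, stage1="bloom", stage1_cutoff=config.stage1_cutoff)
        links = result.linked_pairs
        (outdir / "linked_pairs.csv").write_text(
            "left_id,right_id\n" + "".join(f"{l},{r}\n" for l, r in result.links)
        )
        summary.update({"links": len(result.links), "unlinked_children": len(result.unlinked_children),
                        "ambiguous_children": len(result.ambiguous_children)})
        log("two_stage", links=len(result.links))

    if gold is not None:
        reference = gold.pairs or gold.mother_child
        summary["evaluation"] = _evaluate(links, GoldStandard(pairs=reference))
        log("evaluate", **{k: v for k, v in summary["evaluation"].items() if v is not None})

    provenance = {"software": f"vinculo {__version__}", "config": asdict(config)}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log_fh.close()
    return summary
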