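"""Linkage accuracy assessment and cut-off calibration.

A review sample of scored candidate pairs (default n = 2000, mirroring
manual-review practice) is labeled — here by the synthetic gold
standard, in real use by human reviewers via a CSV round-trip — and
sensitivity, specificity and Youden J are evaluated on a grid of
candidate cut-offs.  The ROC curve over the grid gives the AUC
(trapezoidal rule), and the final cut-off is the grid point maximizing
Youden J = sensitivity + specificity − 1 (smallest such point on ties);
the distance-to-(0,1) criterion is available as an alternative.
"""

from __future__ import annotations

import csv
import json
import random
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bloom import ScoredPair
from .records import GoldStandard

DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 101), 10))
SELECTION_CRITERIA = ("youden", "closest_topleft")


@dataclass
class ReviewSample:
    """Sampled pairs with review labels (1 = match, 0 = non-match)."""

    pairs: list[ScoredPair]
    labels: list[int]
    seed: int
    strategy: str
    truncated: bool = False  # fewer pairs available than requested

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([p.composite for p in self.pairs], dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


def sample_pairs(
    scored: Sequence[ScoredPair],
    n: int = 2000,
    seed: int = 0,
    strategy: str = "uniform",
) -> tuple[list[ScoredPair], bool]:
    """Draw a without-replacement review sample of scored pairs.

    ``uniform`` samples all pairs equally; ``score_stratified`` draws
    equally from the deciles of the score distribution (spare capacity
    in thin deciles is redistributed).  Returns the sample and a flag
    set when the population was smaller than ``n`` (everything is then
    returned).  Deterministic per seed.
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    if strategy not in ("uniform", "score_stratified"):
        raise ValueError(f"unknown sampling strategy {strategy!r}")
    if not scored:
        raise ValueError("cannot sample from an empty pair list")
    ordered = sorted(scored, key=lambda p: (p.composite, p.left_id, p.right_id))
    if n >= len(ordered):
        return list(ordered), True
    rng = random.Random(seed)
    if strategy == "uniform":
        return rng.sample(ordered, n), False

    edges = np.quantile([p.composite for p in ordered], np.linspace(0, 1, 11))
    deciles: list[list[ScoredPair]] = [[] for _ in range(10)]
    for p in ordered:
        d = int(np.searchsorted(edges[1:-1], p.composite, side="right"))
        deciles[d].append(p)
    base, extra = divmod(n, 10)
    want = [base + (1 if i < extra else 0) for i in range(10)]
    sample: list[ScoredPair] = []
    shortfall = 0
    for d, bucket in enumerate(deciles):
        take = min(want[d], len(bucket))
        shortfall += want[d] - take
        sample.extend(rng.sample(bucket, take))
    if shortfall > 0:
        # thin deciles could not fill their quota: draw the remainder
        # uniformly from the not-yet-sampled pairs
        chosen = {id(p) for p in sample}
        pool = [p for p in ordered if id(p) not in chosen]
        sample.extend(rng.sample(pool, min(shortfall, len(pool))))
    return sample, False


def make_review_sample(
    scored: Sequence[ScoredPair],
    gold: GoldStandard,
    n: int = 2000,
    seed: int = 0,
    strategy: str = "score_stratified",
) -> ReviewSample:
    """Sample pairs and label them against the gold standard."""
    sample, truncated = sample_pairs(scored, n=n, seed=seed, strategy=strategy)
    labels = [1 if (p.left_id, p.right_id) in gold.pairs else 0 for p in sample]
    return ReviewSample(pairs=sample, labels=labels, seed=seed, strategy=strategy, truncated=truncated)


# ---------------------------------------------------------------------------
# confusion counts and ROC


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts at one cut-off; undefined ratios are None, never 0."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None

    @property
    def youden_j(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1.0


def confusion_at(sample: ReviewSample, cutoff: float) -> ConfusionCounts:
    """TP/FP/TN/FN of ``sample`` when linking at ``score >= cutoff``."""
    scores, labels = sample.scores, sample.labels
    pred = scores >= cutoff
    labels_arr = np.asarray(labels, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & labels_arr)),
        fp=int(np.sum(pred & ~labels_arr)),
        tn=int(np.sum(~pred & ~labels_arr)),
        fn=int(np.sum(~pred & labels_arr)),
    )


@dataclass
class CutoffReport:
    """Per-cutoff operating characteristics, AUC and the selected cut-off."""

    cutoffs: list[float]
    sensitivity: list[float | None]
    specificity: list[float | None]
    youden: list[float | None]
    auc: float
    selected_cutoff: float
    criterion: str = "youden"

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "auc": self.auc,
            "selected_cutoff": self.selected_cutoff,
            "grid": [
                {"cutoff": c, "sensitivity": se, "specificity": sp, "youden_j": j}
                for c, se, sp, j in zip(self.cutoffs, self.sensitivity, self.specificity, self.youden)
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cutoff", "sensitivity", "specificity", "youden_j"])
            for row in zip(self.cutoffs, self.sensitivity, self.specificity, self.youden):
                writer.writerow(["" if v is None else v for v in row])


def roc_auc(sample: ReviewSample, grid: Sequence[float] = DEFAULT_GRID) -> float:
    """Trapezoidal AUC over ROC points evaluated at the grid cut-offs.

    ROC points (1−specificity, sensitivity) are augmented with (0,0)
    and (1,1) and sorted by false-positive rate.  Rejects single-class
    samples, for which the ROC is undefined.
    """
    if len(grid) < 2:
        raise ValueError("cut-off grid needs at least 2 points")
    if len(set(sample.labels)) < 2:
        raise ValueError("ROC requires both match and non-match labels in the sample")
    points = [(0.0, 0.0), (1.0, 1.0)]
    for c in grid:
        cc = confusion_at(sample, c)
        points.append((1.0 - cc.specificity, cc.sensitivity))
    points.sort()
    xs, ys = zip(*points)
    return float(np.trapezoid(ys, xs))


def select_cutoff(
    cutoffs: Sequence[float],
    sensitivity: Sequence[float | None],
    specificity: Sequence[float | None],
    criterion: str = "youden",
) -> float:
    """Pick the grid cut-off optimizing the selection criterion.

    ``youden`` maximizes J = sensitivity + specificity − 1;
    ``closest_topleft`` minimizes the Euclidean distance to the ideal
    ROC corner (0, 1).  Cut-offs with an undefined ratio are excluded;
    ties resolve to the smallest cut-off.  Invariant to grid ordering
    and duplicated grid points.
    """
    if criterion not in SELECTION_CRITERIA:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    usable: dict[float, tuple[float, float]] = {}
    for c, se, sp in zip(cutoffs, sensitivity, specificity):
        if se is not None and sp is not None:
            usable.setdefault(c, (se, sp))
    if not usable:
        raise ValueError("no cut-off has both sensitivity and specificity defined")
    if criterion == "youden":
        objective = lambda se, sp: se + sp - 1.0
    else:
        objective = lambda se, sp: -((1.0 - sp) ** 2 + (1.0 - se) ** 2)
    best_val, best_cut = None, None
    for c in sorted(usable):
        val = objective(*usable[c])
        if best_val is None or val > best_val + 1e-12:
            best_val, best_cut = val, c
    return best_cut


def cutoff_report(
    sample: ReviewSample,
    grid: Sequence[float] = DEFAULT_GRID,
    criterion: str = "youden",
) -> CutoffReport:
    """Full calibration: grid metrics, AUC, and the selected cut-off."""
    grid_sorted = sorted(set(float(c) for c in grid))
    sens: list[float | None] = []
    spec: list[float | None] = []
    youden: list[float | None] = []
    for c in grid_sorted:
        cc = confusion_at(sample, c)
        sens.append(cc.sensitivity)
        spec.append(cc.specificity)
        youden.append(cc.youden_j)
    auc = roc_auc(sample, grid_sorted)
    selected = select_cutoff(grid_sorted, sens, spec, criterion=criterion)
    return CutoffReport(
        cutoffs=grid_sorted,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        auc=auc,
        selected_cutoff=selected,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# review CSV round-trip (for real, non-simulated review)


def export_review_csv(sample: ReviewSample, path: str | Path) -> None:
    """Write the sample for manual labeling (label column pre-filled
    when gold labels exist, blank otherwise is fine to edit)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["left_id", "right_id", "score", "label"])
        for p, lab in zip(sample.pairs, sample.labels):
            writer.writerow([p.left_id, p.right_id, f"{p.composite:.6f}", lab])


def import_review_csv(path: str | Path, seed: int = 0) -> ReviewSample:
    """Read back a labeled review CSV (label: 1 = match, 0 = non-match)."""
    pairs: list[ScoredPair] = []
    labels: list[int] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pairs.append(
                ScoredPair(row["left_id"], row["right_id"], (None,) * 5, float(row["score"]))
            )
            labels.append(int(row["label"]))
    return ReviewSample(pairs=pairs, labels=labels, seed=seed, strategy="imported")
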