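"""Assessment metrics for binding-residue prediction.

Residue-level metrics are the Matthews correlation coefficient (MCC, the
Pearson correlation between the observed and predicted binary label
vectors), precision and recall.  Pocket localisation is measured by DCA,
the distance from a pocket's center to the nearest ligand atom; a pocket
"hits" when DCA falls below a threshold (4.0 Å by default).

Dataset aggregation is the unweighted per-structure mean (macro); a pooled
residue-level mode is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import LigandGroup, ResidueKey

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "confusion",
    "mcc",
    "precision",
    "recall",
    "dca",
    "evaluate_structure",
    "aggregate",
]

DCA_HIT_THRESHOLD = 4.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    mcc: float
    precision: float
    recall: float
    counts: ConfusionCounts
    dca: float | None = None


def confusion(
    predictions: dict[ResidueKey, int], labels: dict[ResidueKey, int]
) -> ConfusionCounts:
    """2×2 tally over a shared residue-key set."""
    if set(predictions) != set(labels):
        raise ValueError("prediction and label residue keys differ")
    tp = tn = fp = fn = 0
    for key, pred in predictions.items():
        truth = labels[key]
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision(counts: ConfusionCounts) -> float:
    return counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0


def recall(counts: ConfusionCounts) -> float:
    return counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0


def dca(pocket_center: np.ndarray, ligand: LigandGroup) -> float:
    """Distance from a pocket center to the nearest ligand atom (Å)."""
    if not ligand.atoms:
        raise ValueError(f"ligand {ligand.het_code} has no atoms")
    coords = np.array([a.coords for a in ligand.atoms])
    return float(np.min(np.linalg.norm(coords - np.asarray(pocket_center), axis=1)))


def evaluate_structure(
    predictions: dict[ResidueKey, int],
    labels: dict[ResidueKey, int],
    pocket_centers: list[np.ndarray] | None = None,
    ligands: list[LigandGroup] | None = None,
) -> EvaluationResult:
    """Residue-level metrics for one structure, plus the best (smallest) DCA
    over all (pocket, ligand) pairs when both are given."""
    if not labels:
        raise ValueError("empty label set")
    counts = confusion(predictions, labels)
    best_dca = None
    if pocket_centers and ligands:
        best_dca = min(
            dca(center, lig) for center in pocket_centers for lig in ligands
        )
    return EvaluationResult(
        mcc=mcc(counts),
        precision=precision(counts),
        recall=recall(counts),
        counts=counts,
        dca=best_dca,
    )


def aggregate(results: list[EvaluationResult], pooled: bool = False) -> EvaluationResult:
    """Dataset-level metrics: unweighted per-structure mean by default, or
    pooled residue counts with ``pooled=True``."""
    if not results:
        raise ValueError("nothing to aggregate")
    total = ConfusionCounts(
        tp=sum(r.counts.tp for r in results),
        tn=sum(r.counts.tn for r in results),
        fp=sum(r.counts.fp for r in results),
        fn=sum(r.counts.fn for r in results),
    )
    dcas = [r.dca for r in results if r.dca is not None]
    mean_dca = float(np.mean(dcas)) if dcas else None
    if pooled:
        return EvaluationResult(
            mcc=mcc(total), precision=precision(total), recall=recall(total),
            counts=total, dca=mean_dca,
        )
    return EvaluationResult(
        mcc=float(np.mean([r.mcc for r in results])),
        precision=float(np.mean([r.precision for r in results])),
        recall=float(np.mean([r.recall for r in results])),
        counts=total,
        dca=mean_dca,
    )
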