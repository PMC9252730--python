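"""Binding-residue labelling, template selection and the balanced tree ensemble.

The predictor is trained per query: the query sequence is matched against a
local store of annotated templates (ligand-bound structures with known
binding residues, standing in for a BioLip-style database); the matched
templates' feature matrices form the training set.  Because binding residues
are a small minority of any structure, training uses *balanced bagging*:
each of ``n_bags`` bags keeps every minority-class row and an equal-size
random undersample of the majority class (without replacement), and fits one
Extremely Randomized Trees ensemble.  The reported confidence of a residue
is the mean positive-class probability over all trees in all bags; the
binary label applies a 0.5 threshold by default.

Ground-truth binding labels follow the van-der-Waals contact convention:
a residue binds a ligand when some heavy-atom pair (residue atom, ligand
atom) is closer than the sum of their vdW radii plus a 0.5 Å margin.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree
from sklearn.ensemble import ExtraTreesClassifier

from . import features as feat
from . import pockets as pk
from .structure import (
    LigandGroup,
    ResidueKey,
    Structure,
    parse_pdb,
    extract_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VDW_RADII",
    "Prediction",
    "TemplateRecord",
    "TrainedModel",
    "NoTemplatesError",
    "TrainingError",
    "label_binding_residues",
    "label_all_ligands",
    "build_template_record",
    "load_template_store",
    "sequence_identity",
    "select_templates",
    "train",
    "predict",
    "feature_importance",
    "predict_structure",
    "save_model",
    "load_model",
]

#: heavy-atom van der Waals radii (Å), by element; 1.7 for anything else
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70


class NoTemplatesError(RuntimeError):
    """No template passed the identity filter; prediction is impossible."""


class TrainingError(ValueError):
    """Training set is unusable (single class, misaligned labels...)."""


@dataclass(frozen=True)
class Prediction:
    residue_key: ResidueKey
    confidence: float
    label: bool


# ---------------------------------------------------------------------------
# ground-truth labels from ligand proximity


def _vdw(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def label_binding_residues(
    structure: Structure, ligand: LigandGroup, margin: float = 0.5
) -> dict[ResidueKey, int]:
    """Binary labels: 1 when some residue/ligand heavy-atom pair lies within
    the sum of vdW radii plus ``margin`` Å."""
    if not ligand.atoms:
        raise ValueError(f"ligand {ligand.het_code} has no atoms")
    lig_atoms = [a for a in ligand.atoms if not a.is_hydrogen]
    lig_coords = np.array([a.coords for a in lig_atoms])
    lig_radii = np.array([_vdw(a.element) for a in lig_atoms])
    max_cut = lig_radii.max() + max(VDW_RADII.values()) + margin
    tree = cKDTree(lig_coords)
    labels: dict[ResidueKey, int] = {}
    for res in structure.residues:
        hit = 0
        for atom in res.heavy_atoms():
            cutoffs = _vdw(atom.element) + lig_radii + margin
            idx = tree.query_ball_point(atom.coords, max_cut)
            if idx:
                dists = np.linalg.norm(lig_coords[idx] - np.asarray(atom.coords), axis=1)
                if np.any(dists <= cutoffs[idx]):
                    hit = 1
                    break
        labels[res.key] = hit
    return labels


def label_all_ligands(
    structure: Structure, margin: float = 0.5
) -> dict[ResidueKey, int]:
    """Union of :func:`label_binding_residues` over every ligand."""
    labels = {res.key: 0 for res in structure.residues}
    for lig in structure.ligands:
        for key, val in label_binding_residues(structure, lig, margin).items():
            labels[key] |= val
    return labels


# ---------------------------------------------------------------------------
# template store


@dataclass
class TemplateRecord:
    structure_id: str
    features: pd.DataFrame           # META_COLUMNS + 42 feature columns
    labels: np.ndarray               # aligned with feature rows
    het_codes: list[str]
    sequence: str
    sites: list[pk.SiteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.features):
            raise TrainingError(
                f"template {self.structure_id}: {len(self.labels)} labels for "
                f"{len(self.features)} feature rows"
            )
        if int(np.sum(self.labels)) == 0:
            raise TrainingError(
                f"template {self.structure_id} has no positive residue"
            )


def build_template_record(
    structure: Structure, margin: float = 0.5, **featurize_kwargs
) -> TemplateRecord:
    """Featurize a ligand-bound structure and derive its labels and sites."""
    frame = feat.featurize(structure, **featurize_kwargs)
    keys = feat.residue_keys_from_frame(frame)
    labels_map = label_all_ligands(structure, margin)
    labels = np.array([labels_map[k] for k in keys], dtype=int)
    sites = []
    for lig in structure.ligands:
        per_lig = label_binding_residues(structure, lig, margin)
        members = [k for k in keys if per_lig[k]]
        if len(members) >= 2:
            sites.append(pk.make_site_record(structure, members, lig.het_code))
    return TemplateRecord(
        structure_id=structure.structure_id,
        features=frame,
        labels=labels,
        het_codes=sorted({lig.het_code for lig in structure.ligands}),
        sequence=extract_sequence(structure),
        sites=sites,
    )


def load_template_store(
    store_dir: str | Path, margin: float = 0.5, **featurize_kwargs
) -> list[TemplateRecord]:
    """Load an on-disk template store (one directory per template, with
    ``structure.pdb``, ``labels.csv``, ``ligands.tsv``, ``sequence.fasta``,
    indexed by a root ``manifest.json``)."""
    store_dir = Path(store_dir)
    manifest = json.loads((store_dir / "manifest.json").read_text())
    records = []
    for tid in manifest["templates"]:
        tdir = store_dir / tid
        structure = parse_pdb(tdir / "structure.pdb", structure_id=tid)
        record = build_template_record(structure, margin=margin, **featurize_kwargs)
        # stored labels are authoritative when present (they were written by
        # whoever curated the store); fall back to recomputed vdW labels
        labels_path = tdir / "labels.csv"
        if labels_path.exists():
            lab = pd.read_csv(labels_path, keep_default_na=False, na_values=[],
                              dtype={"chain": str, "icode": str})
            by_key = {
                (str(c), int(n), str(i)): int(v)
                for c, n, i, v in zip(lab["chain"], lab["resnum"],
                                      lab["icode"], lab["label"])
            }
            keys = feat.residue_keys_from_frame(record.features)
            record.labels = np.array([by_key[k] for k in keys], dtype=int)
        seq_path = tdir / "sequence.fasta"
        if seq_path.exists():
            record.sequence = "".join(
                str(rec.seq) for rec in SeqIO.parse(seq_path, "fasta")
            )
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# template selection by sequence identity


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(a: str, b: str) -> float:
    """Global pairwise identity: identical positions / alignment length."""
    if not a or not b:
        return 0.0
    aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def select_templates(
    query_sequence: str,
    store: list[TemplateRecord],
    min_identity: float = 0.0,
    max_identity: float = 0.95,
    max_templates: int = 30,
) -> list[TemplateRecord]:
    """Rank templates by sequence identity to the query and keep those inside
    ``[min_identity, max_identity]``, truncated to ``max_templates``.

    ``max_identity`` < 1 excludes the query itself and near-duplicates, which
    keeps benchmarking leakage-free.  Raises :class:`NoTemplatesError` when
    nothing passes.
    """
    if not store:
        raise NoTemplatesError("template store is empty")
    scored = [
        (sequence_identity(query_sequence, t.sequence), i, t)
        for i, t in enumerate(store)
    ]
    kept = [
        (ident, i, t) for ident, i, t in scored
        if min_identity <= ident <= max_identity
    ]
    if not kept:
        raise NoTemplatesError(
            f"no template with identity in [{min_identity}, {max_identity}] "
            f"(best available: {max(s for s, _, _ in scored):.3f})"
        )
    kept.sort(key=lambda x: (-x[0], x[1]))
    return [t for _, _, t in kept[:max_templates]]


# ---------------------------------------------------------------------------
# balanced extra-trees ensemble


@dataclass
class TrainedModel:
    bags: list[ExtraTreesClassifier]
    columns: tuple[str, ...]
    threshold: float
    seed: int
    bag_indices: list[np.ndarray]
    importances: np.ndarray
    metadata: dict

    @property
    def n_bags(self) -> int:
        return len(self.bags)


def _bag_composition(
    labels: np.ndarray, n_bags: int, seed: int
) -> list[np.ndarray]:
    """Per-bag row indices: all minority rows plus an equal-size random
    undersample of the majority class (without replacement)."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    out = []
    for b in range(n_bags):
        rng = np.random.default_rng((seed + b) % 2**31)
        sampled = rng.choice(majority, size=len(minority), replace=False)
        out.append(np.sort(np.concatenate([minority, sampled])))
    return out


def train(
    features_frame: pd.DataFrame,
    labels: np.ndarray,
    n_bags: int = 10,
    trees_per_bag: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
    template_ids: list[str] | None = None,
) -> TrainedModel:
    """Fit the resampling-balanced Extremely Randomized Trees model.

    ``features_frame`` holds the stacked template rows (meta columns are
    ignored if present); ``labels`` is the aligned 0/1 vector.
    """
    cols = [c for c in features_frame.columns if c in feat.FEATURE_COLUMNS]
    if tuple(cols) != feat.FEATURE_COLUMNS:
        raise TrainingError("feature matrix does not carry the 42 expected columns")
    X = features_frame[list(feat.FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise TrainingError(f"{len(X)} rows vs {len(y)} labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training labels contain a single class")

    bag_indices = _bag_composition(y, n_bags, seed)
    bags = []
    for b, idx in enumerate(bag_indices):
        clf = ExtraTreesClassifier(
            n_estimators=trees_per_bag,
            random_state=(seed + b) % 2**31,
            n_jobs=1,
        )
        clf.fit(X[idx], y[idx])
        bags.append(clf)
    raw = np.mean([clf.feature_importances_ for clf in bags], axis=0)
    importances = raw / raw.sum() if raw.sum() > 0 else raw
    config = {
        "n_bags": n_bags, "trees_per_bag": trees_per_bag, "seed": seed,
        "threshold": threshold, "columns": list(feat.FEATURE_COLUMNS),
        "template_ids": template_ids or [],
    }
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    return TrainedModel(
        bags=bags,
        columns=feat.FEATURE_COLUMNS,
        threshold=threshold,
        seed=seed,
        bag_indices=bag_indices,
        importances=importances,
        metadata={**config, "config_hash": config_hash},
    )


def predict(model: TrainedModel, features_frame: pd.DataFrame) -> list[Prediction]:
    """Per-residue confidence (mean positive-class probability over all trees
    in all bags) and thresholded binary label."""
    cols = [c for c in features_frame.columns if c in feat.FEATURE_COLUMNS]
    if tuple(cols) != tuple(model.columns):
        raise ValueError("feature columns differ from the model's training columns")
    X = features_frame[list(model.columns)].to_numpy(dtype=float)
    probs = np.zeros(len(X))
    for clf in model.bags:
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        probs += clf.predict_proba(X)[:, pos_col]
    probs /= len(model.bags)
    keys = feat.residue_keys_from_frame(features_frame)
    return [
        Prediction(residue_key=k, confidence=float(p),
                   label=bool(p >= model.threshold))
        for k, p in zip(keys, probs)
    ]


def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Descending (column, importance) ranking; importances sum to 1.

    Ties are broken by the fixed column order.
    """
    order = sorted(
        range(len(model.columns)),
        key=lambda i: (-model.importances[i], i),
    )
    return [(model.columns[i], float(model.importances[i])) for i in order]


# ---------------------------------------------------------------------------
# per-query pipeline


def predict_structure(
    query: Structure,
    store: list[TemplateRecord],
    *,
    min_identity: float = 0.0,
    max_identity: float = 0.95,
    max_templates: int = 30,
    n_bags: int = 10,
    trees_per_bag: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
    **featurize_kwargs,
) -> tuple[list[Prediction], TrainedModel, pd.DataFrame]:
    """End-to-end per-query prediction: featurize, match templates, train the
    balanced ensemble, predict every residue.

    Returns (predictions, model, query feature frame).
    """
    query_frame = feat.featurize(query, **featurize_kwargs)
    selected = select_templates(
        extract_sequence(query), store,
        min_identity=min_identity, max_identity=max_identity,
        max_templates=max_templates,
    )
    logger.info("selected %d/%d templates for %s",
                len(selected), len(store), query.structure_id)
    stacked = pd.concat([t.features for t in selected], ignore_index=True)
    labels = np.concatenate([t.labels for t in selected])
    model_ = train(
        stacked, labels, n_bags=n_bags, trees_per_bag=trees_per_bag,
        seed=seed, threshold=threshold,
        template_ids=[t.structure_id for t in selected],
    )
    return predict(model_, query_frame), model_, query_frame


def save_model(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(model, path)
    return path


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
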