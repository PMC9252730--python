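"""Two-shell residue neighborhoods and the 42-descriptor feature matrix.

Each residue is summarised by 14 descriptors:

====================  =============================================
residue level         relative solvent accessibility; cysteine flag
atom level            atoms per class (aromatic, acceptor, donor,
                      hydrophobic, positive, negative) — an atom with
                      k classes increments k counters
interaction level     interactions per type touching the residue
                      (aromatic stacking, disulfide bridge, hydrogen
                      bond, hydrophobic, repulsive, salt bridge)
====================  =============================================

The residue's feature vector concatenates its own 14 descriptors with the
arithmetic mean of the descriptors over its first and second shell of
spatial neighbors (42 values total; an empty shell contributes a zero
block).  Neighborhood is a residue contact graph: two residues are adjacent
when any heavy-atom pair lies within a cutoff (6.0 Å by default), across
chain boundaries as well — which is what lets the classifier see binding
sites at protein-protein interfaces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chem
from .structure import Residue, ResidueKey, Structure

__all__ = [
    "DESCRIPTOR_NAMES",
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "NeighborhoodGraph",
    "ResidueDescriptor",
    "residue_contact_graph",
    "interaction_graph",
    "build_neighborhood",
    "interaction_counts",
    "compute_descriptors",
    "featurize",
    "write_feature_csv",
    "read_feature_csv",
    "residue_keys_from_frame",
]

DESCRIPTOR_NAMES: tuple[str, ...] = (
    "rsa",
    "is_cysteine",
    *(f"atoms_{c}" for c in chem.ATOM_CLASSES),
    *(f"int_{t}" for t in chem.INTERACTION_TYPES),
)

#: fixed 42-column order: central block, then shell-1 and shell-2 means
FEATURE_COLUMNS: tuple[str, ...] = (
    *DESCRIPTOR_NAMES,
    *(f"shell1_mean_{n}" for n in DESCRIPTOR_NAMES),
    *(f"shell2_mean_{n}" for n in DESCRIPTOR_NAMES),
)

META_COLUMNS = ("structure_id", "chain", "resnum", "icode", "restype")


@dataclass(frozen=True)
class NeighborhoodGraph:
    center: ResidueKey
    shell1: frozenset[ResidueKey]
    shell2: frozenset[ResidueKey]


@dataclass(frozen=True)
class ResidueDescriptor:
    rsa: float
    is_cysteine: int
    atom_counts: tuple[int, ...]
    interaction_counts: tuple[int, ...]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rsa, self.is_cysteine, *self.atom_counts,
             *self.interaction_counts],
            dtype=float,
        )


def residue_contact_graph(
    structure: Structure, cutoff: float = 6.0
) -> dict[ResidueKey, set[ResidueKey]]:
    """Undirected residue adjacency: some heavy-atom pair within ``cutoff`` Å.

    Adjacency crosses chain boundaries.
    """
    adjacency: dict[ResidueKey, set[ResidueKey]] = {
        res.key: set() for res in structure.residues
    }
    atoms = []
    owner_keys = []
    for res in structure.residues:
        for atom in res.heavy_atoms():
            atoms.append(atom.coords)
            owner_keys.append(res.key)
    if len(atoms) < 2:
        return adjacency
    tree = cKDTree(np.asarray(atoms))
    for i, j in tree.query_pairs(cutoff):
        ki, kj = owner_keys[i], owner_keys[j]
        if ki != kj:
            adjacency[ki].add(kj)
            adjacency[kj].add(ki)
    return adjacency


def interaction_graph(
    structure: Structure, interactions: list[chem.Interaction]
) -> dict[ResidueKey, set[ResidueKey]]:
    """Alternative neighbor criterion: residues sharing a detected interaction."""
    adjacency: dict[ResidueKey, set[ResidueKey]] = {
        res.key: set() for res in structure.residues
    }
    for inter in interactions:
        adjacency[inter.res_a].add(inter.res_b)
        adjacency[inter.res_b].add(inter.res_a)
    return adjacency


def build_neighborhood(
    adjacency: dict[ResidueKey, set[ResidueKey]], center: ResidueKey
) -> NeighborhoodGraph:
    """First and second shells of ``center``: breadth-first levels 1 and 2."""
    if center not in adjacency:
        raise KeyError(f"residue {center} not in contact graph")
    shell1 = set(adjacency[center])
    shell2: set[ResidueKey] = set()
    for nb in shell1:
        shell2.update(adjacency[nb])
    shell2 -= shell1
    shell2.discard(center)
    return NeighborhoodGraph(center, frozenset(shell1), frozenset(shell2))


def interaction_counts(
    interactions: list[chem.Interaction],
) -> dict[ResidueKey, Counter]:
    """Per-residue tally of interactions by type (counted at both endpoints)."""
    counts: dict[ResidueKey, Counter] = {}
    for inter in interactions:
        for key in (inter.res_a, inter.res_b):
            counts.setdefault(key, Counter())[inter.itype] += 1
    return counts


def compute_descriptors(
    structure: Structure,
    residue_key: ResidueKey,
    rsa_records: dict[ResidueKey, chem.RsaRecord],
    interactions: list[chem.Interaction],
    _counts: dict[ResidueKey, Counter] | None = None,
) -> ResidueDescriptor:
    """The 14 descriptors of one residue (annotation must have run already)."""
    if residue_key not in rsa_records:
        raise KeyError(f"residue {residue_key} missing from RSA records")
    residue = structure.residue_map()[residue_key]
    counts = _counts if _counts is not None else interaction_counts(interactions)
    return _descriptor_for(residue, rsa_records[residue_key],
                           counts.get(residue_key, Counter()))


def _descriptor_for(
    residue: Residue, rsa: chem.RsaRecord, icounts: Counter
) -> ResidueDescriptor:
    atom_counts = [0] * len(chem.ATOM_CLASSES)
    for atom in residue.heavy_atoms():
        for idx, cls in enumerate(chem.ATOM_CLASSES):
            if cls in atom.classes:
                atom_counts[idx] += 1
    return ResidueDescriptor(
        rsa=rsa.rsa,
        is_cysteine=int(residue.res_type == "CYS"),
        atom_counts=tuple(atom_counts),
        interaction_counts=tuple(
            icounts.get(t, 0) for t in chem.INTERACTION_TYPES
        ),
    )


def featurize(
    structure: Structure,
    *,
    contact_cutoff: float = 6.0,
    probe_radius: float = 1.4,
    sasa_points: int = 960,
    neighbor_mode: str = "distance",
    atom_table: chem.AtomClassTable | None = None,
    interaction_config: chem.InteractionConfig | None = None,
) -> pd.DataFrame:
    """Run the full encoding and return the residue-by-descriptor data matrix.

    One row per polymer residue, ``META_COLUMNS`` for identity plus the 42
    ``FEATURE_COLUMNS``: the central residue's 14 descriptors followed by the
    shell-1 and shell-2 means (zero blocks for empty shells).

    ``neighbor_mode`` selects the shell criterion: ``"distance"`` (default,
    heavy-atom contact graph at ``contact_cutoff``) or ``"interaction"``
    (residues joined by a detected interaction).
    """
    if not structure.residues:
        raise ValueError("cannot featurize an empty structure")
    chem.assign_atom_classes(structure, atom_table)
    rsa_records = chem.compute_rsa(
        structure, probe_radius=probe_radius, n_points=sasa_points
    )
    interactions = chem.detect_interactions(structure, interaction_config)
    if neighbor_mode == "distance":
        adjacency = residue_contact_graph(structure, cutoff=contact_cutoff)
    elif neighbor_mode == "interaction":
        adjacency = interaction_graph(structure, interactions)
    else:
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")

    icounts = interaction_counts(interactions)
    descriptors: dict[ResidueKey, np.ndarray] = {}
    for res in structure.residues:
        if res.key not in rsa_records:
            continue  # no heavy atoms; excluded from RSA and from the matrix
        descriptors[res.key] = _descriptor_for(
            res, rsa_records[res.key], icounts.get(res.key, Counter())
        ).as_array()

    n_desc = len(DESCRIPTOR_NAMES)
    rows = []
    meta = []
    for res in structure.residues:
        if res.key not in descriptors:
            continue
        hood = build_neighborhood(adjacency, res.key)
        vec = np.zeros(3 * n_desc)
        vec[:n_desc] = descriptors[res.key]
        for offset, shell in ((n_desc, hood.shell1), (2 * n_desc, hood.shell2)):
            members = [descriptors[k] for k in shell if k in descriptors]
            if members:
                vec[offset:offset + n_desc] = np.mean(members, axis=0)
        rows.append(vec)
        meta.append(
            (structure.structure_id, res.chain_id, res.seq_number,
             res.insertion_code, res.res_type)
        )
    frame = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    for i, col in enumerate(META_COLUMNS):
        frame.insert(i, col, [m[i] for m in meta])
    return frame


def residue_keys_from_frame(frame: pd.DataFrame) -> list[ResidueKey]:
    """Residue keys of a feature (or prediction) frame, in row order."""
    return [
        (str(c), int(n), str(i))
        for c, n, i in zip(frame["chain"], frame["resnum"], frame["icode"].fillna(""))
    ]


def write_feature_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False, na_values=[],
                        dtype={"chain": str, "icode": str, "restype": str})
    frame["resnum"] = frame["resnum"].astype(int)
    for col in FEATURE_COLUMNS:
        frame[col] = frame[col].astype(float)
    missing = (set(META_COLUMNS) | set(FEATURE_COLUMNS)) - set(frame.columns)
    if missing:
        raise ValueError(f"feature CSV missing columns: {sorted(missing)[:5]} ...")
    return frame
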