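"""Physicochemical annotation: atom classes, solvent accessibility, interactions.

Three ingredients feed the residue descriptors:

* **atom classes** — every heavy atom is tagged with a subset of the six
  classes {aromatic, acceptor, donor, hydrophobic, positive, negative},
  looked up in a shipped ``(res_type, atom_name)`` table covering the 20
  standard amino acids.  An atom may carry several classes (TYR OH is both
  donor and acceptor); unknown pairs degrade to the empty set and are tallied.

* **relative solvent accessibility (RSA)** — per-residue SASA by the
  Shrake–Rupley sphere-sampling method over heavy atoms (probe 1.4 Å,
  960 points by default), normalised by a table of theoretical maximum
  accessible areas and clamped to [0, 1].

* **non-covalent interactions** — six types (aromatic stacking, disulfide
  bridge, hydrogen bond, hydrophobic, repulsive, salt bridge) detected
  purely from atom classes and Euclidean distance windows.  The windows are
  shipped in an editable config file; pairs of backbone atoms in
  sequence-adjacent residues of the same chain are excluded as covalent
  neighborhood.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder
from scipy.spatial import cKDTree

from .structure import BACKBONE_ATOMS, Atom, Residue, ResidueKey, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ATOM_CLASSES",
    "INTERACTION_TYPES",
    "AtomClassTable",
    "InteractionConfig",
    "Interaction",
    "RsaRecord",
    "load_atom_class_table",
    "load_max_asa",
    "load_interaction_config",
    "assign_atom_classes",
    "compute_rsa",
    "detect_interactions",
]

ATOM_CLASSES = (
    "aromatic", "acceptor", "donor", "hydrophobic", "positive", "negative",
)

INTERACTION_TYPES = (
    "aromatic_stacking", "disulfide_bridge", "hydrogen_bond",
    "hydrophobic", "repulsive", "salt_bridge",
)

#: fallback maximum ASA (Å²) for residues missing from the shipped table
DEFAULT_MAX_ASA = 200.0


@dataclass(frozen=True)
class AtomClassTable:
    entries: dict[tuple[str, str], frozenset[str]]

    def lookup(self, res_type: str, atom_name: str) -> frozenset[str] | None:
        return self.entries.get((res_type, atom_name))


def _read_table_text(name: str, path: str | Path | None) -> str:
    if path is None:
        return resources.files("resbind.data").joinpath(name).read_text()
    return Path(path).read_text()


def load_atom_class_table(path: str | Path | None = None) -> AtomClassTable:
    """Load the ``(res_type, atom_name) -> classes`` typing table (TSV)."""
    entries: dict[tuple[str, str], frozenset[str]] = {}
    for line in _read_table_text("atom_classes.tsv", path).splitlines():
        line = line.split("#", 1)[0].rstrip()
        if not line:
            continue
        parts = line.split("\t")
        res, atom = parts[0].strip(), parts[1].strip()
        raw = parts[2].strip() if len(parts) > 2 else ""
        classes = frozenset(c.strip() for c in raw.split(",") if c.strip())
        unknown = classes - set(ATOM_CLASSES)
        if unknown:
            raise ValueError(f"unknown atom classes {sorted(unknown)} for {res} {atom}")
        entries[(res, atom)] = classes
    return AtomClassTable(entries)


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Theoretical maximum accessible surface per residue type (Å²)."""
    table: dict[str, float] = {}
    for line in _read_table_text("max_asa.tsv", path).splitlines():
        line = line.split("#", 1)[0].rstrip()
        if not line:
            continue
        res, val = line.split("\t")
        table[res.strip()] = float(val)
    return table


@dataclass(frozen=True)
class InteractionConfig:
    """Distance windows (Å) per interaction type, both ends inclusive."""

    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for itype, (lo, hi) in self.windows.items():
            if itype not in INTERACTION_TYPES:
                raise ValueError(f"unknown interaction type {itype!r}")
            if not 0 <= lo < hi:
                raise ValueError(f"invalid window [{lo}, {hi}] for {itype}")

    @property
    def max_distance(self) -> float:
        return max(hi for _, hi in self.windows.values())


def load_interaction_config(path: str | Path | None = None) -> InteractionConfig:
    windows: dict[str, tuple[float, float]] = {}
    for line in _read_table_text("interactions.tsv", path).splitlines():
        line = line.split("#", 1)[0].rstrip()
        if not line:
            continue
        itype, lo, hi = line.split("\t")
        windows[itype.strip()] = (float(lo), float(hi))
    missing = set(INTERACTION_TYPES) - set(windows)
    if missing:
        raise ValueError(f"interaction config missing types: {sorted(missing)}")
    return InteractionConfig(windows)


@dataclass(frozen=True)
class Interaction:
    itype: str
    res_a: ResidueKey
    atom_a: str
    res_b: ResidueKey
    atom_b: str
    distance: float


@dataclass(frozen=True)
class RsaRecord:
    residue_key: ResidueKey
    sasa: float
    max_asa: float
    rsa: float


# ---------------------------------------------------------------------------
# atom class assignment


def assign_atom_classes(
    structure: Structure, table: AtomClassTable | None = None
) -> Counter:
    """Tag every heavy atom with its class set, in place.

    Returns a diagnostics tally of ``(res_type, atom_name)`` pairs absent from
    the table (those atoms get the empty class set).
    """
    if table is None:
        table = load_atom_class_table()
    unknown: Counter = Counter()
    for res in structure.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                atom.classes = frozenset()
                continue
            classes = table.lookup(res.res_type, atom.name)
            if classes is None:
                unknown[(res.res_type, atom.name)] += 1
                atom.classes = frozenset()
            else:
                atom.classes = classes
    if unknown:
        logger.info(
            "atom typing: %d atom(s) of %d unknown (res_type, atom_name) pairs "
            "got the empty class set", sum(unknown.values()), len(unknown)
        )
    return unknown


# ---------------------------------------------------------------------------
# solvent accessibility


def _build_biopdb_entity(structure: Structure):
    """Heavy-atom Bio.PDB copy of the model, for SASA computation."""
    sb = StructureBuilder()
    sb.init_structure(structure.structure_id)
    sb.init_model(0)
    serial = 1
    seen_chains: set[str] = set()
    for res in structure.residues:
        if res.chain_id not in seen_chains:
            sb.init_chain(res.chain_id)
            sb.init_seg(" ")
            seen_chains.add(res.chain_id)
        sb.init_residue(res.res_type, " ", res.seq_number, res.insertion_code or " ")
        for atom in res.heavy_atoms():
            sb.init_atom(
                atom.name,
                np.asarray(atom.coords, dtype=float),
                0.0,
                1.0,
                " ",
                atom.name.center(4),
                serial,
                element=atom.element,
            )
            serial += 1
    return sb.get_structure()


def compute_rsa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    max_asa_table: dict[str, float] | None = None,
) -> dict[ResidueKey, RsaRecord]:
    """Per-residue relative solvent accessibility in [0, 1].

    SASA is computed with the Shrake–Rupley method over heavy atoms only and
    normalised by the residue type's theoretical maximum area (clamped at 1).
    Residues without heavy atoms are excluded with a warning.
    """
    if max_asa_table is None:
        max_asa_table = load_max_asa()
    entity = _build_biopdb_entity(structure)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(entity, level="R")
    sasa_by_key: dict[ResidueKey, float] = {}
    for chain in entity[0]:
        for bres in chain:
            key = (chain.id, bres.id[1], bres.id[2].strip())
            sasa_by_key[key] = float(bres.sasa)
    records: dict[ResidueKey, RsaRecord] = {}
    for res in structure.residues:
        if not res.heavy_atoms():
            logger.warning("residue %s has no heavy atoms; skipped in RSA", res.key)
            continue
        sasa = sasa_by_key[res.key]
        max_asa = max_asa_table.get(res.res_type, DEFAULT_MAX_ASA)
        records[res.key] = RsaRecord(
            residue_key=res.key,
            sasa=sasa,
            max_asa=max_asa,
            rsa=min(1.0, sasa / max_asa),
        )
    return records


# ---------------------------------------------------------------------------
# interaction detection


def _pair_types(
    res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom
) -> list[str]:
    ca, cb = atom_a.classes, atom_b.classes
    types = []
    if ("donor" in ca and "acceptor" in cb) or ("acceptor" in ca and "donor" in cb):
        types.append("hydrogen_bond")
    if ("positive" in ca and "negative" in cb) or ("negative" in ca and "positive" in cb):
        types.append("salt_bridge")
    if ("positive" in ca and "positive" in cb) or ("negative" in ca and "negative" in cb):
        types.append("repulsive")
    if "hydrophobic" in ca and "hydrophobic" in cb:
        types.append("hydrophobic")
    if "aromatic" in ca and "aromatic" in cb:
        types.append("aromatic_stacking")
    if (res_a.res_type == "CYS" and atom_a.name == "SG"
            and res_b.res_type == "CYS" and atom_b.name == "SG"):
        types.append("disulfide_bridge")
    return types


def _chain_positions(structure: Structure) -> dict[ResidueKey, tuple[str, int]]:
    pos: dict[ResidueKey, tuple[str, int]] = {}
    for cid in structure.chain_ids:
        for i, res in enumerate(structure.chain(cid)):
            pos[res.key] = (cid, i)
    return pos


def _covalent_neighbors(
    pos: dict[ResidueKey, tuple[str, int]], key_a: ResidueKey, key_b: ResidueKey
) -> bool:
    ca, ia = pos[key_a]
    cb, ib = pos[key_b]
    return ca == cb and abs(ia - ib) == 1


def detect_interactions(
    structure: Structure, config: InteractionConfig | None = None
) -> list[Interaction]:
    """Detect the six non-covalent interaction types between heavy atoms of
    different residues.

    A pair can satisfy several types at once; one :class:`Interaction` is
    emitted per satisfied type.  Backbone–backbone pairs of sequence-adjacent
    residues on the same chain are skipped (covalent neighborhood).  Uses a
    KD-tree to enumerate candidate pairs within the widest window.
    """
    if config is None:
        config = load_interaction_config()
    atoms: list[Atom] = []
    owners: list[Residue] = []
    for res in structure.residues:
        for atom in res.heavy_atoms():
            atoms.append(atom)
            owners.append(res)
    if len(atoms) < 2:
        return []
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    pos = _chain_positions(structure)
    out: list[Interaction] = []
    for i, j in sorted(tree.query_pairs(config.max_distance)):
        res_i, res_j = owners[i], owners[j]
        if res_i.key == res_j.key:
            continue
        atom_i, atom_j = atoms[i], atoms[j]
        if (atom_i.name in BACKBONE_ATOMS and atom_j.name in BACKBONE_ATOMS
                and _covalent_neighbors(pos, res_i.key, res_j.key)):
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        # canonical endpoint order keeps output independent of input ordering
        if (res_j.key, atom_j.name) < (res_i.key, atom_i.name):
            res_i, res_j = res_j, res_i
            atom_i, atom_j = atom_j, atom_i
        for itype in _pair_types(res_i, atom_i, res_j, atom_j):
            lo, hi = config.windows[itype]
            if lo <= dist <= hi:
                out.append(
                    Interaction(itype, res_i.key, atom_i.name,
                                res_j.key, atom_j.name, dist)
                )
    return out
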