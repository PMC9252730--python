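"""Protein structure data model and PDB-format I/O.

The package is residue-centric: every downstream stage (chemical annotation,
neighborhood featurization, classification, pocket clustering) operates on the
:class:`Structure` / :class:`Residue` / :class:`Atom` model defined here.
Parsing and serialisation of the PDB dialect are delegated to :mod:`gemmi`;
this module adds the conventions the pipeline relies on:

* first model only, for multi-model (NMR-style) files;
* alternate locations resolved to the highest-occupancy conformer
  (ties broken by altloc letter order);
* HETATM groups become :class:`LigandGroup` entries unless their HET code is
  on the shipped exclusion list (water, cryo-agents, buffers, counter-ions);
* residue identity is the opaque key ``(chain_id, seq_number, insertion_code)``
  — never a sequential index — so author numbering survives round-trips.

Hydrogens, when present, are kept in the model but ignored by every
descriptor computation downstream (heavy-atom convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "LigandGroup",
    "Structure",
    "ResidueKey",
    "PdbParseError",
    "EmptyStructureError",
    "ConsistencyError",
    "load_ligand_exclusions",
    "parse_pdb",
    "extract_sequence",
    "structure_to_pdb_string",
    "write_predictions",
    "read_predictions_csv",
]

ResidueKey = tuple[str, int, str]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class PdbParseError(ValueError):
    """Raised when the input cannot be read as PDB-dialect text."""


class EmptyStructureError(PdbParseError):
    """Raised when parsing yields no polymer residues."""


class ConsistencyError(ValueError):
    """Raised when cross-referenced inputs disagree (e.g. a prediction
    pointing at a residue the structure does not contain)."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    classes: frozenset[str] = frozenset()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name!r} has no element")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class LigandGroup:
    het_code: str
    chain_id: str
    seq_number: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.het_code, self.chain_id, self.seq_number)


@dataclass
class Structure:
    structure_id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[LigandGroup] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {res.key: res for res in self.residues}

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chain_ids:
            raise KeyError(f"no chain {chain_id!r} in structure {self.structure_id}")
        return [r for r in self.residues if r.chain_id == chain_id]

    def __len__(self) -> int:
        return len(self.residues)


def load_ligand_exclusions(path: str | Path | None = None) -> frozenset[str]:
    """HET codes filtered out of the ligand list (water, buffers, ions).

    Reads the shipped list unless an override file is given.
    """
    if path is None:
        text = resources.files("resbind.data").joinpath("ligand_exclude.txt").read_text()
    else:
        text = Path(path).read_text()
    codes = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.add(line.upper())
    return frozenset(codes)


# ---------------------------------------------------------------------------
# parsing


def _select_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by altloc letter order
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name
    if name and name != "X":
        return name
    # element column absent: first alphabetic character of the atom name
    for ch in atom.name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _read_gemmi(source: str | Path) -> gemmi.Structure:
    if isinstance(source, Path):
        return gemmi.read_pdb(str(source))
    text = str(source)
    looks_like_records = any(
        text.lstrip().startswith(tag)
        for tag in ("ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "CRYST", "TITLE")
    ) or "\n" in text
    if looks_like_records:
        return gemmi.read_pdb_string(text)
    return gemmi.read_pdb(text)


def parse_pdb(
    source: str | Path,
    structure_id: str | None = None,
    exclusions: frozenset[str] | None = None,
) -> Structure:
    """Parse PDB-dialect text (a path or the text itself) into a :class:`Structure`.

    Only the first model of multi-model files is used.  ATOM records become
    polymer residues; HETATM groups become ligands unless excluded.  Raises
    :class:`EmptyStructureError` when no polymer residue survives.
    """
    if exclusions is None:
        exclusions = load_ligand_exclusions()
    try:
        st = _read_gemmi(source)
    except (RuntimeError, ValueError, OSError) as exc:
        raise PdbParseError(f"cannot read PDB input: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("input contains no coordinate model")

    sid = structure_id or st.name or "structure"
    model = st[0]
    out = Structure(structure_id=sid)
    for chain in model:
        for gres in chain:
            # resolve alternate conformers per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for gatom in gres:
                by_name.setdefault(gatom.name, []).append(gatom)
            atoms = []
            for name in by_name:
                ga = _select_altloc(by_name[name])
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=name,
                        element=_element_of(ga),
                        coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\0" else "",
                        b_factor=ga.b_iso,
                    )
                )
            if not atoms:
                continue
            resname = gres.name.strip().upper()
            het = gres.het_flag
            is_polymer = het == "A" or (het not in ("H",) and resname in STANDARD_AA)
            if is_polymer:
                out.residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        res_type=resname,
                        atoms=atoms,
                        is_polymer=True,
                    )
                )
            else:
                if gres.is_water() or resname in exclusions:
                    continue
                out.ligands.append(
                    LigandGroup(
                        het_code=resname,
                        chain_id=chain.name,
                        seq_number=gres.seqid.num,
                        atoms=atoms,
                    )
                )
    if not out.residues:
        raise EmptyStructureError(
            f"no polymer (ATOM) residues found in {sid!r}"
        )
    keys = [r.key for r in out.residues]
    if len(keys) != len(set(keys)):
        raise PdbParseError(f"duplicate residue identifiers in {sid!r}")
    return out


# ---------------------------------------------------------------------------
# sequence extraction


def extract_sequence(structure: Structure, chain_id: str = "all") -> str:
    """One-letter sequence in residue order; non-standard residues become 'X'.

    ``chain_id="all"`` concatenates chains in file order (per-chain pieces are
    available via :func:`chain_sequences`).
    """
    if chain_id == "all":
        residues: Iterable[Residue] = structure.residues
    else:
        residues = structure.chain(chain_id)
    return "".join(AA3TO1.get(r.res_type, "X") for r in residues)


def chain_sequences(structure: Structure) -> dict[str, str]:
    """Per-chain one-letter sequences, keyed by chain id, in chain order."""
    return {cid: extract_sequence(structure, cid) for cid in structure.chain_ids}


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def get_chain(cid: str) -> gemmi.Chain:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        return chains[cid]

    serial = 1
    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.res_type
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gres.het_flag = "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_factor
            ga.serial = serial
            if atom.altloc:
                ga.altloc = atom.altloc
            serial += 1
            gres.add_atom(ga)
        get_chain(res.chain_id).add_residue(gres)
    for lig in structure.ligands:
        gres = gemmi.Residue()
        gres.name = lig.het_code
        gres.seqid = gemmi.SeqId(lig.seq_number, " ")
        gres.het_flag = "H"
        for atom in lig.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_factor
            ga.serial = serial
            serial += 1
            gres.add_atom(ga)
        get_chain(lig.chain_id).add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def structure_to_pdb_string(structure: Structure) -> str:
    """Serialise the model back to PDB text (3-decimal coordinate precision)."""
    return _to_gemmi(structure).make_pdb_string()


PREDICTION_CSV_COLUMNS = [
    "structure_id", "chain", "resnum", "icode", "restype", "predicted", "confidence",
]


def write_predictions(structure: Structure, predictions, out: str | Path,
                      format: str = "csv") -> Path:
    """Write per-residue predictions as CSV or as a confidence-annotated PDB.

    CSV rows carry the residue identity, the binary label and the confidence.
    PDB output copies the structure with each predicted residue's confidence
    (scaled to 0-100, 2 decimals) in the temperature-factor column of its atoms.
    """
    out = Path(out)
    resmap = structure.residue_map()
    for pred in predictions:
        if pred.residue_key not in resmap:
            raise ConsistencyError(
                f"prediction refers to residue {pred.residue_key} absent from "
                f"structure {structure.structure_id}"
            )
    if format == "csv":
        rows = [
            {
                "structure_id": structure.structure_id,
                "chain": pred.residue_key[0],
                "resnum": pred.residue_key[1],
                "icode": pred.residue_key[2],
                "restype": resmap[pred.residue_key].res_type,
                "predicted": int(pred.label),
                "confidence": float(pred.confidence),
            }
            for pred in predictions
        ]
        frame = pd.DataFrame(rows, columns=PREDICTION_CSV_COLUMNS)
        frame.to_csv(out, index=False)
        return out
    if format == "pdb":
        annotated = Structure(
            structure_id=structure.structure_id,
            residues=[
                Residue(r.chain_id, r.seq_number, r.insertion_code, r.res_type,
                        [Atom(a.serial, a.name, a.element, a.coords, a.occupancy,
                              a.altloc, a.b_factor) for a in r.atoms],
                        r.is_polymer)
                for r in structure.residues
            ],
            ligands=structure.ligands,
        )
        resmap2 = annotated.residue_map()
        for pred in predictions:
            bfac = round(float(pred.confidence) * 100.0, 2)
            for atom in resmap2[pred.residue_key].atoms:
                atom.b_factor = bfac
        out.write_text(structure_to_pdb_string(annotated))
        return out
    raise ValueError(f"unknown prediction output format {format!r}")


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    """Read a prediction CSV written by :func:`write_predictions`."""
    frame = pd.read_csv(
        path,
        dtype={"structure_id": str, "chain": str, "restype": str, "predicted": int},
        keep_default_na=False,
        na_values=[],
    )
    missing = set(PREDICTION_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ConsistencyError(f"prediction CSV missing columns: {sorted(missing)}")
    frame["icode"] = frame["icode"].astype(str).str.strip()
    frame["confidence"] = frame["confidence"].astype(float)
    return frame
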