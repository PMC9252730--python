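"""Synthetic structure and template-store generator with known ground truth.

Every stage of the pipeline is testable offline against fixtures produced
here: toy multi-residue structures in PDB format with named heavy atoms, an
optional placed pseudo-ligand whose contact residues are the planted binding
site, and on-disk template stores in the training-data layout.

The generated "proteins" are deliberately simple (no rotamers, no
energetics): CA traces follow a chosen fold (helical spiral, cubic lattice,
or self-avoiding coil), backbone atoms N/C/O hang off each CA in a local
frame, and short pseudo-side chains use real PDB atom names so the shipped
typing table covers every atom.  What the fixtures *do* emulate is the
statistical structure of the learning problem: binding sites are compact
surface patches of polar/charged residues on an otherwise apolar fold,
while a fraction of scattered polar "decoys" in the background ensures the
classifier must read the spatial neighborhood, not just residue identity.

The ground-truth labels, the residue adjacency and the ligand geometry are
recorded in a manifest computed by brute-force distance scans on the
re-parsed PDB text, so the manifest doubles as an independent oracle for
the production (KD-tree based) code paths.  Seeded generation is
byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .model import VDW_RADII, DEFAULT_VDW
from .structure import (
    Atom,
    LigandGroup,
    Residue,
    Structure,
    parse_pdb,
    chain_sequences,
    structure_to_pdb_string,
)

__all__ = [
    "POLAR_RESIDUES",
    "APOLAR_RESIDUES",
    "FixtureSpec",
    "FixturePlacementError",
    "generate_structure",
    "write_fixture",
    "generate_template_store",
]

POLAR_RESIDUES = ("ASP", "GLU", "LYS", "ARG", "HIS", "SER", "ASN")
APOLAR_RESIDUES = ("ALA", "LEU", "VAL", "ILE", "PHE", "MET", "GLY")

HELIX_RADIUS = 2.3
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RISE = 1.5
COIL_STEP = 3.8

# pseudo-side chains: (atom name, depth along the outward direction, branch)
SIDE_TEMPLATES: dict[str, list[tuple[str, int, int]]] = {
    "ALA": [("CB", 0, 0)],
    "ARG": [("CB", 0, 0), ("CG", 1, 0), ("NE", 2, 0), ("NH1", 3, 0)],
    "ASN": [("CB", 0, 0), ("CG", 1, 0), ("OD1", 2, -1), ("ND2", 2, 1)],
    "ASP": [("CB", 0, 0), ("CG", 1, 0), ("OD1", 2, -1), ("OD2", 2, 1)],
    "CYS": [("CB", 0, 0), ("SG", 1, 0)],
    "GLN": [("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("OE1", 3, -1), ("NE2", 3, 1)],
    "GLU": [("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("OE1", 3, -1), ("OE2", 3, 1)],
    "GLY": [],
    "HIS": [("CB", 0, 0), ("CG", 1, 0), ("ND1", 2, -1), ("NE2", 2, 1)],
    "ILE": [("CB", 0, 0), ("CG1", 1, -1), ("CG2", 1, 1), ("CD1", 2, -1)],
    "LEU": [("CB", 0, 0), ("CG", 1, 0), ("CD1", 2, -1), ("CD2", 2, 1)],
    "LYS": [("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("NZ", 3, 0)],
    "MET": [("CB", 0, 0), ("CG", 1, 0), ("SD", 2, 0), ("CE", 3, 0)],
    "PHE": [("CB", 0, 0), ("CG", 1, 0), ("CD1", 2, -1), ("CD2", 2, 1)],
    "PRO": [("CB", 0, 0), ("CG", 1, 0)],
    "SER": [("CB", 0, 0), ("OG", 1, 0)],
    "THR": [("CB", 0, 0), ("OG1", 1, -1), ("CG2", 1, 1)],
    "TRP": [("CB", 0, 0), ("CG", 1, 0), ("NE1", 2, 0)],
    "TYR": [("CB", 0, 0), ("CG", 1, 0), ("OH", 2, 0)],
    "VAL": [("CB", 0, 0), ("CG1", 1, -1), ("CG2", 1, 1)],
}

LIGAND_ELEMENTS = ("O", "N", "C")


class FixturePlacementError(RuntimeError):
    """Raised when a pseudo-ligand cannot contact exactly the requested
    targets (targets too dispersed for the stated contact distance)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure.

    ``ligand_targets`` are 0-based global residue indices; ``None`` selects a
    compact surface patch automatically and ``"interface"`` plants the site
    between the chains of a multi-chain fixture.
    """

    n_residues: int = 60
    fold: str = "helix"            # helix | lattice | coil
    n_chains: int = 1
    seed: int = 0
    ligand: str = "placed"         # placed | none
    ligand_targets: tuple[int, ...] | str | None = None
    patch_size: int = 5
    contact_distance: float = 3.0
    ligand_push: float = 3.0       # outward offset of the ligand centroid (Å)
    polar_decoy_fraction: float = 0.1
    lattice_spacing: float = 8.0
    chain_gap: float = 9.0         # gap between chain CA bounding boxes (Å)
    adjacency_cutoff: float = 6.0
    het_code: str = "LG1"
    structure_id: str = "fixture"
    strict_targets: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.fold not in ("helix", "lattice", "coil"):
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


# ---------------------------------------------------------------------------
# geometry


def _chain_sizes(spec: FixtureSpec) -> list[int]:
    base = spec.n_residues // spec.n_chains
    sizes = [base] * spec.n_chains
    for i in range(spec.n_residues - base * spec.n_chains):
        sizes[i] += 1
    return sizes


def _helix_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([
        HELIX_RADIUS * np.cos(HELIX_TWIST * i),
        HELIX_RADIUS * np.sin(HELIX_TWIST * i),
        HELIX_RISE * i,
    ])


def _lattice_trace(n: int, spacing: float) -> np.ndarray:
    k = int(np.ceil(n ** (1 / 3)))
    pts = [np.array(idx, dtype=float) * spacing for idx in np.ndindex(k, k, k)]
    return np.array(pts[:n])


def _coil_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    pts = [np.zeros(3)]
    while len(pts) < n:
        for _ in range(200):
            step = rng.normal(size=3)
            step = COIL_STEP * step / np.linalg.norm(step)
            cand = pts[-1] + step
            if all(np.linalg.norm(cand - p) >= 4.0 for p in pts[:-1]):
                pts.append(cand)
                break
        else:
            raise FixturePlacementError("self-avoiding coil walk got stuck")
    return np.array(pts)


def _ca_trace(spec: FixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """CA coordinates for every residue plus the chain id of each."""
    sizes = _chain_sizes(spec)
    all_ca = []
    chain_of: list[str] = []
    # chains laid side by side along x, separated by chain_gap between their
    # CA bounding boxes, so facing side chains can form interface contacts
    offset_x = 0.0
    for c, size in enumerate(sizes):
        if spec.fold == "helix":
            trace = _helix_trace(size, rng)
        elif spec.fold == "lattice":
            trace = _lattice_trace(size, spec.lattice_spacing)
        else:
            trace = _coil_trace(size, rng)
        if c > 0:
            trace = trace + np.array([offset_x - trace[:, 0].min(), 0.0, 0.0])
        all_ca.append(trace)
        offset_x = trace[:, 0].max() + spec.chain_gap
        chain_of.extend([chr(ord("A") + c)] * size)
    return np.vstack(all_ca), chain_of


def _frames(ca: np.ndarray, chain_of: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local frames per residue: tangent t, outward u, binormal w."""
    n = len(ca)
    t = np.zeros((n, 3))
    for i in range(n):
        nxt = i + 1 if i + 1 < n and chain_of[i + 1] == chain_of[i] else i
        prv = i - 1 if i - 1 >= 0 and chain_of[i - 1] == chain_of[i] else i
        vec = ca[nxt] - ca[prv]
        norm = np.linalg.norm(vec)
        t[i] = vec / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    # outward: away from the chain's own centroid (per chain)
    u = np.zeros((n, 3))
    for cid in set(chain_of):
        idx = [i for i, c in enumerate(chain_of) if c == cid]
        centroid = ca[idx].mean(axis=0)
        for i in idx:
            vec = ca[i] - centroid
            vec = vec - t[i] * np.dot(vec, t[i])  # project off the tangent
            norm = np.linalg.norm(vec)
            u[i] = vec / norm if norm > 1e-9 else _any_perpendicular(t[i])
    w = np.cross(t, u)
    wn = np.linalg.norm(w, axis=1, keepdims=True)
    wn[wn < 1e-9] = 1.0
    return t, u, w / wn


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(v, ref)
    return perp / np.linalg.norm(perp)


def _element_of_name(name: str) -> str:
    return name[0]


def _build_residue(
    chain_id: str, seq_number: int, res_type: str,
    ca: np.ndarray, t: np.ndarray, u: np.ndarray, w: np.ndarray, serial: int,
) -> tuple[Residue, int]:
    atoms = [
        Atom(serial, "N", "N", tuple(ca - 1.2 * t + 0.5 * w)),
        Atom(serial + 1, "CA", "C", tuple(ca)),
        Atom(serial + 2, "C", "C", tuple(ca + 1.2 * t + 0.3 * w)),
        Atom(serial + 3, "O", "O", tuple(ca + 1.2 * t + 1.5 * w)),
    ]
    serial += 4
    for name, depth, branch in SIDE_TEMPLATES[res_type]:
        pos = ca + (1.53 + 1.3 * depth) * u + 0.7 * branch * w
        atoms.append(Atom(serial, name, _element_of_name(name), tuple(pos)))
        serial += 1
    return Residue(chain_id, seq_number, "", res_type, atoms), serial


# ---------------------------------------------------------------------------
# target selection and ligand placement


def _auto_patch(
    ca: np.ndarray, chain_of: list[str], spec: FixtureSpec,
    rng: np.random.Generator,
) -> list[int]:
    if spec.ligand_targets == "interface":
        if spec.n_chains < 2:
            raise ValueError("interface targets need n_chains >= 2")
        first = chain_of[0]
        ia = [i for i, c in enumerate(chain_of) if c == first]
        ib = [i for i, c in enumerate(chain_of) if c != first]
        pairs = [(np.linalg.norm(ca[i] - ca[j]), i, j) for i in ia for j in ib]
        _, i0, j0 = min(pairs)
        half = max(1, spec.patch_size // 2)
        near_a = sorted(ia, key=lambda i: np.linalg.norm(ca[i] - ca[i0]))[:half + 1]
        near_b = sorted(ib, key=lambda j: np.linalg.norm(ca[j] - ca[j0]))[:half]
        return sorted(set(near_a) | set(near_b))
    # single compact surface patch: a far-from-centroid seed plus its
    # nearest residues in space
    centroid = ca.mean(axis=0)
    radial = np.linalg.norm(ca - centroid, axis=1)
    surface = np.argsort(-radial)[: max(4, len(ca) // 4)]
    seed_idx = int(rng.choice(surface))
    order = np.argsort(np.linalg.norm(ca - ca[seed_idx], axis=1))
    return sorted(int(i) for i in order[: spec.patch_size])


def _side_tip(residue: Residue) -> np.ndarray:
    heavy = residue.heavy_atoms()
    side = [a for a in heavy if a.name not in ("N", "CA", "C", "O")]
    tip = side[-1] if side else residue.get_atom("CA")
    return np.asarray(tip.coords, dtype=float)


def _place_ligand(
    residues: list[Residue], targets: list[int], spec: FixtureSpec,
) -> LigandGroup:
    tips = np.array([_side_tip(residues[i]) for i in targets])
    centroid_all = np.mean(
        [a.coords for r in residues for a in r.atoms], axis=0
    )
    patch_center = tips.mean(axis=0)
    chains_hit = {residues[i].chain_id for i in targets}
    if len(chains_hit) > 1:
        anchor = patch_center  # between the chains already
    else:
        out = patch_center - centroid_all
        norm = np.linalg.norm(out)
        out = out / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        anchor = patch_center + spec.ligand_push * out
    atoms = []
    serial = 1
    for k, tip in enumerate(tips):
        direction = anchor - tip
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        elem = LIGAND_ELEMENTS[k % len(LIGAND_ELEMENTS)]
        pos = tip + spec.contact_distance * direction
        atoms.append(Atom(serial, f"{elem}{k + 1}", elem, tuple(pos)))
        serial += 1
    if len(atoms) < 3:
        atoms.append(Atom(serial, f"C{len(atoms) + 1}", "C", tuple(anchor)))
    lig_chain = residues[targets[0]].chain_id
    return LigandGroup(spec.het_code, lig_chain, 900, atoms)


# ---------------------------------------------------------------------------
# brute-force oracles for the manifest


def _scan_labels(structure: Structure, margin: float = 0.5) -> list[int]:
    """All-pairs vdW-contact labels (independent of the KD-tree code path)."""
    labels = []
    lig_atoms = [
        (np.asarray(a.coords), VDW_RADII.get(a.element.upper(), DEFAULT_VDW))
        for lig in structure.ligands for a in lig.atoms if not a.is_hydrogen
    ]
    for res in structure.residues:
        hit = 0
        for atom in res.heavy_atoms():
            rad = VDW_RADII.get(atom.element.upper(), DEFAULT_VDW)
            pos = np.asarray(atom.coords)
            for lpos, lrad in lig_atoms:
                if np.linalg.norm(pos - lpos) <= rad + lrad + margin:
                    hit = 1
                    break
            if hit:
                break
        labels.append(hit)
    return labels


def _scan_adjacency(structure: Structure, cutoff: float) -> list[list[int]]:
    """All-pairs residue adjacency (min heavy-atom distance <= cutoff)."""
    coords = [
        np.array([a.coords for a in res.heavy_atoms()])
        for res in structure.residues
    ]
    n = len(coords)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            if np.min(np.sqrt((diff ** 2).sum(axis=2))) <= cutoff:
                pairs.append([i, j])
    return pairs


# ---------------------------------------------------------------------------
# public API


def generate_structure(spec: FixtureSpec) -> tuple[str, dict]:
    """Generate one fixture; returns ``(pdb_text, manifest)``.

    The manifest records, from brute-force scans on the re-parsed text:
    per-residue ground-truth contact labels, the residue adjacency at
    ``spec.adjacency_cutoff``, the ligand geometry and the target indices.
    """
    rng = np.random.default_rng(spec.seed)
    ca, chain_of = _ca_trace(spec, rng)
    n = len(ca)

    targets: list[int] = []
    if spec.ligand == "placed":
        if spec.ligand_targets is None or spec.ligand_targets == "interface":
            targets = _auto_patch(ca, chain_of, spec, rng)
        else:
            targets = sorted(int(i) for i in spec.ligand_targets)
            if targets and (targets[0] < 0 or targets[-1] >= n):
                raise ValueError("ligand target index out of range")

    # residue types: binding-site residues are polar/charged, background is
    # apolar with a fraction of scattered polar decoys.  Draw every per-index
    # choice once so the assignment is a pure function of the site set.
    polar_pick = rng.integers(0, len(POLAR_RESIDUES), size=n)
    apolar_pick = rng.integers(0, len(APOLAR_RESIDUES), size=n)
    decoy = rng.random(n) < spec.polar_decoy_fraction

    def _types_for(site: set[int]) -> list[str]:
        return [
            POLAR_RESIDUES[polar_pick[i]] if (i in site or decoy[i])
            else APOLAR_RESIDUES[apolar_pick[i]]
            for i in range(n)
        ]

    t, u, w = _frames(ca, chain_of)

    def _build(site: set[int]) -> Structure:
        res_types = _types_for(site)
        residues = []
        serial = 1
        seq_in_chain: dict[str, int] = {}
        for i in range(n):
            cid = chain_of[i]
            seq_in_chain[cid] = seq_in_chain.get(cid, 0) + 1
            res, serial = _build_residue(
                cid, seq_in_chain[cid], res_types[i],
                ca[i], t[i], u[i], w[i], serial,
            )
            residues.append(res)
        structure = Structure(spec.structure_id, residues=residues)
        if spec.ligand == "placed" and targets:
            structure.ligands.append(_place_ligand(residues, targets, spec))
        return structure

    # two passes: the ligand placed against the requested patch may touch a
    # few extra residues; those belong to the planted site and must carry the
    # site composition, so rebuild with the scanned contact set
    structure = _build(set(targets))
    if spec.ligand == "placed" and targets:
        contacts = {i for i, lab in enumerate(_scan_labels(structure)) if lab}
        if contacts != set(targets):
            structure = _build(set(targets) | contacts)

    pdb_text = structure_to_pdb_string(structure)
    parsed = parse_pdb(pdb_text, structure_id=spec.structure_id)
    labels = _scan_labels(parsed) if parsed.ligands else [0] * n

    if spec.strict_targets:
        positives = sorted(i for i, lab in enumerate(labels) if lab)
        if positives != targets:
            raise FixturePlacementError(
                f"targets too dispersed: wanted {targets}, ligand contacts "
                f"{positives}"
            )

    manifest = {
        "structure_id": spec.structure_id,
        "seed": spec.seed,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "residues": [
            {"index": i, "chain": r.chain_id, "resnum": r.seq_number,
             "icode": r.insertion_code, "restype": r.res_type}
            for i, r in enumerate(parsed.residues)
        ],
        "labels": labels,
        "adjacency": _scan_adjacency(parsed, spec.adjacency_cutoff),
        "adjacency_cutoff": spec.adjacency_cutoff,
        "targets": targets,
        "ligand": {
            "het_code": spec.het_code,
            "atoms": [
                {"name": a.name, "element": a.element,
                 "coords": [round(c, 3) for c in a.coords]}
                for lig in parsed.ligands for a in lig.atoms
            ],
        } if parsed.ligands else None,
        "sequences": chain_sequences(parsed),
    }
    return pdb_text, manifest


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``<id>.pdb`` and ``<id>.manifest.json`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_text, manifest = generate_structure(spec)
    pdb_path = out_dir / f"{spec.structure_id}.pdb"
    man_path = out_dir / f"{spec.structure_id}.manifest.json"
    pdb_path.write_text(pdb_text)
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return pdb_path, man_path


def generate_template_store(
    n_templates: int,
    out_dir: str | Path,
    base_spec: FixtureSpec | None = None,
    seed: int = 0,
) -> Path:
    """Write an on-disk template store: one directory per bound, labelled,
    sequenced template plus a root manifest with all ground truth."""
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    base_spec = base_spec or FixtureSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    child_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_templates)]
    template_ids = []
    ground_truth = {}
    for i, child_seed in enumerate(child_seeds):
        tid = f"tmpl_{i:03d}"
        spec = FixtureSpec(
            **{**asdict(base_spec), "seed": child_seed, "structure_id": tid,
               "ligand": "placed", "strict_targets": False,
               "ligand_targets": None
               if base_spec.ligand_targets != "interface" else "interface"},
        )
        tdir = out_dir / tid
        tdir.mkdir(exist_ok=True)
        pdb_text, manifest = generate_structure(spec)
        (tdir / "structure.pdb").write_text(pdb_text)
        lines = ["chain,resnum,icode,label"]
        for res, lab in zip(manifest["residues"], manifest["labels"]):
            lines.append(f"{res['chain']},{res['resnum']},{res['icode']},{lab}")
        (tdir / "labels.csv").write_text("\n".join(lines) + "\n")
        (tdir / "ligands.tsv").write_text(
            f"het_code\tchain\tseqnum\n{spec.het_code}\t"
            f"{manifest['residues'][manifest['targets'][0]]['chain']}\t900\n"
        )
        seq = "".join(manifest["sequences"].values())
        (tdir / "sequence.fasta").write_text(f">{tid}\n{seq}\n")
        template_ids.append(tid)
        ground_truth[tid] = manifest
    (out_dir / "manifest.json").write_text(
        json.dumps(
            {"templates": template_ids, "seed": seed,
             "ground_truth": ground_truth},
            indent=1, sort_keys=True,
        )
    )
    return out_dir
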