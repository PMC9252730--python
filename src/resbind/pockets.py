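"""Pocket clustering and binding-site similarity.

The classifier is residue-centric; to give its output a pocket-centric
reading, predicted binding residues are grouped with DBSCAN on their
representative coordinates (CA when present, else the heavy-atom centroid).
Dense groups become candidate pockets, sparse residues are noise.

Each pocket is then compared against the template store's known binding
sites with a distance-multiset similarity: all pairwise distances between
residue representatives are binned by the unordered pair of residue chemical
categories, each bin's sorted list is greedily matched against the
counterpart within a tolerance, and the score is the matched fraction
(1 for identical sites, 0 for category-disjoint ones).  Since similar sites
tend to bind similar ligands, the best-scoring template sites yield a ranked
list of candidate ligands per pocket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.cluster import DBSCAN

from .structure import Residue, ResidueKey, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_PRECEDENCE",
    "Pocket",
    "SiteSignature",
    "SiteRecord",
    "LigandSuggestion",
    "representative_coord",
    "residue_category",
    "cluster_predictions",
    "pocket_center",
    "site_signature",
    "signature_from_record",
    "site_similarity",
    "make_site_record",
    "suggest_ligands",
]

#: residue category = first of these with any atom of that class in the residue
CATEGORY_PRECEDENCE = ("positive", "negative", "aromatic", "polar", "hydrophobic")


def representative_coord(residue: Residue) -> np.ndarray:
    """CA coordinate when present, else the heavy-atom centroid."""
    ca = residue.get_atom("CA")
    if ca is not None and not ca.is_hydrogen:
        return np.asarray(ca.coords, dtype=float)
    heavy = residue.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.key} has no heavy atoms")
    return np.mean([a.coords for a in heavy], axis=0)


def residue_category(residue: Residue) -> str:
    """Dominant chemical category of a residue, by fixed precedence:
    positive > negative > aromatic > polar (donor or acceptor) >
    hydrophobic > other."""
    present: set[str] = set()
    for atom in residue.heavy_atoms():
        present |= atom.classes
    if "donor" in present or "acceptor" in present:
        present.add("polar")
    for cat in CATEGORY_PRECEDENCE:
        if cat in present:
            return cat
    return "other"


@dataclass
class Pocket:
    pocket_id: int
    residue_keys: list[ResidueKey]
    coords: np.ndarray  # (n, 3) representative coordinates, aligned with keys

    @property
    def center(self) -> np.ndarray:
        return pocket_center(self)


@dataclass(frozen=True)
class SiteSignature:
    """Sorted pairwise-distance lists keyed by unordered category pair."""

    lists: dict[tuple[str, str], np.ndarray]
    n_pairs: int

    @property
    def total(self) -> int:
        return self.n_pairs


@dataclass
class SiteRecord:
    """A known binding site from the template store, ready for comparison."""

    site_id: str
    het_code: str
    residue_keys: list[ResidueKey]
    coords: np.ndarray
    categories: tuple[str, ...]


@dataclass(frozen=True)
class LigandSuggestion:
    het_code: str
    site_id: str
    score: float


# ---------------------------------------------------------------------------
# clustering


def cluster_predictions(
    predictions,
    structure: Structure,
    eps: float = 6.0,
    min_samples: int = 3,
) -> tuple[list[Pocket], list[ResidueKey]]:
    """DBSCAN over the representative coordinates of predicted-positive
    residues (standard semantics; a point's own count is included in
    ``min_samples``).  Returns (pockets, noise residues).

    Residues are processed in structure order, which makes border-point
    assignment deterministic.
    """
    resmap = structure.residue_map()
    order = {res.key: i for i, res in enumerate(structure.residues)}
    positive = sorted(
        (p.residue_key for p in predictions if p.label), key=order.__getitem__
    )
    if not positive:
        return [], []
    coords = np.array([representative_coord(resmap[k]) for k in positive])
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    pockets: list[Pocket] = []
    noise: list[ResidueKey] = []
    id_remap: dict[int, int] = {}
    members: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            noise.append(positive[i])
            continue
        if lab not in id_remap:
            id_remap[lab] = len(id_remap)
        members.setdefault(id_remap[lab], []).append(i)
    for pid in sorted(members):
        idx = members[pid]
        pockets.append(
            Pocket(
                pocket_id=pid,
                residue_keys=[positive[i] for i in idx],
                coords=coords[idx],
            )
        )
    return pockets, noise


def pocket_center(pocket: Pocket, structure: Structure | None = None) -> np.ndarray:
    """Arithmetic mean of the member representative coordinates."""
    if structure is not None:
        resmap = structure.residue_map()
        coords = np.array(
            [representative_coord(resmap[k]) for k in pocket.residue_keys]
        )
    else:
        coords = pocket.coords
    if len(coords) == 0:
        raise ValueError("empty pocket has no center")
    return np.mean(coords, axis=0)


# ---------------------------------------------------------------------------
# site signatures and similarity


def _signature(coords: np.ndarray, categories: tuple[str, ...]) -> SiteSignature:
    if len(coords) < 2:
        raise ValueError("a site signature needs at least 2 residues")
    bins: dict[tuple[str, str], list[float]] = {}
    n = 0
    for i, j in combinations(range(len(coords)), 2):
        key = tuple(sorted((categories[i], categories[j])))
        bins.setdefault(key, []).append(float(np.linalg.norm(coords[i] - coords[j])))
        n += 1
    return SiteSignature(
        lists={k: np.sort(np.asarray(v)) for k, v in bins.items()},
        n_pairs=n,
    )


def site_signature(
    residue_keys: list[ResidueKey], structure: Structure
) -> SiteSignature:
    """Distance-multiset signature of a residue set (categories from the
    assigned atom classes; run annotation/featurization first)."""
    resmap = structure.residue_map()
    residues = [resmap[k] for k in residue_keys]
    coords = np.array([representative_coord(r) for r in residues])
    cats = tuple(residue_category(r) for r in residues)
    return _signature(coords, cats)


def make_site_record(
    structure: Structure,
    residue_keys: list[ResidueKey],
    het_code: str,
    site_id: str | None = None,
) -> SiteRecord:
    resmap = structure.residue_map()
    residues = [resmap[k] for k in residue_keys]
    return SiteRecord(
        site_id=site_id or f"{structure.structure_id}:{het_code}",
        het_code=het_code,
        residue_keys=list(residue_keys),
        coords=np.array([representative_coord(r) for r in residues]),
        categories=tuple(residue_category(r) for r in residues),
    )


def signature_from_record(record: SiteRecord) -> SiteSignature:
    return _signature(record.coords, record.categories)


def _greedy_matches(a: np.ndarray, b: np.ndarray, tol: float) -> int:
    """Matches between two sorted lists within ``tol``, each element used once
    (two-pointer greedy; optimal for interval matching on sorted lists)."""
    i = j = matched = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matched


def site_similarity(a: SiteSignature, b: SiteSignature, tol: float = 0.5) -> float:
    """Matched fraction of pairwise distances: 2·matches / (|a| + |b|)."""
    matches = 0
    for key in set(a.lists) & set(b.lists):
        matches += _greedy_matches(a.lists[key], b.lists[key], tol)
    denom = a.n_pairs + b.n_pairs
    return 2.0 * matches / denom if denom else 0.0


# ---------------------------------------------------------------------------
# ligand suggestion


def suggest_ligands(
    pockets: list[Pocket],
    store_sites: list[SiteRecord],
    structure: Structure,
    top_k: int = 5,
    tol: float = 0.5,
) -> dict[int, list[LigandSuggestion]]:
    """Rank candidate ligands per pocket by the best site-similarity score of
    any template site bearing that ligand."""
    if not store_sites:
        logger.warning("template store has no site records; no suggestions")
        return {p.pocket_id: [] for p in pockets}
    out: dict[int, list[LigandSuggestion]] = {}
    for pocket in pockets:
        if len(pocket.residue_keys) < 2:
            logger.warning("pocket %d too small for a signature", pocket.pocket_id)
            out[pocket.pocket_id] = []
            continue
        psig = site_signature(pocket.residue_keys, structure)
        best: dict[str, LigandSuggestion] = {}
        for site in store_sites:
            score = site_similarity(psig, signature_from_record(site), tol=tol)
            cur = best.get(site.het_code)
            if cur is None or score > cur.score:
                best[site.het_code] = LigandSuggestion(site.het_code, site.site_id, score)
        ranked = sorted(best.values(), key=lambda s: (-s.score, s.het_code))
        out[pocket.pocket_id] = ranked[:max(top_k, 0)]
    return out
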