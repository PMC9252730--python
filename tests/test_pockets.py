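"""DBSCAN pocket clustering and distance-multiset site similarity.

Oracles: a hand-written density-reachability BFS for the clustering, and an
exhaustive maximum bipartite matching for the greedy distance alignment.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resbind import chem, pockets as pk
from resbind.model import Prediction
from resbind.structure import parse_pdb


def _fake_predictions(structure, positive_keys):
    positive = set(positive_keys)
    return [
        Prediction(r.key, 1.0 if r.key in positive else 0.0, r.key in positive)
        for r in structure.residues
    ]


def _point_structure(points):
    """One GLY CA per point, numbered in order."""
    lines = []
    for i, (x, y, z) in enumerate(points):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  GLY A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    return parse_pdb("\n".join(lines) + "\nEND\n")


def _dbscan_oracle(points, eps, min_samples):
    """Brute-force density reachability: core points, BFS over cores, then
    border assignment.  Returns labels with -1 for noise."""
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in sorted(neighbors[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
        cluster += 1
    return labels


def test_no_positives_no_pockets(helix_bundle):
    _, _, structure = helix_bundle
    pockets, noise = pk.cluster_predictions(
        _fake_predictions(structure, []), structure
    )
    assert pockets == [] and noise == []


def test_two_separated_groups_form_two_pockets():
    group_a = [(3.0 * i, 0.0, 0.0) for i in range(5)]
    group_b = [(3.0 * i, 40.0, 0.0) for i in range(5)]
    structure = _point_structure(group_a + group_b)
    preds = _fake_predictions(structure, [r.key for r in structure.residues])
    pockets, noise = pk.cluster_predictions(structure=structure,
                                            predictions=preds,
                                            eps=6.0, min_samples=3)
    assert len(pockets) == 2 and noise == []
    assert sorted(len(p.residue_keys) for p in pockets) == [5, 5]


def test_sparse_positives_are_noise():
    structure = _point_structure([(0, 0, 0), (50, 0, 0)])
    preds = _fake_predictions(structure, [r.key for r in structure.residues])
    pockets, noise = pk.cluster_predictions(structure=structure,
                                            predictions=preds,
                                            eps=6.0, min_samples=3)
    assert pockets == [] and len(noise) == 2


def test_clustering_matches_density_reachability_oracle(rng):
    from collections import defaultdict

    for _trial in range(5):
        points = rng.uniform(0, 30, size=(60, 3))
        n = len(points)
        structure = _point_structure(points)
        preds = _fake_predictions(structure, [r.key for r in structure.residues])
        pockets, noise = pk.cluster_predictions(
            preds, structure, eps=5.0, min_samples=3
        )
        oracle = _dbscan_oracle(points, eps=5.0, min_samples=3)
        key_order = [r.key for r in structure.residues]
        ours = {
            k: p.pocket_id for p in pockets for k in p.residue_keys
        }
        # noise agrees exactly
        assert set(noise) == {key_order[i] for i, l in enumerate(oracle) if l == -1}
        # partitions restricted to core points agree exactly
        dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        core = [int(np.sum(dist[i] <= 5.0)) >= 3 for i in range(n)]
        oracle_part = defaultdict(set)
        ours_part = defaultdict(set)
        for i in range(n):
            if core[i]:
                oracle_part[oracle[i]].add(i)
                ours_part[ours[key_order[i]]].add(i)
        assert {frozenset(v) for v in oracle_part.values()} == \
            {frozenset(v) for v in ours_part.values()}
        # every border point joined a cluster whose core reaches it
        for i in range(n):
            if not core[i] and key_order[i] in ours:
                members = [
                    j for j in range(n)
                    if core[j] and ours.get(key_order[j]) == ours[key_order[i]]
                ]
                assert any(dist[i, j] <= 5.0 for j in members)


def test_merge_monotonicity_in_eps(rng):
    points = rng.uniform(0, 25, size=(50, 3))
    structure = _point_structure(points)
    preds = _fake_predictions(structure, [r.key for r in structure.residues])
    small, _ = pk.cluster_predictions(preds, structure, eps=4.0, min_samples=3)
    large, _ = pk.cluster_predictions(preds, structure, eps=6.0, min_samples=3)
    big_sets = [set(p.residue_keys) for p in large]
    for pocket in small:
        covering = [b for b in big_sets if set(pocket.residue_keys) <= b]
        assert len(covering) == 1


def test_pocket_center_midpoint_and_equivariance():
    structure = _point_structure([(0, 0, 0), (2, 0, 0)])
    pocket = pk.Pocket(0, [r.key for r in structure.residues],
                       np.array([[0.0, 0, 0], [2.0, 0, 0]]))
    np.testing.assert_allclose(pk.pocket_center(pocket), [1.0, 0.0, 0.0])
    shifted = pk.Pocket(0, pocket.residue_keys, pocket.coords + np.array([5, 1, -2]))
    np.testing.assert_allclose(
        pk.pocket_center(shifted), np.array([1.0, 0.0, 0.0]) + [5, 1, -2]
    )
    with pytest.raises(ValueError):
        pk.pocket_center(pk.Pocket(1, [], np.zeros((0, 3))))


# ---------------------------------------------------------------------------
# site signatures


def test_signature_counting_single_category():
    structure = _point_structure([(0, 0, 0), (3, 0, 0), (0, 4, 0)])
    keys = [r.key for r in structure.residues]
    sig = pk.site_signature(keys, structure)
    assert sig.n_pairs == 3
    assert len(sig.lists) == 1  # untyped GLY CA atoms: one category pair
    (dists,) = sig.lists.values()
    np.testing.assert_allclose(dists, sorted([3.0, 4.0, 5.0]))


def test_signature_total_pairs(helix_bundle, rng):
    _, _, structure = helix_bundle
    chem.assign_atom_classes(structure)
    keys = [r.key for r in structure.residues]
    for n in (2, 5, 9):
        chosen = [keys[i] for i in rng.choice(len(keys), size=n, replace=False)]
        sig = pk.site_signature(chosen, structure)
        assert sum(len(v) for v in sig.lists.values()) == n * (n - 1) // 2
    with pytest.raises(ValueError):
        pk.site_signature(keys[:1], structure)


def test_signature_invariant_under_rotation(helix_bundle):
    import copy
    _, _, structure = helix_bundle
    chem.assign_atom_classes(structure)
    keys = [r.key for r in structure.residues][:6]
    sig = pk.site_signature(keys, structure)
    rotated = copy.deepcopy(structure)
    theta = 0.9
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    for res in rotated.residues:
        for atom in res.atoms:
            atom.coords = tuple(rot @ np.asarray(atom.coords))
    chem.assign_atom_classes(rotated)
    sig2 = pk.site_signature(keys, rotated)
    assert set(sig.lists) == set(sig2.lists)
    for key in sig.lists:
        np.testing.assert_allclose(sig.lists[key], sig2.lists[key], atol=1e-9)


def _matching_oracle(a, b, tol):
    """Exhaustive maximum bipartite matching within tol (lists <= 10):
    every injective assignment of the smaller list into the larger."""
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for assignment in itertools.permutations(range(len(large)), len(small)):
        matched = sum(
            1 for i, j in enumerate(assignment)
            if abs(small[i] - large[j]) <= tol
        )
        best = max(best, matched)
    return best


@given(
    a=st.lists(st.floats(0, 20), min_size=1, max_size=6),
    b=st.lists(st.floats(0, 20), min_size=1, max_size=6),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_greedy_matching_equals_exhaustive(a, b):
    a, b = np.sort(a), np.sort(b)
    greedy = pk._greedy_matches(a, b, tol=0.5)
    assert greedy == _matching_oracle(list(a), list(b), 0.5)


def test_similarity_identity_and_disjoint():
    coords = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)
    sig = pk._signature(coords, ("polar", "polar", "polar"))
    assert pk.site_similarity(sig, sig) == 1.0
    other = pk._signature(coords, ("hydrophobic", "hydrophobic", "hydrophobic"))
    assert pk.site_similarity(sig, other) == 0.0


def test_similarity_is_symmetric(rng):
    cats = ("polar", "positive", "hydrophobic")
    for _ in range(10):
        ca = rng.uniform(0, 15, size=(5, 3))
        cb = rng.uniform(0, 15, size=(4, 3))
        sa = pk._signature(ca, tuple(rng.choice(cats, 5)))
        sb = pk._signature(cb, tuple(rng.choice(cats, 4)))
        assert pk.site_similarity(sa, sb) == pytest.approx(
            pk.site_similarity(sb, sa)
        )


# ---------------------------------------------------------------------------
# ligand suggestion


def test_self_match_ranks_first(helix_bundle):
    _, manifest, structure = helix_bundle
    chem.assign_atom_classes(structure)
    keys = [r.key for r in structure.residues]
    site_keys = [keys[i] for i, l in enumerate(manifest["labels"]) if l]
    pocket = pk.Pocket(
        0, site_keys,
        np.array([pk.representative_coord(structure.residue_map()[k])
                  for k in site_keys]),
    )
    self_site = pk.make_site_record(structure, site_keys, "XYZ")
    decoy_keys = [k for k in keys if k not in site_keys][:6]
    decoy = pk.make_site_record(structure, decoy_keys, "AAA")
    suggestions = pk.suggest_ligands([pocket], [decoy, self_site], structure)
    ranked = suggestions[0]
    assert ranked[0].het_code == "XYZ"
    assert ranked[0].score == pytest.approx(1.0)


def test_jittered_copy_outranks_random_templates(rng):
    points = rng.uniform(0, 12, size=(6, 3))
    structure = _point_structure(points)
    keys = [r.key for r in structure.residues]
    pocket = pk.Pocket(0, keys, points.copy())
    jitter = points + rng.uniform(-0.1, 0.1, size=points.shape)
    jittered = pk.SiteRecord("jit", "GOOD", keys, jitter, ("other",) * 6)
    randoms = [
        pk.SiteRecord(f"r{i}", f"R{i:02d}", keys,
                      rng.uniform(0, 40, size=(6, 3)), ("other",) * 6)
        for i in range(5)
    ]
    suggestions = pk.suggest_ligands([pocket], [jittered] + randoms, structure,
                                     top_k=6)
    assert suggestions[0][0].het_code == "GOOD"
    assert suggestions[0][0].score > max(s.score for s in suggestions[0][1:])


def test_top_k_zero_and_empty_store(helix_bundle):
    _, _, structure = helix_bundle
    pocket = pk.Pocket(0, [structure.residues[0].key, structure.residues[1].key],
                       np.zeros((2, 3)))
    assert pk.suggest_ligands([pocket], [], structure) == {0: []}
    site = pk.make_site_record(structure, pocket.residue_keys, "LG1")
    assert pk.suggest_ligands([pocket], [site], structure, top_k=0) == {0: []}
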