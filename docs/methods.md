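# Methods

## Model and assumptions

resbind treats binding-site identification as per-residue binary
classification. The central assumption is that a residue's propensity to
contact a ligand is determined by the physicochemical composition of its
local spatial environment — not by its sequence position or by global fold
features. The environment is summarised at three levels (solvent
accessibility and cysteine identity; atom-class counts; non-covalent
interaction counts) for the residue itself and, averaged, for its first and
second contact shells. All geometry enters only through pairwise distances,
so the encoding is invariant under rigid motions of the structure (the
solvent-accessibility term is invariant up to sphere-sampling noise; see
"Numerical choices").

A second assumption is that labelled examples similar to the query exist in
a local template store: training is per query, from templates matched by
global sequence identity. The store layout (structure + per-residue labels
+ ligand identities + sequence) mirrors what a BioLip-style curated
database provides; nothing is fetched from the network.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| contact-graph cutoff | 6.0 | Å | min heavy-atom distance joining residues in one contact shell |
| hydrogen-bond window | 2.0–3.9 | Å | donor×acceptor distance convention |
| salt-bridge / repulsive window | 2.0–6.0 | Å | charged-group contact convention |
| hydrophobic window | 2.0–4.5 | Å | apolar carbon contact convention |
| aromatic-stacking window | 1.5–3.5 | Å | atom–atom between ring atoms |
| disulfide window | 1.8–2.8 | Å | S–S covalent bond length + slack |
| SASA probe radius / points | 1.4 / 960 | Å / – | water probe; sampling error ≪ 0.02 RSA |
| binding-label margin | 0.5 | Å | added to the vdW-radius sum (BioLip-style contact rule) |
| identity window | 0.0–0.95 | – | upper bound excludes the query and near-duplicates |
| bags × trees | 10 × 100 | – | balanced undersampling; enough trees for stable probabilities |
| decision threshold | 0.5 | – | exposed; precision/recall trade-off belongs to the user |
| DBSCAN eps / min_samples | 6.0 / 3 | Å / – | merges residues within one contact shell |
| similarity tolerance | 0.5 | Å | distance-match slack in site comparison |
| DCA hit threshold | 4.0 | Å | community convention for pocket localisation |

All are configurable through the library API, a YAML config file, or CLI
flags; the effective configuration is echoed into every output directory.

## Interaction typing

Atom classes come from a shipped, editable `(residue, atom name)` table
covering the 20 standard amino acids (backbone N donor, backbone O
acceptor, aliphatic carbons hydrophobic, histidine ring nitrogens
aromatic+donor+acceptor, arginine guanidinium nitrogens positive+donor,
carboxylate oxygens negative+acceptor, and so on). A pair of heavy atoms in
different residues yields one interaction per type whose class requirement
and distance window both hold — a pair may satisfy several types at once.
Pairs of backbone atoms (N, CA, C, O) in sequence-adjacent residues of the
same chain are excluded as covalent neighborhood; side-chain pairs of
adjacent residues are kept. Hydrogen-bond geometry is distance-and-type
only (no angles, no hydrogen placement), and aromatic stacking uses
atom–atom rather than ring-centroid distances: the criteria are
deliberately coordinate-light, and all thresholds are parametric.

## The balanced ensemble

Binding residues are typically 5–15% of a structure. Each of `n_bags` bags
keeps every minority-class row and draws, without replacement, an
equal-size sample of majority rows (bag seed = top-level seed + bag index),
then fits an Extremely Randomized Trees classifier. Confidence is the mean
positive-class probability over all trees of all bags, which makes the
ensemble a proper mixture: duplicating bags leaves confidences unchanged.
Feature importances are averaged over bags and renormalised to sum to 1.
Every random draw descends from one top-level seed, so identical seeds give
bit-identical bag compositions, predictions and reports.

## Pockets and site similarity

Predicted residues are clustered with standard DBSCAN on representative
coordinates (CA, else the heavy-atom centroid); residues are processed in
structure order, making border-point assignment deterministic. Site
comparison uses a residue-level distance-multiset signature: every pairwise
distance between residue representatives is binned by the unordered pair of
residue categories (precedence positive > negative > aromatic > polar >
hydrophobic > other, from the assigned atom classes), each bin is sorted,
bins are aligned greedily within a 0.5 Å tolerance (greedy-on-sorted equals
optimal interval matching, verified against exhaustive matching in tests),
and the score is the matched fraction of pairs. This residue-granularity
variant of distance-signature site comparison trades the atom-triplet
detail of classical implementations for speed and robustness at the
granularity the pipeline actually clusters.

## Synthetic data: what it does and does not emulate

The generator produces PDB-format toy structures — helical spirals, cubic
lattices or self-avoiding coils of 60 residues by default — with real atom
names (so the typing table covers every atom), a placed 3–6-atom
pseudo-ligand, and a manifest of ground truth computed by brute-force
distance scans on the re-parsed text. The planted binding site emulates the
statistical signature of real sites: a compact surface patch of
polar/charged residues (ASP, GLU, LYS, ARG, HIS, SER, ASN) on an otherwise
apolar background (ALA, LEU, VAL, ILE, PHE, MET, GLY), with 10% of
background residues drawn polar as scattered decoys. The decoys make
residue identity alone insufficient — the classifier must use the shell
descriptors to tell a clustered polar patch from an isolated polar residue,
which is precisely the method's premise. Ligand contact labels follow the
vdW-sum + 0.5 Å rule, and contact residues are assigned the site
composition so labels and composition are consistent.

What the fixtures do **not** emulate: realistic backbone geometry,
rotamers, packing density, sequence–structure correlation, binding sites
with mixed polarity, and the label noise of curated databases. Passing
tests therefore demonstrate that the machinery is correct and that the
pipeline recovers a planted, learnable signal at toy scale — they do not
certify benchmark-level accuracy on real proteins, which depends on a real
template database.

Default study conditions for the recovery experiments: a 20-template store,
held-out 60-residue queries, 5-residue requested patch at 3.0 Å contact
distance. Problem sizes were chosen so the complete suite and the
acceptance script each finish in well under a minute of compute per stage.

## Numerical choices

* **SASA** is computed by Shrake–Rupley sphere sampling (960 points, probe
  1.4 Å) over heavy atoms; RSA is clamped to [0, 1] after normalising by
  theoretical maximum areas (Tien et al. 2013), with 200 Å² used for
  residue types missing from the table. The sampling sphere has a fixed
  orientation, so RSA varies by up to ~0.02 under rotation of the
  structure; all other descriptors are exactly invariant.
* **Altlocs** resolve to the highest-occupancy conformer, ties broken by
  altloc letter; multi-model files use the first model. These are this
  package's conventions for cases the underlying data model leaves open.
* **MCC** returns 0 whenever a marginal of the confusion table is empty;
  dataset aggregation is the unweighted per-structure mean (a pooled mode
  exists behind a flag).
* **Degenerate inputs**: empty structures and water-only files are parse
  errors; residues without heavy atoms are excluded from RSA and the
  feature matrix with a warning; empty shells contribute zero blocks rather
  than sentinels, keeping the matrix dense.
* **Ties** are broken deterministically throughout: feature-importance ties
  by column order, ligand-suggestion ties lexicographically by HET code,
  template ties by store order.

## Design choices made where the design was open

* Shells are defined on a plain heavy-atom distance contact graph rather
  than on the detected-interaction graph; an `interaction` neighbor mode is
  exposed but not the default, since a distance criterion makes inter-chain
  shells automatic and is robust to typing gaps.
* One model is trained per query from its matched templates (rather than
  one global model); this keeps the training set relevant to the query fold
  family and makes leakage control explicit via the identity window.
* Balancing undersamples the majority class 1:1 without replacement;
  oversampling the minority was rejected to keep bags independent and
  cheap.
* Interaction counts of a residue include partners outside its shells: the
  descriptors report the residue's complete interaction load.
* Metal ions are treated as ligands (when not on the exclusion list), never
  as typed protein atoms.

## Known limitations

* The PDB dialect only (no mmCIF); structures with duplicate residue
  identifiers are rejected.
* No angle terms in hydrogen-bond or stacking detection; no ring centroids.
* Sequence matching is global pairwise alignment — slow for very large
  stores (a k-mer prefilter would be the natural extension).
* The per-query training design means prediction quality degrades when the
  store holds nothing similar to the query; the explicit `NoTemplatesError`
  surfaces this instead of guessing.
* Binding sites smaller than DBSCAN's `min_samples` appear as noise, not
  pockets (the residue-level predictions still report them).
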