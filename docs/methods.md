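# Methods

## Contact model

A protein complex is reduced to the heavy atoms (C, N, O, S) of the 20
standard residues, model 1 only, alternate locations collapsed to the
highest-occupancy conformer. Each atom carries a van der Waals radius; the
default table is element-based (C 1.70, N 1.55, O 1.52, S 1.80 Å) and can
be replaced by a per-(residue, atom) TSV, because the contact definition
depends on radii only through the surface-distance offset
d(i, j) = ‖x_i − x_j‖ − (r_i + r_j).

A pair of atoms on opposite sides of the interface is graded through three
nested requirements:

1. **distance**: d(i, j) ≤ t_max. Default t_max = 3.3 Å — the diameter of
   a water molecule (2.8 Å) plus 0.5 Å — i.e. a gap wide enough for a
   solvent molecule disqualifies direct contact.
2. **Voronoi**: i and j share a Voronoi facet of the *entire* complex,
   computed as Delaunay adjacency of the unweighted atom centers.
3. **beta skeleton with β = 1 (Gabriel graph)**: no third atom's center
   lies strictly inside the open ball with segment ij as diameter. All
   atoms of the complex are admissible blockers; interface pruning happens
   after flagging, never before.

Each contact records which definitions it satisfies, so the three contact
sets come from one pass and the chain beta ⊆ Voronoi ⊆ distance is
structural. General β ≠ 1 skeletons are deliberately not implemented.

### Numerical conventions

* **Open-ball boundary.** A blocker exactly on the Gabriel sphere does not
  break the contact; the test is ‖k − mid‖ < ‖i − j‖/2 − ε with
  ε = 10⁻⁹ Å. This makes degenerate lattices deterministic.
* **Degenerate point sets.** Voronoi adjacency of a lower-dimensional
  point set is computed exactly in its affine hull: all pairs for an
  affinely independent set, consecutive pairs for collinear points, a 2-D
  Delaunay triangulation for coplanar sets. Cospherical degeneracies in
  full 3-D fall back to qhull's joggled input; if that also fails the
  detector raises and points to the brute-force path. Since the midpoint
  of an empty diameter ball is equidistant from, and strictly closest to,
  its endpoints, a Gabriel edge always implies Voronoi adjacency — the
  brute-force detector uses this to flag Voronoi on beta contacts even
  when no triangulation exists.
* **Production shortcut.** The fast path evaluates the Gabriel test only
  on Delaunay edges that pass the distance filter (Gabriel ⊆ Delaunay in
  general position). Its equivalence with the exhaustive oracle — every
  candidate pair against every possible blocker, no triangulation — is
  asserted on 100 seeded random packings up to 500 atoms in the test
  suite and measured again by the acceptance script.
* **Bin edges.** ACV3 surface-distance bins are left-open/right-closed:
  ≤ 0.5, (0.5, 1.9], (1.9, 3.3]; a contact at exactly 0.5 or 1.9 Å lands
  in the nearer bin. Negative surface distances (overlapping spheres)
  belong to the ≤ 0.5 bin.
* **Disulfides.** Inter-side CYS SG–SG pairs with center distance
  strictly < 2.6 Å fill the final vector slot only — they are covalent
  bridges, so they are not double-counted as an S–S type-pair contact.

## Atomic typing

The 12 atomic types group standard-residue heavy atoms by element, heavy
coordination and bonded hydrogens: C_4H_3, C_4H_2, C_4H_1, C_3(S_2)H_0,
C_3(S_2)H_1, N_3H_0, N_3H_1, N_3H_2, N_4H_3/2+, O_1H_0, O_1H_0−, O_2H_1.
The shipped TSV covers every heavy atom of the 20 residues plus OXT.
Choices that a different convention could make otherwise — and which the
editable table exists to absorb — are: HIS ND1 → N_3H_0 and NE2 → N_3H_1
(fixed assignment, no protonation inference); ARG NH1/NH2 in the charged
class N_4H_3/2+; MET SD with the H_0 and CYS SG with the H_1
sulfur-bearing class. Typing is a pure function of (residue, atom); atoms
without an entry are marked UNTYPED and their contacts are skipped with a
logged count.

## Classifier

The classifier is a linear soft-margin SVM (libsvm backend) on
min-max-scaled features, scaling fitted on training rows only and frozen
into the model. The paper-silent hyperparameters are fixed as: C = 1 by
default (a grid can be swept through the CLI); homodimer = +1 so recall is
dimer recall. SVM-RFE removes exactly one feature per step — the one with
the smallest squared weight, so zero-variance features leave first — and
records stratified 5-fold CV accuracy at every subset size; the selected
subset maximizes CV accuracy with ties broken toward fewer features.
Evaluation is leave-one-out on a learning set (n single-holdout rounds,
metrics pooled) or a frozen model on an independent set. MCC with a zero
denominator is reported as 0 with an explicit flag; an empty class makes
the corresponding rate NaN with a warning rather than an error.

Decision trees for rule extraction use entropy splits, minimum leaf size
2, on the RFE-selected count features; because inputs are integer counts,
split points are printed as integer thresholds (`count > t`). Rules are
serialized as indented branch lines ending in a class label and
`(samples/misclassified)`.

## Synthetic data

The generators define the desk-scale study conditions:

* **Planar fixture** — 7 fixed atoms whose distance/Voronoi/beta sets are
  enumerated analytically in code, including one pair whose Gabriel ball
  contains a blocker 0.71 Å from its midpoint: a Voronoi contact that is
  not a beta contact.
* **Random packings** — hard-sphere rejection sampling (attempt cap 10⁴)
  at ≥ 2.8 Å center separation, ~50 Å³ per atom, two sides facing across
  a plane with a 1 Å gap; deterministic per seed; writable as valid PDB.
  These packings exercise the geometry, not protein physics: atoms are
  unbonded spheres at roughly a third of protein-core density, so
  synthetic interfaces are sparser and their beta/distance contact ratio
  far higher than in real structures. Oracle-equivalence and invariance
  results transfer to real inputs; absolute contact ratios do not.
* **Planted ACV datasets** — integer count matrices with Poisson noise:
  background slots have mean 2 in both classes (a typical occupancy of a
  mid-frequency ACV3 slot), and 5 informative slots gain a 2-standard-
  deviation mean shift in the positive class at n = 100 per class. These
  stand in for real homodimer/crystal-packing feature matrices in
  classifier tests; they model class separation and count noise but not
  inter-feature correlation or interface-size confounding, so they
  validate the selection/evaluation machinery rather than biological
  discriminability.

Problem sizes used by the shipped checks — 100 fixtures up to 500 atoms
for oracle equivalence, 20 (tests) or 10 (acceptance script) planted
datasets of 200 × 235 for RFE recovery — keep a full run in the
single-digit minutes on one core.

## Known limitations

Interfacial waters, ligands, non-standard residues and hydrogens are
outside the contact model; crystal-packing partners must be present as
explicit chains (no symmetry expansion); the Voronoi stage uses unweighted
centers (no Laguerre/power weighting by radius); tie handling for
cospherical atoms is a declared convention, not an exact-arithmetic
predicate.
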