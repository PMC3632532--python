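"""Desk-scale synthetic inputs with known ground truth.

Three generators cover the package's test surface:

* a fixed, hand-analysed near-planar arrangement whose distance/Voronoi/
  beta contact sets are enumerated in code (the blocked-pair geometry of a
  Gabriel violation is built in explicitly);
* clash-free random atom packings split into two sides facing across a
  plane, writable as valid PDB files;
* labeled two-class ACV count datasets with Poisson noise and planted mean
  shifts on chosen informative features, standing in for real
  homodimer/crystal-packing feature matrices.

All generators are pure functions of their spec (seed included).  None of
them attempts physically realistic protein geometry: atoms are independent
hard spheres, not bonded residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .acv_features import LabeledDataset, feature_labels
from .structure_io import Atom, ComplexStructure

#: (residue_name, atom_name, element) identities cycled over generated atoms;
#: spans 8 of the 12 atomic types so featurization sees a varied palette.
DEFAULT_PALETTE: tuple[tuple[str, str, str], ...] = (
    ("ALA", "CB", "C"),
    ("SER", "OG", "O"),
    ("LYS", "NZ", "N"),
    ("GLY", "CA", "C"),
    ("ASP", "OD1", "O"),
    ("CYS", "SG", "S"),
    ("LEU", "CD1", "C"),
    ("ASN", "ND2", "N"),
)

_ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass(frozen=True)
class FixtureSpec:
    """Random two-sided packing parameters.

    ``n_per_side`` atoms are placed on each side of the plane x = 0, inside
    a box whose cross-section is ``box`` Å and whose depth scales with the
    atom count; ``gap`` Å separates the two inner box faces, and all atom
    centers keep at least ``min_separation`` Å apart (a realistic
    non-bonded heavy-atom floor).
    """

    n_per_side: int = 25
    box: float = 12.0
    gap: float = 1.0
    min_separation: float = 2.8
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.n_per_side < 1:
            raise ValueError("need at least one atom per side")


@dataclass(frozen=True)
class SignalSpec:
    """Two-class ACV dataset parameters.

    Counts are Poisson around class-conditional means: background slots
    share ``baseline_mean`` in both classes, while ``informative`` slots
    get a mean shift of ``effect_size`` baseline standard deviations
    (sqrt of the mean, as counts are Poisson) in the positive class.
    """

    n_per_class: int = 100
    n_features: int = 235
    informative: tuple[int, ...] = (5, 40, 110, 170, 230)
    effect_size: float = 2.0
    baseline_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(i < 0 or i >= self.n_features for i in self.informative):
            raise ValueError("informative indices out of range")
        if self.baseline_mean < 0 or self.effect_size < 0:
            raise ValueError("means and effect sizes must be non-negative")


def _mk_atom(atom_id, resname, name, element, chain, resseq, side, coord) -> Atom:
    return Atom(
        atom_id=atom_id,
        element=element,
        atom_name=name,
        residue_name=resname,
        residue_id=(chain, resseq, ""),
        side=side,
        coord=tuple(float(x) for x in coord),
        vdw_radius=_ELEMENT_RADII[element],
    )


def make_planar_fixture() -> tuple[ComplexStructure, dict[str, set[tuple[int, int]]]]:
    """A fixed 7-atom configuration with analytically known contact sets.

    Three inter-side pairs are within the 3.3 Å surface-distance threshold.
    The pair (1, 5) is Gabriel-blocked: atom 2 sits 0.71 Å from its
    midpoint, well inside the 2.0 Å open ball, so the pair is a distance
    and Voronoi contact but not a beta contact.  Pair (0, 4) is unblocked
    and pair (2, 5) — the blocker touching the opposite side — is a beta
    contact in its own right.  Atoms 3 and 6 are 7.5 Å apart (surface
    distance 4.1 Å) and contribute no contact at all.

    Returns the complex and the expected pair-key sets per definition.
    """
    coords = [
        ("A", (0.0, 0.0, 0.0)),
        ("A", (10.0, 0.0, 0.0)),
        ("A", (10.5, 2.0, 0.5)),
        ("A", (20.0, 0.0, 0.0)),
        ("B", (0.0, 4.0, 0.0)),
        ("B", (10.0, 4.0, 0.0)),
        ("B", (20.0, 7.5, 0.0)),
    ]
    atoms = [
        _mk_atom(i, "ALA", "CB", "C", side, i + 1, side, xyz)
        for i, (side, xyz) in enumerate(coords)
    ]
    expected = {
        "DISTANCE": {(0, 4), (1, 5), (2, 5)},
        "VORONOI": {(0, 4), (1, 5), (2, 5)},
        "BETA": {(0, 4), (2, 5)},
    }
    return ComplexStructure(atoms, {"A": "A", "B": "B"}, "planar-fixture"), expected


def make_random_complex(spec: FixtureSpec) -> ComplexStructure:
    """Rejection-sample a clash-free two-sided packing; deterministic per seed.

    Side A occupies x < -gap/2 and side B x > gap/2; the box depth grows
    with the atom count so the target density stays samplable.  Raises
    ``RuntimeError`` if the packing is infeasible within the attempt cap.
    """
    rng = np.random.default_rng(spec.seed)
    # depth sized for ~50 A^3 per atom: well below the random-sequential
    # jamming density, so rejection sampling stays cheap at any n
    depth = max(spec.box / 2.0, 50.0 * spec.n_per_side / spec.box**2)
    placed: list[np.ndarray] = []
    sides: list[str] = []
    for side, x_lo, x_hi in (
        ("A", -(spec.gap / 2.0 + depth), -spec.gap / 2.0),
        ("B", spec.gap / 2.0, spec.gap / 2.0 + depth),
    ):
        n_placed = 0
        attempts = 0
        while n_placed < spec.n_per_side:
            if attempts >= spec.max_attempts:
                raise RuntimeError(
                    f"packing infeasible: side {side} placed {n_placed}/{spec.n_per_side} "
                    f"atoms in {spec.max_attempts} attempts"
                )
            attempts += 1
            candidate = np.array(
                [
                    rng.uniform(x_lo, x_hi),
                    rng.uniform(0.0, spec.box),
                    rng.uniform(0.0, spec.box),
                ]
            )
            if placed:
                d = np.linalg.norm(np.array(placed) - candidate, axis=1)
                if d.min() < spec.min_separation:
                    continue
            placed.append(candidate)
            sides.append(side)
            n_placed += 1
    atoms = []
    for i, (xyz, side) in enumerate(zip(placed, sides)):
        resname, name, element = DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
        atoms.append(_mk_atom(i, resname, name, element, side, i + 1, side, np.round(xyz, 3)))
    return ComplexStructure(
        atoms, {"A": "A", "B": "B"}, f"random-fixture-seed{spec.seed}"
    )


def write_pdb(complex_structure: ComplexStructure, path: str | Path) -> None:
    """Write the fixture as a minimal, standard-conforming PDB file."""
    lines = []
    for atom in complex_structure.atoms:
        chain, resseq, icode = atom.residue_id
        name = atom.atom_name if len(atom.atom_name) == 4 else f" {atom.atom_name:<3}"
        x, y, z = atom.coord
        lines.append(
            f"ATOM  {atom.atom_id + 1:>5} {name}{'':1}{atom.residue_name:>3} "
            f"{chain:1}{resseq:>4}{icode or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_acv_dataset(spec: SignalSpec) -> LabeledDataset:
    """Draw a labeled two-class count matrix with planted informative slots.

    Positive-class rows (+1, 'homodimers') have elevated means on the
    informative features; negative rows (-1, 'crystal packing') are pure
    background.  Labels are balanced, rows interleaved, everything
    reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    means_neg = np.full(spec.n_features, spec.baseline_mean, dtype=float)
    means_pos = means_neg.copy()
    shift = spec.effect_size * np.sqrt(max(spec.baseline_mean, 1e-12))
    means_pos[list(spec.informative)] += shift
    X_pos = rng.poisson(means_pos, size=(spec.n_per_class, spec.n_features))
    X_neg = rng.poisson(means_neg, size=(spec.n_per_class, spec.n_features))
    X = np.vstack([X_pos, X_neg])
    y = np.array([1] * spec.n_per_class + [-1] * spec.n_per_class)
    order = rng.permutation(len(y))
    if spec.n_features == 235:
        labels = tuple(feature_labels("ACV3"))
        variant = "ACV3"
    elif spec.n_features == 79:
        labels = tuple(feature_labels("ACV1a"))
        variant = "ACV1a"
    else:
        labels = tuple(f"f{i}" for i in range(spec.n_features))
        variant = "ACV3"
    ids = [f"synthetic-{'dimer' if y[i] == 1 else 'cp'}-{i}" for i in order]
    return LabeledDataset(X[order], y[order], ids, labels, variant, "beta")
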