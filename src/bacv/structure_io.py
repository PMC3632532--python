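"""Read protein complexes and prepare them for interface contact analysis.

A complex is reduced to the heavy atoms (C, N, O, S) of the 20 standard
residues, each carrying a van der Waals radius and an interface-side label
(``A`` or ``B``).  Waters, ligands, hydrogens and non-standard residues are
dropped; alternate locations are collapsed to the highest-occupancy
conformer.  The two sides of the interface are supplied by the caller as a
partition of the chain identifiers — no crystallographic symmetry expansion
is performed, so crystal-packing partners must already be present as chains
in the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.PDB import MMCIFParser, PDBParser

logger = logging.getLogger(__name__)

#: 3-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Heavy-atom elements retained for contact analysis.
HEAVY_ELEMENTS = frozenset({"C", "N", "O", "S"})

UNTYPED = "UNTYPED"


@dataclass(frozen=True)
class Atom:
    """A typed heavy atom of a protein complex.

    ``side`` labels which half of the interface the atom belongs to;
    ``atomic_type`` is one of the 12 contact-vector type labels once
    :func:`bacv.atom_typing.assign_types` has run, else ``UNTYPED``.
    """

    atom_id: int
    element: str
    atom_name: str
    residue_name: str
    residue_id: tuple[str, int, str]  # (chain id, residue number, insertion code)
    side: str
    coord: tuple[float, float, float]
    vdw_radius: float
    atomic_type: str = UNTYPED

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for {self.atom_name}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for {self.atom_name}")

    @property
    def chain_id(self) -> str:
        return self.residue_id[0]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class ComplexStructure:
    """A two-sided protein complex: atoms plus the chain → side assignment."""

    atoms: list[Atom]
    side_assignment: dict[str, str]
    source_id: str = ""

    def __post_init__(self) -> None:
        sides = {a.side for a in self.atoms}
        if self.atoms and sides != {"A", "B"}:
            raise ValueError(f"both interface sides must be non-empty, got sides {sorted(sides)}")
        seen: set[tuple[str, tuple[str, int, str]]] = set()
        for a in self.atoms:
            key = (a.atom_name, a.residue_id)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in {self.source_id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of atom centers, in atom order."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def sides(self) -> np.ndarray:
        return np.array([a.side for a in self.atoms])

    def with_atoms(self, atoms: Iterable[Atom]) -> "ComplexStructure":
        return ComplexStructure(list(atoms), dict(self.side_assignment), self.source_id)


class RadiiTable:
    """van der Waals radii, resolvable per element or per (residue, atom).

    The default table is element-based (C 1.70, N 1.55, O 1.52, S 1.80 Å).
    Per-(residue, atom) entries, when present, take precedence, so a
    NACCESS-style table can be swapped in from a TSV file.
    """

    DEFAULT_ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

    def __init__(
        self,
        element_radii: Mapping[str, float] | None = None,
        atom_radii: Mapping[tuple[str, str], float] | None = None,
        name: str = "element-default",
    ) -> None:
        self.element_radii = dict(element_radii or self.DEFAULT_ELEMENT_RADII)
        self.atom_radii = dict(atom_radii or {})
        self.name = name

    def lookup(self, element: str, residue_name: str, atom_name: str) -> float:
        key = (residue_name.upper(), atom_name.upper())
        if key in self.atom_radii:
            return self.atom_radii[key]
        try:
            return self.element_radii[element.upper()]
        except KeyError:
            raise KeyError(
                f"no vdW radius for atom {atom_name} ({element}) in residue {residue_name}"
            ) from None

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "RadiiTable":
        """Load per-(residue, atom) radii from a 3-column TSV: residue, atom, radius."""
        atom_radii: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, atom, radius = line.split("\t")[:3]
                atom_radii[(res.upper(), atom.upper())] = float(radius)
        return cls(atom_radii=atom_radii, name=name or str(path))


def parse_side_assignment(spec: str) -> dict[str, str]:
    """Parse a side string like ``"A,B:C,D"`` into chain → side {A, B}."""
    try:
        left, right = spec.split(":")
    except ValueError:
        raise ValueError(f"side assignment {spec!r} must contain exactly one ':'") from None
    mapping: dict[str, str] = {}
    for chain in filter(None, (c.strip() for c in left.split(","))):
        mapping[chain] = "A"
    for chain in filter(None, (c.strip() for c in right.split(","))):
        if chain in mapping:
            raise ValueError(f"chain {chain!r} assigned to both sides")
        mapping[chain] = "B"
    if "A" not in mapping.values() or "B" not in mapping.values():
        raise ValueError(f"side assignment {spec!r} leaves one side empty")
    return mapping


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if not elem:
        # fall back to the first alphabetic character of the atom name
        elem = next((c for c in bio_atom.get_name() if c.isalpha()), "")
    return elem


def read_complex(
    path: str | Path,
    side_assignment: Mapping[str, str],
    radii: RadiiTable | None = None,
    source_id: str | None = None,
) -> ComplexStructure:
    """Read a PDB (or mmCIF) file into a filtered, two-sided :class:`ComplexStructure`.

    Only heavy atoms (C/N/O/S) of the 20 standard residues are retained: no
    hydrogens, no waters, no HETATM ligands, no non-standard residues.  For
    NMR-style multi-model files only model 1 is used.  Alternate locations
    are collapsed to the highest-occupancy conformer (ties broken by altloc
    code order).

    Raises ``ValueError`` if a retained chain is missing from
    ``side_assignment``, and ``KeyError`` if an atom has no radius entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    radii = radii or RadiiTable()
    parser = (
        MMCIFParser(QUIET=True)
        if path.suffix.lower() in {".cif", ".mmcif"}
        else PDBParser(QUIET=True)
    )
    structure = parser.get_structure(source_id or path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    if len(models) > 1:
        logger.warning("%s: %d models present; using model 1 only", path, len(models))
    model = models[0]

    dropped = {"water": 0, "hetero": 0, "nonstandard": 0, "hydrogen": 0, "nonheavy": 0}
    missing_chains: set[str] = set()
    atoms: list[Atom] = []
    atom_id = 0
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip().upper()
            if resname == "HOH" or hetflag == "W":
                dropped["water"] += 1
                continue
            if hetflag.strip():
                dropped["hetero"] += 1
                continue
            if resname not in STANDARD_RESIDUES:
                dropped["nonstandard"] += 1
                continue
            if chain.id not in side_assignment:
                missing_chains.add(chain.id)
                continue
            side = side_assignment[chain.id]
            if side not in {"A", "B"}:
                raise ValueError(f"side for chain {chain.id!r} must be 'A' or 'B', got {side!r}")
            # collapse altlocs: per atom name keep the highest-occupancy copy
            best: dict[str, object] = {}
            for bio_atom in residue.get_unpacked_list():
                name = bio_atom.get_name()
                prev = best.get(name)
                if prev is None:
                    best[name] = bio_atom
                else:
                    occ_new = bio_atom.get_occupancy() or 0.0
                    occ_old = prev.get_occupancy() or 0.0
                    if occ_new > occ_old or (
                        occ_new == occ_old and (bio_atom.get_altloc() or "") < (prev.get_altloc() or "")
                    ):
                        best[name] = bio_atom
            for name in sorted(best):
                bio_atom = best[name]
                element = _element_of(bio_atom)
                if element == "H" or element == "D":
                    dropped["hydrogen"] += 1
                    continue
                if element not in HEAVY_ELEMENTS:
                    dropped["nonheavy"] += 1
                    continue
                coord = tuple(float(x) for x in bio_atom.get_coord())
                radius = radii.lookup(element, resname, name)
                atoms.append(
                    Atom(
                        atom_id=atom_id,
                        element=element,
                        atom_name=name,
                        residue_name=resname,
                        residue_id=(chain.id, int(resseq), icode.strip() or ""),
                        side=side,
                        coord=coord,
                        vdw_radius=radius,
                    )
                )
                atom_id += 1

    if missing_chains:
        raise ValueError(
            f"{path}: chains {sorted(missing_chains)} present in structure but absent "
            f"from side assignment"
        )
    for kind, count in dropped.items():
        if count:
            logger.info("%s: dropped %d %s entries", path, count, kind)
    return ComplexStructure(atoms, dict(side_assignment), source_id or path.stem)
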