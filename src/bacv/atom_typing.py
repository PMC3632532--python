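"""Assign the 12 atomic types used by atomic contact vectors.

Heavy atoms of the 20 standard residues are grouped into 12 chemical types
named by element, heavy-atom coordination number and bonded-hydrogen count
(e.g. ``C_4H_3`` for an sp3 methyl carbon, ``N_3H_1`` for a backbone amide
nitrogen, ``O_1H_0-`` for a carboxylate oxygen).  Typing is a pure function
of (residue name, atom name) — coordinates play no role.  The default table
ships as an editable TSV so an alternative convention can be dropped in.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

from .structure_io import UNTYPED, ComplexStructure

logger = logging.getLogger(__name__)

_DEFAULT_TABLE: "TypingTable | None" = None


class TypingTable:
    """Mapping (residue_name, atom_name) → one of 12 atomic type labels."""

    def __init__(self, entries: dict[tuple[str, str], str], name: str = "default") -> None:
        self.entries = dict(entries)
        self.name = name
        labels = set(self.entries.values())
        if len(labels) != 12:
            raise ValueError(f"typing table {name!r} has {len(labels)} type labels, expected 12")
        self.type_labels: tuple[str, ...] = tuple(sorted(labels))

    def get(self, residue_name: str, atom_name: str) -> str:
        """Type label for the atom, or ``UNTYPED`` if the table has no entry."""
        return self.entries.get((residue_name.upper(), atom_name.upper()), UNTYPED)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return (key[0].upper(), key[1].upper()) in self.entries

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "TypingTable":
        entries: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, atom, label = line.split("\t")[:3]
                entries[(res.upper(), atom.upper())] = label
        return cls(entries, name=name or str(path))


def default_typing_table() -> TypingTable:
    """The typing table shipped with the package (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("bacv").joinpath("data/atom_types.tsv")
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = TypingTable.from_tsv(path, name="bacv-default")
    return _DEFAULT_TABLE


def assign_types(
    complex_structure: ComplexStructure, table: TypingTable | None = None
) -> ComplexStructure:
    """Return a copy of the complex with every atom's ``atomic_type`` set.

    Atoms absent from the table are marked ``UNTYPED`` (and later excluded
    from featurization); this is logged, never fatal.
    """
    from dataclasses import replace

    table = table or default_typing_table()
    typed = []
    n_untyped = 0
    for atom in complex_structure.atoms:
        label = table.get(atom.residue_name, atom.atom_name)
        if label == UNTYPED:
            n_untyped += 1
        typed.append(replace(atom, atomic_type=label))
    if n_untyped:
        logger.warning(
            "%s: %d atoms have no typing entry and stay UNTYPED",
            complex_structure.source_id,
            n_untyped,
        )
    return complex_structure.with_atoms(typed)
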