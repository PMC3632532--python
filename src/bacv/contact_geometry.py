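"""Detect distance-based, Voronoi-based and Gabriel (beta) atomic contacts.

An inter-protein heavy-atom pair (i, j) is graded through three nested
requirements:

1. *distance*: the surface distance ``|i - j| - (r_i + r_j)`` is at most
   ``tmax`` (default 3.3 Å: the 2.8 Å diameter of a water molecule plus
   0.5 Å);
2. *Voronoi*: i and j share a Voronoi facet of the whole complex, i.e. they
   are Delaunay neighbours of the full point set of atom centers;
3. *beta*: no other atom's center lies strictly inside the open ball whose
   diameter is the segment ij — the Gabriel-graph (beta = 1 skeleton)
   condition.

Every atom of the complex, on either side of the interface, can act as a
blocker; only pairs spanning the interface are reported.  Because Gabriel
edges are a subgraph of Delaunay edges in general position, the production
path tests the Gabriel condition only on Delaunay edges; a brute-force
detector with no triangulation serves as the independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import cdist

from .structure_io import Atom, ComplexStructure

DISTANCE = "DISTANCE"
VORONOI = "VORONOI"
BETA = "BETA"
DEFINITIONS = (DISTANCE, VORONOI, BETA)

#: Sulfur–sulfur center distance below which an inter-side CYS SG pair is a disulfide (Å).
DISULFIDE_CUTOFF = 2.6


@dataclass(frozen=True)
class ContactConfig:
    """Parameters of the contact cascade.

    ``tmax`` is the surface-distance threshold in Å.  ``beta`` is the
    skeleton parameter; only the Gabriel graph (beta = 1) is supported on
    the production path.  ``boundary_epsilon`` is the tolerance of the
    open-ball blocker test: a blocker exactly on the sphere does not break
    a contact.
    """

    tmax: float = 3.3
    beta: float = 1.0
    boundary_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.tmax <= 0:
            raise ValueError("tmax must be positive")
        if self.beta != 1.0:
            raise NotImplementedError("only the Gabriel graph (beta = 1) is supported")


@dataclass(frozen=True)
class Contact:
    """An inter-side atom pair with its distances and satisfied definitions.

    ``atom_i`` is always on side A and ``atom_j`` on side B, so unordered
    pairs have a single canonical representation.
    """

    atom_i: Atom
    atom_j: Atom
    euclid_distance: float
    surface_distance: float
    satisfies: frozenset[str]

    @property
    def pair_key(self) -> tuple[int, int]:
        return (self.atom_i.atom_id, self.atom_j.atom_id)


@dataclass
class ContactGraph:
    """All inter-side contacts of a complex under one configuration."""

    complex_structure: ComplexStructure
    config: ContactConfig
    contacts: list[Contact]
    voronoi_available: bool = True

    def __post_init__(self) -> None:
        keys = [c.pair_key for c in self.contacts]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate contact pairs in graph")

    def select(self, definition: str) -> list[Contact]:
        """Contacts satisfying a definition; ``"complement"`` = distance minus beta."""
        if definition == "complement":
            return [c for c in self.contacts if DISTANCE in c.satisfies and BETA not in c.satisfies]
        if definition not in DEFINITIONS:
            raise ValueError(f"unknown definition {definition!r}")
        if definition == VORONOI and not self.voronoi_available:
            raise ValueError("Voronoi flags unavailable (degenerate triangulation)")
        return [c for c in self.contacts if definition in c.satisfies]

    def pair_set(self, definition: str) -> set[tuple[int, int]]:
        return {c.pair_key for c in self.select(definition)}

    def counts(self) -> dict[str, int]:
        out = {d: 0 for d in DEFINITIONS}
        for c in self.contacts:
            for d in c.satisfies:
                out[d] += 1
        if not self.voronoi_available:
            out.pop(VORONOI)
        return out


def surface_distance(a: Atom, b: Atom) -> float:
    """Euclidean center distance minus the sum of the two vdW radii (Å).

    Negative values mean overlapping spheres.
    """
    return float(np.linalg.norm(a.xyz - b.xyz)) - (a.vdw_radius + b.vdw_radius)


def _as_xyz(point) -> np.ndarray:
    return point.xyz if isinstance(point, Atom) else np.asarray(point, dtype=float)


def gabriel_blocked(i, j, k, eps: float = 1e-9) -> bool:
    """True iff atom k's center lies strictly inside the open Gabriel ball of (i, j).

    The ball is centered at the midpoint of i and j with the segment ij as
    diameter.  Points exactly on the sphere (within ``eps``) do not block.
    Accepts :class:`Atom` objects or bare 3-vectors.
    """
    pi, pj, pk = _as_xyz(i), _as_xyz(j), _as_xyz(k)
    mid = 0.5 * (pi + pj)
    radius = 0.5 * float(np.linalg.norm(pi - pj))
    return float(np.linalg.norm(pk - mid)) < radius - eps


def _delaunay_edges(coords: np.ndarray) -> set[tuple[int, int]] | None:
    """Unordered index pairs of atoms sharing a Voronoi facet, or None if qhull fails.

    Degenerate sets are handled exactly rather than joggled where possible:
    the Voronoi cells of a lower-dimensional point set are prisms orthogonal
    to its affine hull, so adjacency equals Delaunay adjacency *within* the
    hull — all pairs for an affinely independent (simplex) set, consecutive
    pairs for collinear points, the planar triangulation for coplanar ones.
    """
    n = len(coords)
    if n < 2:
        return set()
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(svals > 1e-9 * max(svals[0], 1.0)))
    all_pairs = {(a, b) for a in range(n) for b in range(a + 1, n)}
    if rank == 0:
        return all_pairs  # coincident points: every cell boundary is shared
    if n <= rank + 1:
        return all_pairs  # affinely independent: one simplex, all edges
    if rank == 1:
        order = np.argsort(centered @ vt[0])
        return {tuple(sorted((order[i], order[i + 1]))) for i in range(n - 1)}
    points = centered @ vt[:rank].T if rank == 2 else coords
    try:
        tri = Delaunay(points)
    except (QhullError, ValueError):
        try:
            tri = Delaunay(points, qhull_options="QJ")
        except (QhullError, ValueError):
            return None
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex.tolist(), 2):
            edges.add((a, b) if a < b else (b, a))
    return edges


def _candidate_pairs(
    complex_structure: ComplexStructure, config: ContactConfig
) -> list[tuple[int, int, float, float]]:
    """Inter-side pairs with surface distance <= tmax: (ia, ib, euclid, surface)."""
    coords = complex_structure.coords()
    radii = complex_structure.radii()
    sides = complex_structure.sides()
    if len(coords) < 2:
        return []
    cutoff = config.tmax + 2.0 * radii.max()
    tree = cKDTree(coords)
    out = []
    for a, b in tree.query_pairs(cutoff):
        if sides[a] == sides[b]:
            continue
        ia, ib = (a, b) if sides[a] == "A" else (b, a)
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        s = d - (radii[ia] + radii[ib])
        if s <= config.tmax:
            out.append((ia, ib, d, s))
    out.sort()
    return out


def detect_contacts(
    complex_structure: ComplexStructure, config: ContactConfig | None = None
) -> ContactGraph:
    """Run the full contact cascade on a complex.

    Falls back to :func:`brute_force_contacts` when fewer than 5 atoms are
    present (no 3-D triangulation exists).  Raises ``RuntimeError`` if the
    point set defeats triangulation even after joggling.
    """
    config = config or ContactConfig()
    atoms = complex_structure.atoms
    coords = complex_structure.coords()
    if len(atoms) < 5:
        return brute_force_contacts(complex_structure, config)
    edges = _delaunay_edges(coords)
    if edges is None:
        raise RuntimeError(
            "degenerate point set: Delaunay triangulation failed even with joggled "
            "input; use brute_force_contacts instead"
        )
    eps = config.boundary_epsilon
    tree = cKDTree(coords)
    contacts: list[Contact] = []
    for ia, ib, d, s in _candidate_pairs(complex_structure, config):
        flags = {DISTANCE}
        key = (ia, ib) if ia < ib else (ib, ia)
        if key in edges:
            flags.add(VORONOI)
            mid = 0.5 * (coords[ia] + coords[ib])
            inside = tree.query_ball_point(mid, 0.5 * d - eps)
            if all(k in (ia, ib) for k in inside):
                flags.add(BETA)
        contacts.append(Contact(atoms[ia], atoms[ib], d, s, frozenset(flags)))
    return ContactGraph(complex_structure, config, contacts)


def brute_force_contacts(
    complex_structure: ComplexStructure,
    config: ContactConfig | None = None,
    max_atoms: int = 2000,
) -> ContactGraph:
    """Oracle detector: exhaustive pair scan and exhaustive blocker checks.

    The distance flag comes from an all-pairs scan; the beta flag from
    testing every other atom of the complex against the open Gabriel ball.
    The Voronoi flag is filled in as "beta or Delaunay edge" when a
    triangulation is available.  Without one (fewer than 5 atoms, or a
    degenerate set), the graph's ``voronoi_available`` is False; beta
    contacts still carry the Voronoi flag, since the midpoint of an empty
    diameter ball is equidistant to, and strictly closest to, the two
    endpoints — a Gabriel edge always witnesses a shared Voronoi facet.
    """
    config = config or ContactConfig()
    atoms = complex_structure.atoms
    n = len(atoms)
    if n > max_atoms:
        raise ValueError(f"brute-force guard: {n} atoms exceeds limit {max_atoms}")
    coords = complex_structure.coords()
    eps = config.boundary_epsilon
    edges = _delaunay_edges(coords)
    voronoi_available = edges is not None
    contacts: list[Contact] = []
    for ia, ib, d, s in _candidate_pairs(complex_structure, config):
        flags = {DISTANCE}
        mid = 0.5 * (coords[ia] + coords[ib])
        dist_to_mid = np.linalg.norm(coords - mid, axis=1)
        dist_to_mid[[ia, ib]] = np.inf
        if not np.any(dist_to_mid < 0.5 * d - eps):
            flags.add(BETA)
            flags.add(VORONOI)  # Gabriel edges are Delaunay edges
        if voronoi_available and BETA not in flags:
            key = (ia, ib) if ia < ib else (ib, ia)
            if key in edges:
                flags.add(VORONOI)
        contacts.append(Contact(atoms[ia], atoms[ib], d, s, frozenset(flags)))
    return ContactGraph(complex_structure, config, contacts, voronoi_available=voronoi_available)


def detect_disulfides(complex_structure: ComplexStructure) -> tuple[int, list[tuple[Atom, Atom]]]:
    """Count inter-side CYS SG–SG pairs with center distance < 2.6 Å.

    Disulfide bridges are nearly covalent, so they are detected by center
    distance alone, independent of the Gabriel test.
    """
    sg_a = [a for a in complex_structure.atoms
            if a.residue_name == "CYS" and a.atom_name == "SG" and a.side == "A"]
    sg_b = [a for a in complex_structure.atoms
            if a.residue_name == "CYS" and a.atom_name == "SG" and a.side == "B"]
    pairs = []
    for a in sg_a:
        for b in sg_b:
            if float(np.linalg.norm(a.xyz - b.xyz)) < DISULFIDE_CUTOFF:
                pairs.append((a, b))
    return len(pairs), pairs


@dataclass
class DefinitionComparison:
    """Contact counts per definition and their pairwise set differences."""

    counts: dict[str, int]
    differences: dict[tuple[str, str], int]

    @staticmethod
    def beta_percent_of_distance(beta_count: float, distance_count: float) -> float:
        """Beta contacts as a percentage of distance-based contacts."""
        if distance_count == 0:
            return float("nan")
        return 100.0 * beta_count / distance_count


def compare_definitions(graph: ContactGraph) -> DefinitionComparison:
    """Summarize how the three contact definitions differ on one interface."""
    defs = DEFINITIONS if graph.voronoi_available else (DISTANCE, BETA)
    sets = {d: graph.pair_set(d) for d in defs}
    counts = {d: len(sets[d]) for d in defs}
    differences = {
        (a, b): len(sets[a] - sets[b]) for a in defs for b in defs if a != b
    }
    return DefinitionComparison(counts, differences)


def aggregate_comparisons(
    summaries: Sequence[DefinitionComparison],
) -> dict[str, dict[str, float]]:
    """Dataset-level totals and per-interface mean ± sd for each definition."""
    out: dict[str, dict[str, float]] = {}
    if not summaries:
        return out
    defs = [d for d in DEFINITIONS if all(d in s.counts for s in summaries)]
    for d in defs:
        values = np.array([s.counts[d] for s in summaries], dtype=float)
        out[d] = {
            "total": float(values.sum()),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        }
    return out


def contacts_to_records(graph: ContactGraph) -> list[dict]:
    """Flatten a contact graph for TSV/CSV export."""
    records = []
    for c in graph.contacts:
        ai, aj = c.atom_i, c.atom_j
        records.append(
            {
                "chain_i": ai.chain_id,
                "resid_i": ai.residue_id[1],
                "resname_i": ai.residue_name,
                "atom_i": ai.atom_name,
                "type_i": ai.atomic_type,
                "chain_j": aj.chain_id,
                "resid_j": aj.residue_id[1],
                "resname_j": aj.residue_name,
                "atom_j": aj.atom_name,
                "type_j": aj.atomic_type,
                "euclid_d": round(c.euclid_distance, 4),
                "surface_d": round(c.surface_distance, 4),
                "is_distance": DISTANCE in c.satisfies,
                "is_voronoi": VORONOI in c.satisfies,
                "is_beta": BETA in c.satisfies,
            }
        )
    return records
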