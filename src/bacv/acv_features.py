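"""Atomic contact vectors (ACVs): fixed-length interface featurizations.

An interface is represented by occurrence counts of its contacts over the
78 unordered pairs of the 12 atomic types, plus one final slot for
inter-side disulfide bridges.  Three variants differ in how surface
distance enters:

* ``ACV1``  — only contacts with surface distance <= 0.5 Å (79 slots);
* ``ACV1a`` — all contacts up to the 3.3 Å threshold (79 slots);
* ``ACV3``  — contacts split into the three surface-distance bins <=0.5,
  (0.5, 1.9] and (1.9, 3.3] (78 x 3 + 1 = 235 slots).

Each variant can count beta contacts, distance-based contacts, or the
complement (distance-based minus beta), so the discriminative value of the
Gabriel condition can be isolated.  Feature order is canonical — type pairs
sorted lexicographically, bins from nearest to farthest, disulfide last —
and serialized with every matrix so models are portable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atom_typing import default_typing_table
from .contact_geometry import BETA, DISTANCE, ContactGraph, detect_disulfides
from .structure_io import UNTYPED

logger = logging.getLogger(__name__)

VARIANTS = ("ACV1", "ACV1a", "ACV3")
DEFINITIONS = ("beta", "distance", "complement")

#: Surface-distance bin labels in canonical inner order.
BIN_LABELS = ("<=0.5", "(0.5,1.9]", "(1.9,3.3]")
BIN_EDGES = (0.5, 1.9, 3.3)

SS_LABEL = "SS"


def type_pair_labels(type_labels: Sequence[str] | None = None) -> list[tuple[str, str]]:
    """The 78 unordered type pairs in canonical (sorted) order."""
    labels = sorted(type_labels) if type_labels else list(default_typing_table().type_labels)
    return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i, len(labels))]


def feature_labels(variant: str) -> list[str]:
    """Ordered feature labels of a variant; type pairs (x bins for ACV3), SS last."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    pairs = type_pair_labels()
    if variant == "ACV3":
        labels = [f"{a}__{b}|{bin_}" for a, b in pairs for bin_ in BIN_LABELS]
    else:
        labels = [f"{a}__{b}" for a, b in pairs]
    labels.append(SS_LABEL)
    return labels


def surface_bin(surface_d: float) -> int:
    """Bin index of a surface distance: 0 for <=0.5, 1 for (0.5,1.9], 2 for (1.9,3.3]."""
    if surface_d <= BIN_EDGES[0]:
        return 0
    if surface_d <= BIN_EDGES[1]:
        return 1
    if surface_d <= BIN_EDGES[2]:
        return 2
    raise ValueError(f"surface distance {surface_d} beyond the 3.3 Å threshold")


@dataclass
class ACVector:
    """One interface's contact-count vector."""

    variant: str
    definition: str
    values: np.ndarray  # non-negative integer counts
    labels: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels length mismatch")
        if np.any(self.values < 0):
            raise ValueError("negative contact counts")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_contacts(self) -> int:
        """Number of contacts counted (disulfide slot excluded)."""
        return int(self.values[:-1].sum())


def build_acv(graph: ContactGraph, variant: str = "ACV3", definition: str = "beta") -> ACVector:
    """Count a contact graph into an ACV of the requested variant.

    Contacts involving untyped atoms are skipped (logged).  Disulfide
    SG–SG pairs fill only the final SS slot, never an ordinary type-pair
    slot: they are covalent bridges, not contacts.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}")
    labels = feature_labels(variant)
    index = {label: k for k, label in enumerate(labels)}
    values = np.zeros(len(labels), dtype=int)

    n_ss, ss_pairs = detect_disulfides(graph.complex_structure)
    ss_keys = {(a.atom_id, b.atom_id) for a, b in ss_pairs}
    values[index[SS_LABEL]] = n_ss

    selected = graph.select({"beta": BETA, "distance": DISTANCE, "complement": "complement"}[definition])
    n_untyped = 0
    for c in selected:
        if c.pair_key in ss_keys:
            continue
        ti, tj = c.atom_i.atomic_type, c.atom_j.atomic_type
        if UNTYPED in (ti, tj):
            n_untyped += 1
            continue
        a, b = sorted((ti, tj))
        if variant == "ACV3":
            label = f"{a}__{b}|{BIN_LABELS[surface_bin(c.surface_distance)]}"
        else:
            if variant == "ACV1" and c.surface_distance > BIN_EDGES[0]:
                continue
            label = f"{a}__{b}"
        values[index[label]] += 1
    if n_untyped:
        logger.warning(
            "%s: skipped %d contacts involving untyped atoms",
            graph.complex_structure.source_id,
            n_untyped,
        )
    return ACVector(variant, definition, values, tuple(labels), graph.complex_structure.source_id)


@dataclass
class LabeledDataset:
    """A feature matrix of ACVs with ±1 labels (+1 homodimer, −1 crystal packing)."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    labels: tuple[str, ...]
    variant: str = "ACV3"
    definition: str = "beta"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.y), len(self.labels)):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.y)} labels x {len(self.labels)} features"
            )
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("class labels must be +1 (homodimer) or -1 (crystal packing)")

    def __len__(self) -> int:
        return len(self.y)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.labels))
        df.insert(0, "label", self.y)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, variant: str = "ACV3", definition: str = "beta"
    ) -> "LabeledDataset":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError("feature CSV must start with columns id,label")
        labels = tuple(df.columns[2:])
        return cls(
            df[list(labels)].to_numpy(),
            df["label"].to_numpy(),
            df["id"].astype(str).tolist(),
            labels,
            variant,
            definition,
        )

    def subset(self, feature_subset: Sequence[str]) -> "LabeledDataset":
        idx = [self.labels.index(f) for f in feature_subset]
        return LabeledDataset(
            self.X[:, idx], self.y, list(self.ids), tuple(feature_subset),
            self.variant, self.definition,
        )


def featurize_dataset(
    graphs: Iterable[ContactGraph],
    sample_labels: Sequence[int],
    variant: str = "ACV3",
    definition: str = "beta",
) -> LabeledDataset:
    """One ACV row per interface, in input order, with labels attached.

    Per-interface failures are collected and re-raised together at the end
    so one bad complex does not silently truncate a batch.
    """
    rows, ids, errors = [], [], []
    for graph in graphs:
        try:
            acv = build_acv(graph, variant, definition)
            rows.append(acv.values)
            ids.append(acv.source_id or f"interface_{len(ids)}")
        except Exception as exc:  # noqa: BLE001 — batch error report
            errors.append(f"{graph.complex_structure.source_id}: {exc}")
    if errors:
        raise RuntimeError("featurization failed for:\n" + "\n".join(errors))
    if len(rows) != len(sample_labels):
        raise ValueError("number of interfaces and labels differ")
    return LabeledDataset(
        np.array(rows, dtype=int).reshape(len(rows), -1),
        np.asarray(sample_labels, dtype=int),
        ids,
        tuple(feature_labels(variant)),
        variant,
        definition,
    )
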