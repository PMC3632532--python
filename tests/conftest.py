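from __future__ import annotations

import numpy as np
import pytest

from bacv import (
    FixtureSpec,
    SignalSpec,
    assign_types,
    make_acv_dataset,
    make_planar_fixture,
    make_random_complex,
)


def pdb_line(serial, name, resname, chain, resseq, x, y, z, element,
             altloc=" ", occ=1.00, record="ATOM") -> str:
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc}{resname:>3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.00:6.2f}          {element:>2}"
    )


@pytest.fixture
def messy_pdb(tmp_path):
    """A 2-chain PDB with water, a Zn HETATM, hydrogens and an altloc pair."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
        pdb_line(3, "C", "ALA", "A", 1, 2.2, 1.3, 0.0, "C"),
        pdb_line(4, "O", "ALA", "A", 1, 1.6, 2.3, 0.0, "O"),
        # altloc: B copy has the higher occupancy and must win
        pdb_line(5, "CB", "ALA", "A", 1, 2.0, -1.0, 1.0, "C", altloc="A", occ=0.4),
        pdb_line(6, "CB", "ALA", "A", 1, 2.1, -1.1, 1.1, "C", altloc="B", occ=0.6),
        pdb_line(7, "HA", "ALA", "A", 1, 1.5, -0.5, -0.8, "H"),
        pdb_line(8, "N", "GLY", "B", 1, 0.0, 4.0, 0.0, "N"),
        pdb_line(9, "CA", "GLY", "B", 1, 1.4, 4.2, 0.0, "C"),
        pdb_line(10, "C", "GLY", "B", 1, 2.2, 5.4, 0.5, "C"),
        pdb_line(11, "O", "GLY", "B", 1, 3.4, 5.3, 0.7, "O"),
        pdb_line(12, "O", "HOH", "B", 90, 5.0, 5.0, 5.0, "O", record="HETATM"),
        pdb_line(13, "ZN", "ZN", "B", 91, 6.0, 6.0, 6.0, "ZN", record="HETATM"),
        "END",
    ]
    path = tmp_path / "messy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def planar():
    """The hand-analysed 7-atom fixture and its expected contact sets."""
    return make_planar_fixture()


@pytest.fixture
def random_complex():
    return make_random_complex(FixtureSpec(n_per_side=40, seed=7))


@pytest.fixture
def typed_random_complex(random_complex):
    return assign_types(random_complex)


@pytest.fixture
def planted_dataset():
    """200-sample, 235-feature count dataset with 5 informative slots."""
    return make_acv_dataset(SignalSpec(n_per_class=100, seed=11))


@pytest.fixture
def small_planted_dataset():
    """Smaller, lower-dimensional planted dataset for fast classifier tests."""
    return make_acv_dataset(
        SignalSpec(n_per_class=30, n_features=40, informative=(3, 17, 29), seed=5)
    )


def rigid_motion(coords: np.ndarray, seed: int) -> np.ndarray:
    """A random rotation + translation (proper orthogonal, det +1)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return coords @ q.T + t
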