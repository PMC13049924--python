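"""Shared fixtures: hand-built PDB text and toy structures."""

import numpy as np
import pytest

from peroxidyn import synthetic as syn


def pdb_line(
    serial, name, resname, chain, resid, x, y, z,
    occ=1.0, element="C", altloc=" ", hetero=False,
):
    record = "HETATM" if hetero else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s}{altloc}{resname:<3s} {chain}"
        f"{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


# GLY (4 backbone atoms) + SER (6) + HIS (10) = 20 atoms, hand-counted.
TRIPEPTIDE_ATOMS = [
    # name, resname, resid, xyz, element
    ("N", "GLY", 1, (0.0, 0.0, 0.0), "N"),
    ("CA", "GLY", 1, (1.5, 0.4, 0.2), "C"),
    ("C", "GLY", 1, (2.6, -0.5, 0.1), "C"),
    ("O", "GLY", 1, (2.6, -1.7, 0.3), "O"),
    ("N", "SER", 2, (3.8, 0.0, 0.0), "N"),
    ("CA", "SER", 2, (5.0, -0.6, 0.2), "C"),
    ("C", "SER", 2, (6.2, 0.3, 0.1), "C"),
    ("O", "SER", 2, (6.2, 1.5, 0.3), "O"),
    ("CB", "SER", 2, (5.1, -1.6, 1.3), "C"),
    ("OG", "SER", 2, (5.2, -2.9, 0.8), "O"),
    ("N", "HIS", 3, (7.4, -0.3, 0.0), "N"),
    ("CA", "HIS", 3, (8.6, 0.5, 0.2), "C"),
    ("C", "HIS", 3, (9.8, -0.4, 0.1), "C"),
    ("O", "HIS", 3, (9.8, -1.6, 0.3), "O"),
    ("CB", "HIS", 3, (8.7, 1.5, 1.3), "C"),
    ("CG", "HIS", 3, (9.9, 2.4, 1.2), "C"),
    ("ND1", "HIS", 3, (11.1, 2.0, 1.7), "N"),
    ("CD2", "HIS", 3, (10.0, 3.7, 0.8), "C"),
    ("CE1", "HIS", 3, (12.0, 3.0, 1.5), "C"),
    ("NE2", "HIS", 3, (11.3, 4.1, 0.9), "N"),
]

N_TRIPEPTIDE_ATOMS = 20
N_TRIPEPTIDE_RESIDUES = 3


@pytest.fixture
def tripeptide_path(tmp_path):
    lines = [
        pdb_line(i + 1, name, resname, "A", resid, *xyz, element=element)
        for i, (name, resname, resid, xyz, element) in enumerate(TRIPEPTIDE_ATOMS)
    ]
    path = tmp_path / "tripeptide.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture(scope="session")
def toy_small():
    return syn.build_toy_topology(5)


@pytest.fixture(scope="session")
def toy_polar():
    return syn.build_toy_topology(6, polar_sidechains=True)


@pytest.fixture(scope="session")
def toy_cofactors():
    return syn.build_toy_topology(12, with_cofactors=True, polar_sidechains=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
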