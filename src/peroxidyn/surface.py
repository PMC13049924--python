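"""Solvent-accessible surface area and the charged-residue census.

SASA uses the Shrake–Rupley sphere-point quadrature with a deterministic
Fibonacci-lattice point set (probe radius 1.4 Å, 960 points by default).
Surface residues are those whose summed SASA exceeds a threshold (default
2.5 Å², the convention of the published surface-residue script this mirrors),
and the census counts charged residues — R, D, E, H, K — over the whole
protein and over the surface subset. Histidine is counted in the positive
total but also reported separately, its charge being pH-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import RadiusError
from .structures import Topology

#: Van der Waals radii, Å (Bondi-style defaults; override via ``radii_table``).
DEFAULT_VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}

DEFAULT_PROBE_RADIUS = 1.4  # Å
DEFAULT_N_POINTS = 960

NEGATIVE_RESIDUES = ("ASP", "GLU")
POSITIVE_RESIDUES = ("ARG", "LYS", "HIS")
CHARGED_RESIDUES = NEGATIVE_RESIDUES + POSITIVE_RESIDUES
_ONE_LETTER = {"ARG": "R", "ASP": "D", "GLU": "E", "HIS": "H", "LYS": "K"}


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n_points, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas, Å²."""

    per_atom: np.ndarray
    per_residue: dict  # residue key -> summed member-atom SASA
    probe_radius: float
    quadrature_points: int


def _resolve_radii(
    topology: Topology,
    radii_table: dict[str, float],
    fallback_radius: float | None,
) -> np.ndarray:
    radii = np.empty(topology.n_atoms)
    for i, atom in enumerate(topology.atoms):
        key = atom.element.strip().upper()
        if key in radii_table:
            radii[i] = radii_table[key]
        elif fallback_radius is not None:
            radii[i] = fallback_radius
        else:
            raise RadiusError(
                f"no van der Waals radius for element {key!r} (atom {atom.name})"
            )
    return radii


def shrake_rupley_sasa(
    topology: Topology,
    frame: np.ndarray,
    radii_table: dict[str, float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    fallback_radius: float | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of one structure frame.

    Each atom is covered by ``n_points`` quadrature points on its solvent
    sphere (vdW radius + probe); points inside any neighbor's solvent sphere
    are occluded and the accessible area is the unoccluded fraction of the
    sphere area. Deterministic for a fixed point count.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ValueError(f"frame shape {frame.shape} does not match topology")
    radii = _resolve_radii(topology, radii_table or DEFAULT_VDW_RADII, fallback_radius)
    solvent_radii = radii + probe_radius
    unit_points = fibonacci_sphere(n_points)

    tree = cKDTree(frame)
    max_reach = 2.0 * solvent_radii.max()
    per_atom = np.empty(topology.n_atoms)
    for i in range(topology.n_atoms):
        points = frame[i] + solvent_radii[i] * unit_points
        neighbor_ids = [
            j for j in tree.query_ball_point(frame[i], max_reach) if j != i
        ]
        if neighbor_ids:
            neighbors = np.asarray(neighbor_ids, dtype=int)
            d = np.linalg.norm(
                points[:, None, :] - frame[neighbors][None, :, :], axis=2
            )
            accessible = np.all(d >= solvent_radii[neighbors][None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * solvent_radii[i] ** 2

    per_residue: dict = {}
    for key, atom_positions in topology.residue_index.items():
        per_residue[key] = float(per_atom[atom_positions].sum())
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        probe_radius=probe_radius,
        quadrature_points=n_points,
    )


def classify_surface_residues(
    sasa: SasaResult, residue_threshold: float = 2.5
) -> set:
    """Residues whose summed SASA exceeds the threshold (default 2.5 Å²)."""
    return {
        key for key, area in sasa.per_residue.items() if area > residue_threshold
    }


@dataclass
class SurfaceCensus:
    """Counts of charged residues (R/D/E/H/K) over a residue set."""

    counts: dict  # one-letter code -> count
    negative_total: int  # D + E
    positive_total: int  # R + K + H (H pH-dependent, also reported alone)
    net: int
    n_residues: int
    other: list  # nonstandard residue names encountered


def charged_residue_census(
    topology: Topology, residue_subset: set | None = None
) -> SurfaceCensus:
    """Charged-residue census over all residues or a (surface) subset.

    Hetero residues (cofactors, substrate) are not part of the census; any
    nonstandard polymer residue name is tallied under ``other``.
    """
    counts = {code: 0 for code in _ONE_LETTER.values()}
    other: list = []
    n_residues = 0
    standard = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    for key, atom_positions in topology.residue_index.items():
        first = topology.atoms[atom_positions[0]]
        if first.is_hetero:
            continue
        if residue_subset is not None and key not in residue_subset:
            continue
        n_residues += 1
        name = first.residue_name.upper()
        if name in _ONE_LETTER:
            counts[_ONE_LETTER[name]] += 1
        elif name not in standard:
            other.append(name)
    negative = counts["D"] + counts["E"]
    positive = counts["R"] + counts["K"] + counts["H"]
    return SurfaceCensus(
        counts=counts,
        negative_total=negative,
        positive_total=positive,
        net=positive - negative,
        n_residues=n_residues,
        other=other,
    )
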