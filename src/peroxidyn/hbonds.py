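"""Geometric hydrogen-bond detection, occupancies, differential networks.

A hydrogen bond is present when the donor–acceptor heavy-atom distance is at
most 3.0 Å and the D–H–A angle deviates from linearity by at most 20°
(i.e. the angle at the hydrogen is ≥ 160°). Donors are N/O atoms carrying a
covalently assigned hydrogen (within 1.2 Å in the reference frame);
acceptors are all N/O atoms, which lets heme propionates and the substrate
carboxylate participate under the same rules. Occupancy is the fraction of
frames in which a residue pair shows at least one detected bond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Topology, TrajectoryEnsemble

DEFAULT_DISTANCE_CUTOFF = 3.0  # Å, donor to acceptor heavy atom
DEFAULT_ANGLE_CUTOFF = 20.0  # degrees of deviation from D-H-A linearity
DEFAULT_COVALENT_CUTOFF = 1.2  # Å, H assignment to its donor

_POLAR_ELEMENTS = ("N", "O")


@dataclass(frozen=True)
class HBondTriad:
    """Donor, hydrogen and acceptor atom indices of one detected bond."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int


@dataclass
class DonorAcceptorCatalog:
    """Deterministic donor (with hydrogens) and acceptor listings."""

    donor_pairs: list[tuple[int, int]]  # (donor heavy atom, hydrogen)
    acceptors: np.ndarray  # indices of acceptor heavy atoms

    def donors_by_atom(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for d, h in self.donor_pairs:
            out.setdefault(d, []).append(h)
        return out


def assign_donors_acceptors(
    topology: Topology,
    reference_frame: np.ndarray,
    covalent_cutoff: float = DEFAULT_COVALENT_CUTOFF,
    polar_elements: tuple[str, ...] = _POLAR_ELEMENTS,
) -> DonorAcceptorCatalog:
    """Build donor/acceptor catalogs from the reference geometry.

    Emits a warning and an empty donor list when the topology carries no
    hydrogens (detection then finds no bonds, by construction).
    """
    elements = np.char.upper(topology.elements.astype(str))
    polar = np.flatnonzero(np.isin(elements, polar_elements))
    hydrogens = np.flatnonzero(topology.hydrogen_mask)
    acceptors = polar.copy()
    if hydrogens.size == 0:
        warnings.warn(
            "topology has no hydrogens: donor catalog is empty",
            RuntimeWarning,
            stacklevel=2,
        )
        return DonorAcceptorCatalog(donor_pairs=[], acceptors=acceptors)
    reference_frame = np.asarray(reference_frame, dtype=float)
    tree = cKDTree(reference_frame[hydrogens])
    donor_pairs: list[tuple[int, int]] = []
    for d in polar:
        near = tree.query_ball_point(reference_frame[d], covalent_cutoff)
        for h_local in sorted(near):
            donor_pairs.append((int(d), int(hydrogens[h_local])))
    donor_pairs.sort()
    return DonorAcceptorCatalog(donor_pairs=donor_pairs, acceptors=acceptors)


def _angle_deviation_deg(
    donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray
) -> float:
    """Deviation of the D-H-A angle from linearity (0 = perfectly linear)."""
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return 180.0 - angle


def detect_hbonds_frame(
    frame: np.ndarray,
    catalog: DonorAcceptorCatalog,
    topology: Topology,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    exclude_intra_residue: bool = True,
) -> set[HBondTriad]:
    """Hydrogen bonds present in a single frame (an empty set is valid)."""
    frame = np.asarray(frame, dtype=float)
    if catalog.acceptors.size == 0 or not catalog.donor_pairs:
        return set()
    acc_tree = cKDTree(frame[catalog.acceptors])
    residue_keys = topology.residue_keys_per_atom()
    found: set[HBondTriad] = set()
    for d, h in catalog.donor_pairs:
        near = acc_tree.query_ball_point(frame[d], distance_cutoff)
        for a_local in near:
            a = int(catalog.acceptors[a_local])
            if a == d:
                continue
            if exclude_intra_residue and residue_keys[a] == residue_keys[d]:
                continue
            if _angle_deviation_deg(frame[d], frame[h], frame[a]) <= angle_cutoff:
                found.add(HBondTriad(d, h, a))
    return found


def _pair_key(topology: Topology, donor: int, acceptor: int):
    """Unordered residue-pair key, each side (chain, resid, icode, resname)."""
    atoms = topology.atoms
    sides = []
    for idx in (donor, acceptor):
        a = atoms[idx]
        sides.append((a.chain_id, a.residue_id, a.insertion_code, a.residue_name))
    return tuple(sorted(sides))


@dataclass
class HBondOccupancyTable:
    """Residue-pair hydrogen-bond occupancies for one condition."""

    condition: str
    n_frames: int
    occupancy: dict  # pair key -> fraction of frames with >= 1 triad
    triads: dict = field(default_factory=dict)  # pair key -> set of HBondTriad

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, occ in sorted(self.occupancy.items()):
            (c1, r1, i1, n1), (c2, r2, i2, n2) = pair
            rows.append(
                {
                    "residue_1": f"{n1}{r1}{i1}:{c1}",
                    "residue_2": f"{n2}{r2}{i2}:{c2}",
                    "occupancy": occ,
                    "condition": self.condition,
                    "n_frames": self.n_frames,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["residue_1", "residue_2", "occupancy", "condition", "n_frames"],
        )


def hbond_occupancy(
    trajectory,
    topology: Topology,
    catalog: DonorAcceptorCatalog,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    condition: str = "default",
    exclude_intra_residue: bool = True,
) -> HBondOccupancyTable:
    """Per-residue-pair occupancy over trajectory frames.

    ``trajectory`` is an (F, N, 3) array, a :class:`TrajectoryEnsemble` or a
    pseudotrajectory; pairs never satisfied are absent from the table.
    """
    from .pseudotrajectory import Pseudotrajectory

    if isinstance(trajectory, TrajectoryEnsemble):
        frames = trajectory.frames
    elif isinstance(trajectory, Pseudotrajectory):
        frames = trajectory.frames
    else:
        frames = np.asarray(trajectory, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames = frames.shape[0]
    counts: dict = {}
    triads: dict = {}
    for f in range(n_frames):
        detected = detect_hbonds_frame(
            frames[f], catalog, topology, distance_cutoff, angle_cutoff,
            exclude_intra_residue,
        )
        pairs_this_frame = set()
        for triad in detected:
            key = _pair_key(topology, triad.donor_atom, triad.acceptor_atom)
            pairs_this_frame.add(key)
            triads.setdefault(key, set()).add(triad)
        for key in pairs_this_frame:
            counts[key] = counts.get(key, 0) + 1
    occupancy = {key: counts[key] / n_frames for key in counts}
    return HBondOccupancyTable(
        condition=condition, n_frames=n_frames, occupancy=occupancy, triads=triads
    )


@dataclass(frozen=True)
class DifferentialEdge:
    """One residue pair whose occupancy differs between two conditions."""

    pair: tuple
    delta_occupancy: float  # condition A minus condition B
    enriched_condition: str


def differential_network(
    table_a: HBondOccupancyTable,
    table_b: HBondOccupancyTable,
    delta_threshold: float = 0.25,
) -> list[DifferentialEdge]:
    """Residue pairs switching occupancy between two conditions.

    Pairs absent from one table count as occupancy 0 there. An edge is
    emitted when |occ_A − occ_B| ≥ ``delta_threshold`` and is tagged with the
    condition in which it is enriched. Swapping A and B flips every tag and
    negates every Δ.
    """
    if not (0.0 < delta_threshold <= 1.0):
        raise ValueError(f"delta_threshold must be in (0, 1], got {delta_threshold}")
    pairs = set(table_a.occupancy) | set(table_b.occupancy)
    edges: list[DifferentialEdge] = []
    for pair in sorted(pairs):
        occ_a = table_a.occupancy.get(pair, 0.0)
        occ_b = table_b.occupancy.get(pair, 0.0)
        delta = occ_a - occ_b
        if abs(delta) >= delta_threshold:
            enriched = table_a.condition if delta > 0 else table_b.condition
            edges.append(DifferentialEdge(pair, delta, enriched))
    return edges


def edges_to_frame(edges: list[DifferentialEdge]) -> pd.DataFrame:
    """Plain edge-table export (source, target, Δoccupancy, enriched condition)."""
    rows = []
    for e in edges:
        (c1, r1, i1, n1), (c2, r2, i2, n2) = e.pair
        rows.append(
            {
                "source": f"{n1}{r1}{i1}:{c1}",
                "target": f"{n2}{r2}{i2}:{c2}",
                "delta_occupancy": e.delta_occupancy,
                "enriched_condition": e.enriched_condition,
            }
        )
    return pd.DataFrame(
        rows, columns=["source", "target", "delta_occupancy", "enriched_condition"]
    )
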