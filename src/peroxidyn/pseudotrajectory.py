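"""Medoid ordering, morph-interpolated pseudotrajectories, and Cα RMSF.

A pseudotrajectory strings the conformational-state medoids together in a
nearest-neighbor order over their RMSD matrix, superposes each medoid onto
its predecessor to suppress rigid-body drift, and inserts linearly
interpolated frames between successive medoids in proportion to the RMSD
separating them. The resulting geometric morph (its frames carry no physical
time) is the input for per-residue RMSF profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import kabsch_superpose
from .structures import (
    BACKBONE_HEAVY,
    SelectionSpec,
    Topology,
    TrajectoryEnsemble,
    select_atoms,
)


def nearest_neighbor_order(
    matrix: np.ndarray, start: int = 0
) -> list[int]:
    """Greedy nearest-neighbor traversal of a symmetric RMSD matrix.

    From the current medoid the next one is the unvisited medoid with the
    smallest RMSD; ties break to the lowest index. Every medoid is visited
    exactly once.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"RMSD matrix must be square, got {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("RMSD matrix must be symmetric")
    n = matrix.shape[0]
    if not (0 <= start < n):
        raise ValueError(f"start index {start} outside 0..{n - 1}")
    visited = [start]
    remaining = set(range(n)) - {start}
    while remaining:
        current = visited[-1]
        # lowest index among the unvisited minimizers
        candidates = sorted(remaining)
        dists = [matrix[current, c] for c in candidates]
        nxt = candidates[int(np.argmin(dists))]
        visited.append(nxt)
        remaining.discard(nxt)
    return visited


def interpolation_frame_count(
    distance: float, frames_per_angstrom: float, min_frames: int = 1
) -> int:
    """Number of interpolated frames between two medoids at RMSD ``distance``.

    Zero-distance pairs get no interpolation; otherwise the count is
    ``max(min_frames, ceil(frames_per_angstrom · distance))``.
    """
    if frames_per_angstrom <= 0:
        raise ValueError("frames_per_angstrom must be positive")
    if distance <= 1e-12:
        return 0
    return max(min_frames, math.ceil(frames_per_angstrom * distance))


@dataclass
class Pseudotrajectory:
    """Ordered morph frames with per-frame provenance.

    Provenance tags are ``("medoid", cluster_id)`` for medoid frames and
    ``("interp", cluster_i, cluster_j, t)`` for frames interpolated at
    fraction ``t`` between the (aligned) medoids of clusters i and j.
    """

    frames: np.ndarray  # (F, N, 3), Å
    provenance: list[tuple]
    ordering: list[int]  # visited cluster ids

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def build_pseudotrajectory(
    ensemble: TrajectoryEnsemble,
    decomposition_ordering: list[int],
    medoid_frame_index: dict[int, int],
    rmsd_spec: SelectionSpec,
    frames_per_angstrom: float = 10.0,
    min_frames: int = 1,
) -> Pseudotrajectory:
    """Assemble the interpolated pseudotrajectory for a medoid visit order.

    Parameters
    ----------
    decomposition_ordering : cluster ids in visit order (e.g. from
        :func:`nearest_neighbor_order` mapped back to cluster ids).
    medoid_frame_index : cluster id -> ensemble frame index of its medoid.
    rmsd_spec : selection used both for the drift-reducing superposition of
        each medoid onto its predecessor and for the RMSD that scales the
        interpolated frame count.
    """
    if not decomposition_ordering:
        raise ValueError("empty medoid ordering")
    rmsd_idx = select_atoms(ensemble.topology, rmsd_spec)

    first_cluster = decomposition_ordering[0]
    aligned_medoids = [ensemble.frames[medoid_frame_index[first_cluster]].copy()]
    distances: list[float] = []
    for cluster in decomposition_ordering[1:]:
        prev = aligned_medoids[-1]
        raw = ensemble.frames[medoid_frame_index[cluster]]
        _, moved, rmsd = kabsch_superpose(raw, prev, rmsd_idx)
        aligned_medoids.append(moved)
        distances.append(rmsd)

    frames: list[np.ndarray] = [aligned_medoids[0]]
    provenance: list[tuple] = [("medoid", first_cluster)]
    for seg, cluster in enumerate(decomposition_ordering[1:]):
        a = aligned_medoids[seg]
        b = aligned_medoids[seg + 1]
        prev_cluster = decomposition_ordering[seg]
        m = interpolation_frame_count(distances[seg], frames_per_angstrom, min_frames)
        for step in range(1, m + 1):
            t = step / (m + 1)
            frames.append((1.0 - t) * a + t * b)
            provenance.append(("interp", prev_cluster, cluster, t))
        frames.append(b)
        provenance.append(("medoid", cluster))
    return Pseudotrajectory(
        frames=np.asarray(frames), provenance=provenance,
        ordering=list(decomposition_ordering),
    )


@dataclass
class RmsfProfile:
    """Per-residue Cα root-mean-square fluctuation, Å."""

    per_residue: dict  # residue key (chain, resid, icode) -> RMSF

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        keys = sorted(self.per_residue, key=lambda k: (k[0], k[1], k[2]))
        return (
            np.array([k[1] for k in keys]),
            np.array([self.per_residue[k] for k in keys]),
        )


def rmsf_calpha(
    frames: np.ndarray | Pseudotrajectory | TrajectoryEnsemble,
    topology: Topology,
    fit_spec: SelectionSpec = BACKBONE_HEAVY,
    mean_passes: int = 2,
) -> RmsfProfile:
    """Per-residue Cα RMSF after removing global motion.

    Frames are superposed onto an iterated mean structure (``mean_passes``
    alignment/mean rounds, default 2) over the fit selection before the
    deviations are accumulated. Residues without a Cα atom are excluded with
    a warning.
    """
    if isinstance(frames, Pseudotrajectory):
        coords = frames.frames
    elif isinstance(frames, TrajectoryEnsemble):
        coords = frames.frames
    else:
        coords = np.asarray(frames, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames of (F, N, 3) coordinates")
    fit_idx = select_atoms(topology, fit_spec)

    aligned = coords.copy()
    reference = aligned[0]
    for _ in range(mean_passes):
        for f in range(aligned.shape[0]):
            _, aligned[f], _ = kabsch_superpose(aligned[f], reference, fit_idx)
        reference = aligned.mean(axis=0)

    mean_structure = aligned.mean(axis=0)
    sq_dev = np.sum((aligned - mean_structure) ** 2, axis=2)  # (F, N)
    per_atom_rmsf = np.sqrt(sq_dev.mean(axis=0))

    per_residue: dict = {}
    missing = []
    for key, atom_positions in topology.residue_index.items():
        ca = [
            i for i in atom_positions
            if topology.atoms[i].name == "CA" and not topology.atoms[i].is_hetero
        ]
        if not ca:
            missing.append(key)
            continue
        per_residue[key] = float(per_atom_rmsf[ca[0]])
    if missing:
        warnings.warn(
            f"{len(missing)} residue(s) without a CA atom excluded from RMSF",
            RuntimeWarning,
            stacklevel=2,
        )
    return RmsfProfile(per_residue=per_residue)
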