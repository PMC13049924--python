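"""Substrate-positioning z-score and per-residue coupling profiles.

Substrate positioning in the active site is summarized per frame by two
descriptors: the heme iron to substrate Cβ distance and the Cα–Cβ–Fe angle
(vertex at Cβ). Each descriptor is standardized over the frames of one
condition and the combined z-score is their equal-weight mean by default.
The coupling profile is the per-residue Pearson correlation between the
frame-wise Cα displacement magnitude (from the ensemble mean position, on an
aligned ensemble) and the z series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, ShapeMismatchError
from .structures import TrajectoryEnsemble


@dataclass
class ReactionGeometrySeries:
    """Per-frame Fe–Cβ distance (Å) and Cα–Cβ–Fe angle (degrees)."""

    fe_cbeta_distance: np.ndarray
    calpha_cbeta_fe_angle: np.ndarray

    def __post_init__(self):
        self.fe_cbeta_distance = np.asarray(self.fe_cbeta_distance, dtype=float)
        self.calpha_cbeta_fe_angle = np.asarray(
            self.calpha_cbeta_fe_angle, dtype=float
        )
        if self.fe_cbeta_distance.shape != self.calpha_cbeta_fe_angle.shape:
            raise ShapeMismatchError("distance and angle series differ in length")
        if np.any(self.fe_cbeta_distance <= 0):
            raise ValueError("Fe-Cβ distances must be positive")
        if np.any((self.calpha_cbeta_fe_angle < 0) | (self.calpha_cbeta_fe_angle > 180)):
            raise ValueError("angles must lie in [0°, 180°]")

    @property
    def n_frames(self) -> int:
        return self.fe_cbeta_distance.shape[0]


def angle_at_vertex(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees at ``vertex`` between rays toward ``a`` and ``b``."""
    v1 = np.asarray(a, float) - np.asarray(vertex, float)
    v2 = np.asarray(b, float) - np.asarray(vertex, float)
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def reaction_geometry_series(
    ensemble: TrajectoryEnsemble,
    fe_atom: int | None = None,
    calpha_atom: int | None = None,
    cbeta_atom: int | None = None,
    heme_resname: str = "HEM",
    substrate_resname: str = "PLM",
) -> ReactionGeometrySeries:
    """Per-frame substrate-positioning descriptors.

    Atom indices may be given explicitly; otherwise FE is looked up in the
    heme residue and CA/CB in the substrate residue (raising a lookup error
    naming the missing atom).
    """
    top = ensemble.topology
    fe = top.find_atom(heme_resname, "FE") if fe_atom is None else fe_atom
    ca = top.find_atom(substrate_resname, "CA") if calpha_atom is None else calpha_atom
    cb = top.find_atom(substrate_resname, "CB") if cbeta_atom is None else cbeta_atom

    diff = ensemble.frames[:, fe, :] - ensemble.frames[:, cb, :]
    distances = np.linalg.norm(diff, axis=1)
    angles = np.array(
        [
            angle_at_vertex(
                ensemble.frames[f, ca], ensemble.frames[f, cb], ensemble.frames[f, fe]
            )
            for f in range(ensemble.n_frames)
        ]
    )
    return ReactionGeometrySeries(distances, angles)


@dataclass
class CouplingSeries:
    """Standardized substrate-positioning score per frame."""

    z: np.ndarray
    z_distance: np.ndarray
    z_angle: np.ndarray


def _standardize(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=0)
    if sd <= 1e-12:
        raise DegenerateSeriesError(f"{what} series has zero variance")
    return (values - values.mean()) / sd


def combined_zscore(
    series: ReactionGeometrySeries,
    weights: tuple[float, float] = (0.5, 0.5),
) -> CouplingSeries:
    """Equal-weight (by default) mean of the standardized descriptors.

    Larger z means larger Fe–Cβ distance and larger angle relative to the
    series means; the weights are configurable but must sum to a nonzero
    total.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to standardize")
    w = np.asarray(weights, dtype=float)
    if w.shape != (2,) or abs(w.sum()) < 1e-12:
        raise ValueError("weights must be two numbers with nonzero sum")
    z_d = _standardize(series.fe_cbeta_distance, "Fe-Cβ distance")
    z_a = _standardize(series.calpha_cbeta_fe_angle, "Cα-Cβ-Fe angle")
    z = (w[0] * z_d + w[1] * z_a) / w.sum()
    return CouplingSeries(z=z, z_distance=z_d, z_angle=z_a)


@dataclass
class CouplingProfile:
    """Per-residue Pearson correlation with the substrate z-score."""

    per_residue: dict  # residue key (chain, resid, icode) -> r
    n_frames: int

    def argmax_residue(self):
        return max(self.per_residue, key=lambda k: self.per_residue[k])

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        keys = sorted(self.per_residue, key=lambda k: (k[0], k[1], k[2]))
        return (
            np.array([k[1] for k in keys]),
            np.array([self.per_residue[k] for k in keys]),
        )


def residue_coupling_profile(
    ensemble: TrajectoryEnsemble,
    coupling: CouplingSeries | np.ndarray,
) -> CouplingProfile:
    """Correlate per-residue Cα motion with the substrate z-score.

    The ensemble must already be aligned (global motion removed): the residue
    motion statistic is the per-frame Cα displacement magnitude from the
    ensemble-mean Cα position. Residues without a Cα (cofactors, substrate)
    are excluded.
    """
    z = coupling.z if isinstance(coupling, CouplingSeries) else np.asarray(coupling)
    if z.shape[0] != ensemble.n_frames:
        raise ShapeMismatchError(
            f"z series has {z.shape[0]} frames, ensemble has {ensemble.n_frames}"
        )
    top = ensemble.topology
    z_centered = z - z.mean()
    z_norm = np.linalg.norm(z_centered)
    per_residue: dict = {}
    for key, atom_positions in top.residue_index.items():
        ca = [
            i for i in atom_positions
            if top.atoms[i].name == "CA" and not top.atoms[i].is_hetero
        ]
        if not ca:
            continue
        traj = ensemble.frames[:, ca[0], :]
        disp = np.linalg.norm(traj - traj.mean(axis=0), axis=1)
        disp_centered = disp - disp.mean()
        denom = np.linalg.norm(disp_centered) * z_norm
        r = 0.0 if denom < 1e-15 else float(np.dot(disp_centered, z_centered) / denom)
        per_residue[key] = r
    return CouplingProfile(per_residue=per_residue, n_frames=ensemble.n_frames)
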