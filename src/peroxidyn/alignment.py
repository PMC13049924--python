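"""Rigid-body superposition (Kabsch) and ensemble alignment.

Superposition minimizes the RMSD over a fit selection by the closed-form SVD
solution, with reflections excluded; the same rotation/translation is applied
to all atoms of the mobile frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateFitError
from .structures import BACKBONE_HEAVY, SelectionSpec, TrajectoryEnsemble, select_atoms


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (proper, det=+1) and translation applied as ``x @ R.T + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError(
            f"need at least 3 fit atoms, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    # collinear point sets have rank < 2 after centering
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[RigidTransform, np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (N, 3) arrays in Å.
    fit_indices : atoms over which the fit (and the returned RMSD) is computed;
        the transform is applied to every atom of ``mobile``.

    Returns
    -------
    (transform, transformed_mobile, rmsd_over_fit_atoms)
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    mob_fit = mobile[fit_indices]
    ref_fit = reference[fit_indices]
    if mob_fit.shape != ref_fit.shape:
        raise DegenerateFitError("fit selections differ in size")
    _check_fit_atoms(mob_fit)
    _check_fit_atoms(ref_fit)

    mob_center = mob_fit.mean(axis=0)
    ref_center = ref_fit.mean(axis=0)
    h = (mob_fit - mob_center).T @ (ref_fit - ref_center)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_center - rotation @ mob_center
    transform = RigidTransform(rotation, translation)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved[fit_indices] - ref_fit) ** 2, axis=1))))
    return transform, moved, rmsd


def superposed_rmsd(
    frame_a: np.ndarray, frame_b: np.ndarray, indices: np.ndarray
) -> float:
    """Minimal RMSD between two frames over ``indices`` after superposition."""
    _, _, rmsd = kabsch_superpose(frame_a[indices], frame_b[indices], None)
    return rmsd


def align_ensemble(
    ensemble: TrajectoryEnsemble,
    reference_frame: int = 0,
    fit_spec: SelectionSpec = BACKBONE_HEAVY,
) -> TrajectoryEnsemble:
    """Superpose every frame onto a reference frame over the fit selection.

    The default fit selection is the protein backbone heavy atoms; non-fit
    atoms (sidechains, cofactors, substrate) are carried by the same rigid
    transform. Aligning an already-aligned ensemble is a fixed point.
    """
    fit_idx = select_atoms(ensemble.topology, fit_spec)
    reference = ensemble.frames[reference_frame]
    aligned = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        _, moved, _ = kabsch_superpose(ensemble.frames[f], reference, fit_idx)
        aligned[f] = moved
    return ensemble.with_frames(aligned)
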