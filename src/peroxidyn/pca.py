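"""Essential dynamics: trajectory PCA and the composite per-residue score.

The analysis operates on the flattened (3N-dimensional) coordinates of an
atom selection — by default all heavy atoms — of an aligned ensemble. The
covariance uses the unbiased (F−1) denominator, and components are retained
up to a cumulative-variance target (default 75%).

The per-atom essential-dynamics score is a temperature-factor-like quantity

    B_a = (8π²/3) · Σ_{k ≤ K} λ_k · ‖v_{k,a}‖²   [Å²]

where λ_k are the retained eigenvalues and v_{k,a} the atom's 3-component
block of the k-th unit loading vector; residue scores average B_a over the
residue's analysis atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA
from sklearn.utils.validation import check_is_fitted

from .exceptions import InsufficientFramesError, UndefinedScoreError
from .structures import (
    HEAVY_ATOMS,
    SelectionSpec,
    Topology,
    TrajectoryEnsemble,
    select_atoms,
)

B_FACTOR_SCALE = 8.0 * np.pi**2 / 3.0


def _as_feature_matrix(X, selection, out_indices=False):
    """Flatten an ensemble (or accept a ready (F, 3N) matrix)."""
    if isinstance(X, TrajectoryEnsemble):
        idx = select_atoms(X.topology, selection) if selection is not None else np.arange(X.n_atoms)
        mat = X.frames[:, idx, :].reshape(X.n_frames, -1)
        return (mat, idx) if out_indices else mat
    mat = np.asarray(X, dtype=float)
    if mat.ndim != 2:
        raise ValueError(f"expected (F, 3N) matrix, got shape {mat.shape}")
    return (mat, None) if out_indices else mat


class TrajectoryPCA(TransformerMixin, BaseEstimator):
    """PCA of trajectory coordinates with cumulative-variance truncation.

    Parameters
    ----------
    variance_target : float
        Retain the smallest number of components whose cumulative explained
        variance fraction reaches this target. If the total variance is zero
        the model keeps 0 components and warns.
    selection : SelectionSpec or None
        Atom selection applied when fitting on a :class:`TrajectoryEnsemble`
        (default: all heavy atoms). Ignored for plain matrices.

    Attributes
    ----------
    mean_ : (3N,) mean coordinates of the analysis selection, Å.
    eigenvalues_ : all covariance eigenvalues, Å², nonincreasing.
    components_ : (n_components, 3N) unit loading vectors; the sign is fixed
        so each vector's largest-magnitude entry is positive.
    cumulative_variance_ : cumulative explained-variance fractions.
    n_retained_ : number of components retained at the variance target.
    selection_indices_ : atom indices of the analysis selection (when fitted
        on an ensemble).
    """

    def __init__(
        self,
        variance_target: float = 0.75,
        selection: SelectionSpec | None = HEAVY_ATOMS,
    ):
        self.variance_target = variance_target
        self.selection = selection

    def fit(self, X, y=None):
        mat, idx = _as_feature_matrix(X, self.selection, out_indices=True)
        if mat.shape[0] < 2:
            raise InsufficientFramesError(
                f"PCA needs at least 2 frames, got {mat.shape[0]}"
            )
        self.selection_indices_ = idx
        pca = _SKPCA(n_components=None, svd_solver="full")
        pca.fit(mat)
        eigenvalues = np.asarray(pca.explained_variance_, dtype=float)
        components = np.asarray(pca.components_, dtype=float)
        # deterministic sign: largest-magnitude entry of each loading positive
        for k in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[k])))
            if components[k, j] < 0:
                components[k] *= -1.0
        self.mean_ = np.asarray(pca.mean_, dtype=float)
        self.eigenvalues_ = eigenvalues
        self.components_ = components
        total = float(eigenvalues.sum())
        # guard against numerically-nonzero eigenvalues of a constant input
        scale = max(1.0, float(np.mean(mat**2)))
        if total <= 1e-10 * scale:
            warnings.warn(
                "total variance is zero; retaining 0 components",
                RuntimeWarning,
                stacklevel=2,
            )
            self.cumulative_variance_ = np.zeros_like(eigenvalues)
            self.n_retained_ = 0
        else:
            self.cumulative_variance_ = np.cumsum(eigenvalues) / total
            k = int(
                np.searchsorted(self.cumulative_variance_, self.variance_target - 1e-12)
                + 1
            )
            self.n_retained_ = min(k, eigenvalues.size)
        self.n_features_in_ = mat.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Project frames onto the retained components -> (F, K) score table."""
        check_is_fitted(self, "components_")
        mat = _as_feature_matrix(X, self.selection)
        if mat.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: {mat.shape[1]} vs fitted {self.n_features_in_}"
            )
        centered = mat - self.mean_
        return centered @ self.components_[: self.n_retained_].T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        scores = np.asarray(scores, dtype=float)
        return self.mean_ + scores @ self.components_[: scores.shape[1]]


@dataclass
class EssentialDynamicsProfile:
    """Per-atom and per-residue essential-dynamics scores, Å²."""

    atom_indices: np.ndarray  # topology indices of the analysis atoms
    per_atom: np.ndarray  # (n_analysis_atoms,)
    per_residue: dict  # residue key (chain, resid, icode) -> score
    n_components: int


def essential_dynamics_score(
    model: TrajectoryPCA,
    topology: Topology | None = None,
    n_components: int | None = None,
) -> EssentialDynamicsProfile:
    """Composite per-residue score from a fitted :class:`TrajectoryPCA`.

    ``n_components`` overrides the model's retained count (e.g. to use every
    component, where the score reduces to 8π²/3 times each atom's total
    positional variance).
    """
    check_is_fitted(model, "components_")
    k = model.n_retained_ if n_components is None else int(n_components)
    if k < 1:
        raise UndefinedScoreError(
            "no retained components; essential-dynamics score undefined"
        )
    loadings = model.components_[:k].reshape(k, -1, 3)
    sq = np.sum(loadings**2, axis=2)  # (k, n_atoms)
    per_atom = B_FACTOR_SCALE * (model.eigenvalues_[:k, None] * sq).sum(axis=0)

    atom_indices = model.selection_indices_
    per_residue: dict = {}
    if topology is not None and atom_indices is not None:
        groups: dict = {}
        for pos, atom_idx in enumerate(atom_indices):
            key = topology.atoms[atom_idx].residue_key
            groups.setdefault(key, []).append(pos)
        per_residue = {
            key: float(np.mean(per_atom[pos_list])) for key, pos_list in groups.items()
        }
    return EssentialDynamicsProfile(
        atom_indices=atom_indices if atom_indices is not None else np.arange(per_atom.size),
        per_atom=per_atom,
        per_residue=per_residue,
        n_components=k,
    )


# -- thin functional wrappers -------------------------------------------------

def pca_heavy_atoms(
    ensemble: TrajectoryEnsemble,
    analysis_spec: SelectionSpec = HEAVY_ATOMS,
    variance_target: float = 0.75,
) -> TrajectoryPCA:
    """Fit heavy-atom PCA on an aligned ensemble to a variance target."""
    return TrajectoryPCA(variance_target=variance_target, selection=analysis_spec).fit(
        ensemble
    )


def project_frames(model: TrajectoryPCA, ensemble) -> np.ndarray:
    """Frame scores on the retained components (F × K)."""
    return model.transform(ensemble)
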