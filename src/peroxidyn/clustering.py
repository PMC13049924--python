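"""Conformational-state clustering in PC space and medoid structures.

Frames are clustered with HDBSCAN (Manhattan metric, leaf cluster selection)
on the first principal components; each cluster's medoid is the member frame
minimizing the mean pairwise RMSD to the other members, and a symmetric
medoid-to-medoid RMSD matrix over a structural selection feeds the
pseudotrajectory construction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN

from .alignment import superposed_rmsd
from .structures import SelectionSpec, TrajectoryEnsemble, select_atoms

logger = logging.getLogger(__name__)

NOISE_LABEL = -1


class ConformationalStateClusterer(ClusterMixin, BaseEstimator):
    """Density-based clustering of PC-space frames.

    Parameters
    ----------
    n_dimensions : int
        Number of leading PC columns used (default 20; fewer are used if the
        table is narrower).
    min_cluster_size, min_samples : int or None
        HDBSCAN density parameters. ``None`` selects the scale-free defaults
        ``max(10, ceil(0.05·F))`` and ``min_cluster_size`` respectively;
        leaf cluster selection needs a minimum size on the order of the
        smallest state population, or it fragments compact states into
        density-fluctuation leaves.
    metric, cluster_selection_method : str
        HDBSCAN settings; the defaults (manhattan / leaf) are the ones this
        pipeline is defined with.

    Attributes
    ----------
    labels_ : per-frame cluster id, with −1 marking noise frames.
    n_clusters_ : number of non-noise clusters.
    """

    def __init__(
        self,
        n_dimensions: int = 20,
        min_cluster_size: int | None = None,
        min_samples: int | None = None,
        metric: str = "manhattan",
        cluster_selection_method: str = "leaf",
    ):
        self.n_dimensions = n_dimensions
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.metric = metric
        self.cluster_selection_method = cluster_selection_method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError(f"PC table must be (F, K) with K >= 1, got {X.shape}")
        n_frames = X.shape[0]
        mcs = self.min_cluster_size
        if mcs is None:
            mcs = max(10, math.ceil(0.05 * n_frames))
        if n_frames < mcs:
            raise ValueError(
                f"{n_frames} frames is fewer than min_cluster_size={mcs}"
            )
        ms = self.min_samples if self.min_samples is not None else mcs
        cols = min(self.n_dimensions, X.shape[1])
        reduced = X[:, :cols]
        if np.allclose(reduced, reduced[0]):
            # degenerate: all frames identical in PC space -> one cluster
            self.labels_ = np.zeros(n_frames, dtype=int)
        else:
            model = HDBSCAN(
                min_cluster_size=mcs,
                min_samples=ms,
                metric=self.metric,
                cluster_selection_method=self.cluster_selection_method,
            )
            with warnings.catch_warnings():
                # sklearn 1.9 warns about its own future `copy` default
                warnings.simplefilter("ignore", FutureWarning)
                self.labels_ = model.fit_predict(reduced)
        self.n_clusters_ = int(len(set(self.labels_) - {NOISE_LABEL}))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_pc_space(
    pc_table: np.ndarray,
    n_components_used: int = 20,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
) -> np.ndarray:
    """Functional wrapper: HDBSCAN labels for a (F, K) PC score table."""
    return ConformationalStateClusterer(
        n_dimensions=n_components_used,
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
    ).fit_predict(pc_table)


def _pairwise_rmsd_submatrix(
    frames: np.ndarray, indices: np.ndarray, rmsd_idx: np.ndarray
) -> np.ndarray:
    n = len(indices)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = superposed_rmsd(frames[indices[i]], frames[indices[j]], rmsd_idx)
            mat[i, j] = mat[j, i] = d
    return mat


def find_cluster_medoids(
    ensemble: TrajectoryEnsemble,
    labels: np.ndarray,
    rmsd_spec: SelectionSpec,
) -> dict[int, int]:
    """Medoid frame index per cluster (noise frames are ignored).

    The medoid is the member minimizing the mean pairwise superposed RMSD to
    all other members of its cluster; ties break to the lowest frame index.
    """
    labels = np.asarray(labels)
    rmsd_idx = select_atoms(ensemble.topology, rmsd_spec)
    medoids: dict[int, int] = {}
    for cluster in sorted(set(labels.tolist()) - {NOISE_LABEL}):
        members = np.flatnonzero(labels == cluster)
        if members.size == 1:
            medoids[int(cluster)] = int(members[0])
            continue
        sub = _pairwise_rmsd_submatrix(ensemble.frames, members, rmsd_idx)
        mean_rmsd = sub.sum(axis=1) / (members.size - 1)
        best = int(np.argmin(mean_rmsd))  # argmin takes the first (lowest index) tie
        medoids[int(cluster)] = int(members[best])
    if not medoids:
        raise LookupError("no non-noise clusters; cannot identify medoids")
    return medoids


def medoid_rmsd_matrix(
    ensemble: TrajectoryEnsemble,
    medoid_frames: list[int],
    rmsd_spec: SelectionSpec,
) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs between medoid frames.

    RMSD after per-pair superposition need not satisfy the triangle
    inequality; violations are logged, not raised.
    """
    if len(medoid_frames) < 2:
        raise ValueError("need at least 2 medoids for an RMSD matrix")
    rmsd_idx = select_atoms(ensemble.topology, rmsd_spec)
    mat = _pairwise_rmsd_submatrix(
        ensemble.frames, np.asarray(medoid_frames, dtype=int), rmsd_idx
    )
    n = mat.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if mat[i, j] > mat[i, k] + mat[k, j] + 1e-9:
                    logger.info(
                        "triangle inequality violated for medoids (%d, %d, %d)",
                        i, j, k,
                    )
    return mat


@dataclass
class StateDecomposition:
    """Clustering output bundle: labels, medoids and their RMSD matrix."""

    labels: np.ndarray
    medoid_frame_index: dict[int, int]
    medoid_rmsd_matrix: np.ndarray
    rmsd_selection: SelectionSpec

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_frame_index)

    def cluster_sizes(self) -> dict[int, int]:
        labels = np.asarray(self.labels)
        return {
            c: int((labels == c).sum()) for c in self.medoid_frame_index
        }


def decompose_states(
    ensemble: TrajectoryEnsemble,
    pc_table: np.ndarray,
    rmsd_spec: SelectionSpec,
    n_components_used: int = 20,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
) -> StateDecomposition:
    """Cluster, find medoids and build the medoid RMSD matrix in one call."""
    labels = cluster_pc_space(
        pc_table, n_components_used, min_cluster_size, min_samples
    )
    medoids = find_cluster_medoids(ensemble, labels, rmsd_spec)
    ordered = [medoids[c] for c in sorted(medoids)]
    if len(ordered) >= 2:
        matrix = medoid_rmsd_matrix(ensemble, ordered, rmsd_spec)
    else:
        matrix = np.zeros((1, 1))
    return StateDecomposition(labels, medoids, matrix, rmsd_spec)
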