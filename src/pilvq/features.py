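"""fMRI feature extraction for ROI voxel time series.

Three feature families are derived from a block-design BOLD experiment in
which volumes alternate between temporally *structured* and *random*
stimulus sequences:

* **PSC** — percent signal change, a scalar activation contrast per
  (subject, ROI, session),
* **SGF-ready** reduced graphs — the voxel-by-voxel Pearson correlation
  (connectivity) matrix compressed through *spatially grouped* Gaussian
  kernels (k-means on voxel positions),
* **FGF-ready** reduced graphs — the same compression through
  *functionally grouped* kernels obtained by consensus clustering of
  per-subject connectivity-based voxel groupings.

The scalar discriminative features (SGF/FGF proper) are extracted from the
reduced graphs by 2D-LDA, which lives in :mod:`pilvq.discriminant`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import multivariate_normal
from sklearn.cluster import KMeans

__all__ = [
    "ROITimeSeries",
    "GraphMatrix",
    "SmoothingBasis",
    "ReducedGraph",
    "compute_psc",
    "compute_graph_matrix",
    "build_spatial_basis",
    "build_functional_basis",
    "reduce_graph",
    "assemble_feature_table",
    "default_n_kernels",
    "CANONICAL_ROIS",
    "CANONICAL_SESSIONS",
]

CANONICAL_ROIS = ("Cerebellar", "Frontal", "Subcortical")
CANONICAL_SESSIONS = ("Pre", "Post")


@dataclass
class ROITimeSeries:
    """Voxel x volume BOLD matrix for one (subject, ROI, session).

    Parameters
    ----------
    Y : ndarray of shape (V, T)
        BOLD values, one row per voxel.
    coords : ndarray of shape (V, 3)
        Voxel centre positions in mm.
    structured_idx : ndarray of int
        Volume indices acquired under the structured condition.
    random_idx : ndarray of int
        Volume indices acquired under the random condition.
    """

    Y: np.ndarray
    coords: np.ndarray
    structured_idx: np.ndarray
    random_idx: np.ndarray
    roi_name: str = ""
    session: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.structured_idx = np.asarray(self.structured_idx, dtype=int)
        self.random_idx = np.asarray(self.random_idx, dtype=int)
        self.validate()

    @property
    def n_voxels(self) -> int:
        return self.Y.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.Y.shape[1]

    def validate(self) -> None:
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D voxel x volume matrix")
        if self.coords.shape != (self.Y.shape[0], 3):
            raise ValueError(
                f"coords must be (V, 3) = ({self.Y.shape[0]}, 3), "
                f"got {self.coords.shape}"
            )
        inter = np.intersect1d(self.structured_idx, self.random_idx)
        if inter.size:
            raise ValueError(f"condition index sets overlap at volumes {inter}")
        if self.structured_idx.size < 2 or self.random_idx.size < 2:
            raise ValueError("need at least 2 volumes per condition")
        all_idx = np.concatenate([self.structured_idx, self.random_idx])
        if all_idx.min() < 0 or all_idx.max() >= self.Y.shape[1]:
            raise ValueError("condition indices out of range")
        sd = self.Y.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"constant (zero-variance) voxel rows: {dead[:5].tolist()}"
            )


@dataclass
class GraphMatrix:
    """Symmetric V x V voxel connectivity (Pearson correlation) matrix."""

    G: np.ndarray
    roi_name: str = ""
    session: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G must be square")


@dataclass
class SmoothingBasis:
    """Gaussian kernel evaluations P[i, k] = N(r_i; mu_k, Sigma_k)."""

    P: np.ndarray
    kernels: list  # list of (mu, Sigma) tuples
    grouping_mode: Literal["spatial", "functional"]
    labels: np.ndarray | None = None  # voxel -> cluster assignment


@dataclass
class ReducedGraph:
    """K x K kernel-reduced connectivity matrix."""

    X_tilde: np.ndarray
    subject_id: str = ""
    roi_name: str = ""
    session: str = ""
    grouping_mode: str = ""


def compute_psc(ts: ROITimeSeries, denominator: str = "sum") -> float:
    """Percent signal change of an ROI.

    Per voxel v the contrast is
    ``(mean_s(v) - mean_r(v)) / (mean_s(v) + mean_r(v))`` where ``mean_s``
    and ``mean_r`` are the mean BOLD values over structured and random
    volumes; the ROI value is the average over voxels.

    ``denominator="mean"`` divides by the *average* of the two condition
    means instead of their sum (a factor-2 variant occasionally used).
    """
    mean_s = ts.Y[:, ts.structured_idx].mean(axis=1)
    mean_r = ts.Y[:, ts.random_idx].mean(axis=1)
    denom = mean_s + mean_r
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"PSC denominator vanishes for voxel(s) {zero[:5].tolist()}"
        )
    if denominator == "mean":
        denom = denom / 2.0
    elif denominator != "sum":
        raise ValueError("denominator must be 'sum' or 'mean'")
    return float(np.mean((mean_s - mean_r) / denom))


def compute_graph_matrix(ts: ROITimeSeries | np.ndarray) -> GraphMatrix:
    """Voxel-by-voxel Pearson correlation matrix over all volumes.

    Accepts a full :class:`ROITimeSeries` or a bare (V, T) array.  Raises
    if any voxel has zero temporal variance (correlation undefined).
    """
    if not isinstance(ts, ROITimeSeries):
        Y = np.asarray(ts, dtype=float)
        ts = ROITimeSeries.__new__(ROITimeSeries)
        ts.Y, ts.coords = Y, np.zeros((Y.shape[0], 3))
        ts.roi_name = ts.session = ts.subject_id = ""
    sd = ts.Y.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance voxel(s): {dead[:5].tolist()}")
    G = np.corrcoef(ts.Y)
    G = np.clip(G, -1.0, 1.0)
    np.fill_diagonal(G, 1.0)
    G = 0.5 * (G + G.T)
    return GraphMatrix(
        G=G, roi_name=ts.roi_name, session=ts.session, subject_id=ts.subject_id
    )


def default_n_kernels(n_voxels: int) -> int:
    """Default kernel count for an ROI of a given size.

    Small ROIs (<= 40 voxels) get 3 kernels, medium ones (<= 100) get 4,
    large bilateral ROIs get 8 (4 per hemisphere).
    """
    if n_voxels <= 40:
        return 3
    if n_voxels <= 100:
        return 4
    return 8


def _kernel_from_members(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and regularized covariance of member voxel positions."""
    mu = coords.mean(axis=0)
    if coords.shape[0] > 1:
        Sigma = np.cov(coords, rowvar=False)
    else:
        Sigma = np.zeros((3, 3))
    Sigma = np.atleast_2d(Sigma)
    tr = np.trace(Sigma)
    if tr <= 0:
        Sigma = np.eye(3)  # unit mm^2 for degenerate clusters
    else:
        Sigma = Sigma + (1e-6 * tr / 3.0) * np.eye(3)
    return mu, Sigma


def _basis_from_labels(
    coords: np.ndarray, labels: np.ndarray, mode: str
) -> SmoothingBasis:
    ks = np.unique(labels)
    kernels = []
    P = np.empty((coords.shape[0], ks.size))
    for col, k in enumerate(ks):
        members = coords[labels == k]
        mu, Sigma = _kernel_from_members(members)
        kernels.append((mu, Sigma))
        P[:, col] = multivariate_normal.pdf(coords, mean=mu, cov=Sigma)
    # relabel to contiguous 0..K-1 in column order
    relabel = np.searchsorted(ks, labels)
    return SmoothingBasis(P=P, kernels=kernels, grouping_mode=mode, labels=relabel)


def build_spatial_basis(
    coords: np.ndarray,
    n_kernels: int | None = None,
    seed: int = 0,
    hemispheres: bool = False,
) -> SmoothingBasis:
    """Spatial-grouping kernel basis: k-means on voxel positions.

    Each of the K clusters yields a Gaussian kernel with the cluster mean
    as centre and the (regularized) within-cluster position covariance as
    shape. With ``hemispheres=True`` the voxels on each side of the x = 0
    plane are clustered independently into ``n_kernels // 2`` clusters
    (used for large bilateral ROIs).
    """
    coords = np.asarray(coords, dtype=float)
    V = coords.shape[0]
    K = default_n_kernels(V) if n_kernels is None else int(n_kernels)
    if K < 1 or K >= V:
        raise ValueError(f"need 1 <= K < V, got K={K}, V={V}")
    if hemispheres:
        if K % 2:
            raise ValueError("hemisphere split needs an even kernel count")
        left = coords[:, 0] < 0
        labels = np.empty(V, dtype=int)
        for side, offset in ((left, 0), (~left, K // 2)):
            side_coords = coords[side]
            if side_coords.shape[0] <= K // 2:
                raise ValueError(
                    "too few voxels in one hemisphere; use a smaller K"
                )
            km = KMeans(n_clusters=K // 2, n_init=50, random_state=seed)
            labels[side] = km.fit_predict(side_coords) + offset
    else:
        km = KMeans(n_clusters=K, n_init=50, random_state=seed)
        labels = km.fit_predict(coords)
    sizes = np.bincount(labels, minlength=K)
    if (sizes == 0).any():
        raise ValueError("empty cluster produced; try a smaller K")
    return _basis_from_labels(coords, labels, "spatial")


def _cluster_graph(G: np.ndarray, K: int) -> np.ndarray:
    """Average-linkage clustering of voxels with dissimilarity 1 - G."""
    D = 1.0 - G
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=K, criterion="maxclust") - 1


def build_functional_basis(
    cohort_graphs: Sequence[GraphMatrix | np.ndarray],
    coords: np.ndarray,
    n_kernels: int,
    seed: int = 0,
) -> SmoothingBasis:
    """Functional-grouping basis via consensus clustering.

    Each subject's voxels are clustered on connectivity dissimilarity
    1 - G (average linkage, cut at K); the per-subject partitions are
    merged through a co-association matrix (fraction of subjects placing
    two voxels in the same cluster), which is itself clustered into K
    consensus groups. Kernel means/covariances come from the member voxel
    positions, as in the spatial basis.
    """
    mats = [g.G if isinstance(g, GraphMatrix) else np.asarray(g) for g in cohort_graphs]
    if len(mats) < 2:
        raise ValueError("consensus clustering needs at least 2 subjects")
    coords = np.asarray(coords, dtype=float)
    V = coords.shape[0]
    if any(m.shape != (V, V) for m in mats):
        raise ValueError("all graphs must share the voxel order of coords")
    K = int(n_kernels)
    if K < 1 or K >= V:
        raise ValueError(f"need 1 <= K < V, got K={K}, V={V}")
    coassoc = np.zeros((V, V))
    for m in mats:
        labels = _cluster_graph(m, K)
        coassoc += labels[:, None] == labels[None, :]
    coassoc /= len(mats)
    labels = _cluster_graph(coassoc, K)
    return _basis_from_labels(coords, labels, "functional")


def reduce_graph(g: GraphMatrix | np.ndarray, basis: SmoothingBasis) -> ReducedGraph:
    """Congruence reduction of a V x V graph to K x K: ``P^T G P``."""
    G = g.G if isinstance(g, GraphMatrix) else np.asarray(g, dtype=float)
    if basis.P.shape[0] != G.shape[0]:
        raise ValueError(
            f"basis built for V={basis.P.shape[0]} voxels, graph has {G.shape[0]}"
        )
    X = basis.P.T @ G @ basis.P
    X = 0.5 * (X + X.T)
    meta = {}
    if isinstance(g, GraphMatrix):
        meta = dict(subject_id=g.subject_id, roi_name=g.roi_name, session=g.session)
    return ReducedGraph(X_tilde=X, grouping_mode=basis.grouping_mode, **meta)


def assemble_feature_table(
    per_subject_values: Mapping[tuple[str, str, str], float],
    family: str,
    rois: Sequence[str] = CANONICAL_ROIS,
    sessions: Sequence[str] = CANONICAL_SESSIONS,
) -> pd.DataFrame:
    """Assemble a subjects x features table with canonical column order.

    Keys of ``per_subject_values`` are (subject_id, roi, session); columns
    are named ``<family>-<ROI>-<Session>`` in (ROI major, session minor)
    order. Every subject present must have all roi x session cells.
    """
    norm = {}
    for (subj, roi, session), value in per_subject_values.items():
        key = (str(subj), roi.capitalize(), session.capitalize())
        if key in norm:
            raise ValueError(f"duplicate cell {key}")
        norm[key] = float(value)
    columns = [f"{family}-{roi}-{ses}" for roi in rois for ses in sessions]
    subjects = sorted({k[0] for k in norm})
    data = np.full((len(subjects), len(columns)), np.nan)
    for i, subj in enumerate(subjects):
        for j, (roi, ses) in enumerate((r, s) for r in rois for s in sessions):
            key = (subj, roi, ses)
            if key not in norm:
                raise ValueError(f"missing cell for subject {subj}: ({roi}, {ses})")
            data[i, j] = norm[key]
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"), columns=columns)
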