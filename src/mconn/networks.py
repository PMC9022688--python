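"""Functional connectome construction, RSN clustering, seed maps, and
edge-wise group comparison.

Edges are Fisher-z-transformed Pearson correlations between component time
courses. Components are grouped into resting-state networks by average-
linkage agglomerative clustering on the distance d = 1 - r computed from
the *signed* correlation, so anticorrelated component pairs are maximally
distant. Group differences are tested edge-wise on subject z values with
Benjamini-Hochberg control over the unique edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .image import Image4D
from .ica import concatenate_temporal
from .stats import bh_fdr, two_sample_test

__all__ = [
    "ZMatrix",
    "ClusterAssignment",
    "GroupDifference",
    "component_correlation",
    "subject_z_matrices",
    "fisher_z",
    "zmatrix_from_r",
    "cluster_components",
    "group_difference_matrix",
    "seed_correlation_map",
]


def fisher_z(r, clip: float = 1e-7):
    """Variance-stabilizing transform z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    Values with |r| >= 1 - 1e-7 are clipped (with a warning); |r| > 1 is an
    error. Odd and monotone; works elementwise on arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must satisfy |r| <= 1")
    lim = 1.0 - clip
    if np.any(np.abs(r) > lim):
        warnings.warn("clipping |r| >= 1-1e-7 before Fisher z", stacklevel=2)
        r = np.clip(r, -lim, lim)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class ZMatrix:
    """Symmetric Fisher-z edge matrix with zero diagonal."""

    z: np.ndarray
    component_ids: np.ndarray
    level: str = "group"        # "group" or "subject"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite")
        np.fill_diagonal(z, 0.0)
        self.z = z

    @property
    def r(self) -> np.ndarray:
        r = np.tanh(self.z)
        np.fill_diagonal(r, 1.0)
        return r


def component_correlation(timecourses) -> np.ndarray:
    """Pearson correlation matrix of component time courses.

    A single (T, K) array gives that subject's r. A list of per-subject
    arrays gives the group-level r: the mean of subject Fisher z values
    back-transformed through tanh.
    """
    if isinstance(timecourses, np.ndarray):
        return _corr_one(timecourses)
    zs = subject_z_matrices(list(timecourses))
    r = np.tanh(zs.mean(axis=0))
    np.fill_diagonal(r, 1.0)
    return r


def _corr_one(tc: np.ndarray) -> np.ndarray:
    tc = np.asarray(tc, dtype=float)
    if tc.shape[0] < 3:
        raise ValueError("at least 3 timepoints are required")
    sd = tc.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance time course for component(s) {bad.tolist()}")
    return np.corrcoef(tc.T)


def subject_z_matrices(timecourses: list[np.ndarray]) -> np.ndarray:
    """Per-subject Fisher-z matrices, shape (n_subjects, K, K), zero diagonal."""
    out = []
    for tc in timecourses:
        r = _corr_one(tc)
        np.fill_diagonal(r, 0.0)
        out.append(fisher_z(r))
    return np.stack(out)


def zmatrix_from_r(r: np.ndarray, component_ids=None, level: str = "group") -> ZMatrix:
    r = np.asarray(r, dtype=float).copy()
    np.fill_diagonal(r, 0.0)
    ids = np.arange(r.shape[0]) if component_ids is None else np.asarray(component_ids)
    return ZMatrix(z=fisher_z(r), component_ids=ids, level=level)


@dataclass
class ClusterAssignment:
    """Component-to-RSN labels (1..k) with the linkage merge record."""

    labels: np.ndarray
    linkage_matrix: np.ndarray
    component_ids: np.ndarray

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_components(zm: ZMatrix, k: int) -> ClusterAssignment:
    """Average-linkage hierarchical clustering of components into k RSNs.

    Distance is d_ij = 1 - r_ij on the signed correlation, so a pair with
    r = -1 is at distance 2 (maximally separated) and r = 1 at distance 0.
    The dendrogram is cut to exactly k clusters; cluster ids are renumbered
    by descending cluster size, ties broken by smallest member index.
    """
    n = zm.z.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} components")
    if k < 1:
        raise ValueError("k must be >= 1")
    r = zm.r
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber deterministically: size desc, then smallest member id
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    return ClusterAssignment(labels=labels, linkage_matrix=Z, component_ids=zm.component_ids)


@dataclass
class GroupDifference:
    """Edge-wise group contrast with BH-FDR over unique edges."""

    delta_z: np.ndarray            # mean_z(A) - mean_z(B), symmetric
    p: np.ndarray                  # symmetric, diagonal 1
    rejected: set[tuple[int, int]]  # upper-triangle (i, j), i < j
    alpha: float
    method: str
    degenerate_edges: set[tuple[int, int]]


def group_difference_matrix(
    z_subjects: np.ndarray,
    group_labels,
    alpha: float = 0.05,
    method: str = "t",
) -> GroupDifference:
    """Per-edge two-sample test of subject z values between groups.

    ``z_subjects`` is (n_subjects, K, K); ``group_labels`` a length-n
    sequence with exactly two levels, each with >= 2 subjects. Delta is
    first-level mean minus second-level mean (levels in order of first
    appearance). BH-FDR is applied at ``alpha`` over the K(K-1)/2 unique
    upper-triangle edges.
    """
    z_subjects = np.asarray(z_subjects, dtype=float)
    labels = np.asarray(group_labels)
    if z_subjects.ndim != 3 or z_subjects.shape[1] != z_subjects.shape[2]:
        raise ValueError("z_subjects must be (n_subjects, K, K)")
    if len(labels) != z_subjects.shape[0]:
        raise ValueError("one group label per subject required")
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    a_idx = labels == levels[0]
    b_idx = labels == levels[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group requires at least 2 subjects")
    K = z_subjects.shape[1]
    iu, ju = np.triu_indices(K, k=1)
    za = z_subjects[a_idx][:, iu, ju]
    zb = z_subjects[b_idx][:, iu, ju]
    pvals = np.ones(len(iu))
    stat = np.zeros(len(iu))
    degenerate: set[tuple[int, int]] = set()
    for e in range(len(iu)):
        res = two_sample_test(za[:, e], zb[:, e], method=method)
        pvals[e] = res.p_value
        stat[e] = res.statistic
        if res.degenerate:
            degenerate.add((int(iu[e]), int(ju[e])))
    fdr = bh_fdr(pvals, alpha)
    rejected = {(int(iu[e]), int(ju[e])) for e in fdr.rejected_indices}

    delta = np.zeros((K, K))
    delta[iu, ju] = za.mean(axis=0) - zb.mean(axis=0)
    delta = delta + delta.T
    p = np.ones((K, K))
    p[iu, ju] = pvals
    p[ju, iu] = pvals
    return GroupDifference(
        delta_z=delta, p=p, rejected=rejected, alpha=alpha,
        method=method, degenerate_edges=degenerate,
    )


def seed_correlation_map(
    images: list[Image4D] | Image4D,
    seed_mask: np.ndarray,
    brain_mask: np.ndarray,
    concatenate: bool = True,
) -> np.ndarray:
    """Seed-based connectivity: Fisher-z map of voxel correlations with the
    mean in-seed time course.

    With ``concatenate`` the correlation is computed on the temporally
    concatenated, per-subject-normalized group matrix (the group-level
    map); otherwise per-subject z maps are averaged. Returns a 3D z volume
    (zeros outside the brain mask).
    """
    if isinstance(images, Image4D):
        images = [images]
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if np.any(seed_mask & ~brain_mask):
        raise ValueError("seed mask must lie inside the brain mask")
    concat = concatenate_temporal(images, brain_mask)
    seed_flat = np.flatnonzero(seed_mask.ravel())
    in_cols = np.isin(concat.voxel_indices, seed_flat)
    if not in_cols.any():
        raise ValueError("seed mask voxels were all dropped (zero variance)")

    def _zmap(X: np.ndarray) -> np.ndarray:
        seed_tc = X[:, in_cols].mean(axis=1)
        if seed_tc.std(ddof=0) == 0:
            raise ValueError("seed time course has zero variance")
        s = (seed_tc - seed_tc.mean()) / seed_tc.std(ddof=0)
        Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        r = (Xc * s[:, None]).mean(axis=0)
        # in-seed voxels correlate ~1 with the seed mean; clip silently
        return fisher_z(np.clip(r, -1.0 + 1e-7, 1.0 - 1e-7))

    if concatenate:
        zvals = _zmap(concat.data)
    else:
        zvals = np.mean([_zmap(concat.data[blk]) for blk in concat.row_blocks], axis=0)
    vol = np.zeros(int(np.prod(concat.grid_shape)))
    vol[concat.voxel_indices] = zvals
    return vol.reshape(concat.grid_shape)
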