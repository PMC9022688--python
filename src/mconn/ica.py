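"""Temporal concatenation, group spatial ICA, and noise-component screening.

The decomposition follows the MELODIC convention: subjects' normalized
time-by-voxel matrices are stacked in time, PCA-reduced, and unmixed with
fixed-point ICA applied over the voxel dimension so the *spatial maps* are
the independent sources. Per-subject time courses are then recovered by
least-squares regression of each subject's data onto the group maps (the
first dual-regression stage), which is what defines subject-level edge
correlations downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .image import Image4D, mask_edge_shell

__all__ = [
    "ComponentSet",
    "ConcatData",
    "ICAConvergenceError",
    "concatenate_temporal",
    "group_ica",
    "classify_noise",
    "match_components",
]


class ICAConvergenceError(RuntimeError):
    """Fixed-point ICA failed to converge within the iteration budget."""

    def __init__(self, n_iter: int, max_iter: int):
        self.n_iter = n_iter
        self.max_iter = max_iter
        super().__init__(f"ICA did not converge after {n_iter}/{max_iter} iterations")


@dataclass
class ConcatData:
    """Temporally concatenated, per-subject-normalized group matrix."""

    data: np.ndarray                 # (sum_s T_s, V)
    row_blocks: list[slice]          # one slice per subject
    voxel_indices: np.ndarray        # (V,) flat indices into the grid
    dropped_voxels: np.ndarray       # flat indices removed for zero variance
    grid_shape: tuple[int, int, int]
    tr: float


@dataclass
class ComponentSet:
    """Group ICA result: unit-norm spatial maps plus per-subject time courses."""

    maps: np.ndarray                          # (K, V) unit-norm rows
    timecourses: list[np.ndarray]             # per subject, (T_s, K)
    voxel_indices: np.ndarray
    grid_shape: tuple[int, int, int]
    tr: float
    explained_variance: np.ndarray | None = None
    noise_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        K = self.maps.shape[0]
        for tc in self.timecourses:
            if tc.shape[1] != K:
                raise ValueError("timecourse column count must equal map count")
        if self.noise_flags is not None and len(self.noise_flags) != K:
            raise ValueError("one noise flag per component required")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_volumes(self) -> np.ndarray:
        """Maps as a (K, X, Y, Z) stack (zeros outside the mask)."""
        vols = np.zeros((self.n_components, int(np.prod(self.grid_shape))))
        vols[:, self.voxel_indices] = self.maps
        return vols.reshape((self.n_components,) + tuple(self.grid_shape))

    def retained(self) -> "ComponentSet":
        """Subset with noise-flagged components removed."""
        if self.noise_flags is None:
            raise ValueError("classify_noise has not been run")
        keep = ~self.noise_flags
        return ComponentSet(
            maps=self.maps[keep],
            timecourses=[tc[:, keep] for tc in self.timecourses],
            voxel_indices=self.voxel_indices,
            grid_shape=self.grid_shape,
            tr=self.tr,
            explained_variance=None if self.explained_variance is None
            else self.explained_variance[keep],
            noise_flags=np.zeros(int(keep.sum()), dtype=bool),
        )


def concatenate_temporal(images: list[Image4D], mask: np.ndarray) -> ConcatData:
    """Stack subjects in time after per-subject voxel-wise normalization.

    Each subject's in-mask voxel time series are demeaned and scaled to
    unit variance before stacking. Voxels with zero variance in any
    subject are dropped from all subjects and reported.
    """
    if not images:
        raise ValueError("at least one image is required")
    grid = images[0].grid_shape
    for img in images:
        if img.grid_shape != grid:
            raise ValueError(
                f"grid mismatch: {img.grid_shape} vs {grid}"
            )
    if mask.shape != grid:
        raise ValueError("mask grid does not match images")
    vox = np.flatnonzero(mask.ravel())
    mats, keep = [], np.ones(len(vox), dtype=bool)
    for img in images:
        X = img.data.reshape(-1, img.n_timepoints)[vox].T  # (T, V)
        keep &= X.max(axis=0) - X.min(axis=0) > 0          # exact constancy
        mats.append(X)
    dropped = vox[~keep]
    blocks, rows, out = [], 0, []
    for X in mats:
        Xk = X[:, keep]
        Xk = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=0)
        out.append(Xk)
        blocks.append(slice(rows, rows + Xk.shape[0]))
        rows += Xk.shape[0]
    return ConcatData(
        data=np.vstack(out),
        row_blocks=blocks,
        voxel_indices=vox[keep],
        dropped_voxels=dropped,
        grid_shape=grid,
        tr=images[0].tr,
    )


def _pca_reduce(X: np.ndarray, n_components: int) -> np.ndarray:
    """Top spatial principal modes of the time-by-voxel matrix, (q, V)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return s[:n_components, None] * Vt[:n_components]


def pca_order_95(X: np.ndarray) -> int:
    """Default model order: number of PCs retaining 95% of the variance."""
    s = np.linalg.svd(X, compute_uv=False)
    frac = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(frac, 0.95) + 1)


def group_ica(
    concat: ConcatData,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> ComponentSet:
    """PCA reduction followed by fixed-point spatial ICA (logcosh contrast).

    Maps are unit-norm with the sign convention that each map's
    largest-magnitude voxel is positive, which makes the output
    deterministic for a fixed seed. Raises :class:`ICAConvergenceError`
    (carrying the iteration count) on non-convergence.
    """
    X = concat.data
    if n_components is None:
        n_components = pca_order_95(X)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds data rank bound {min(X.shape)}"
        )
    Y = _pca_reduce(X, n_components)          # (q, V)
    ica = FastICA(
        n_components=n_components,
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            ica.fit(Y.T)                      # samples = voxels, features = PCs
        except ConvergenceWarning as exc:
            raise ICAConvergenceError(getattr(ica, "n_iter_", max_iter), max_iter) from exc
    # apply the unmixing to the uncentered modes so the maps span exactly
    # the top-q PCA subspace (the feature centering only shifts each map
    # by a constant)
    maps = ica.components_ @ Y                # (q, V)
    norms = np.linalg.norm(maps, axis=1)
    norms[norms == 0] = 1.0
    maps = maps / norms[:, None]
    flip = maps[np.arange(len(maps)), np.argmax(np.abs(maps), axis=1)] < 0
    maps[flip] *= -1.0

    pinv_m = np.linalg.pinv(maps)             # (V, q)
    tcs = [X[blk] @ pinv_m for blk in concat.row_blocks]

    proj = X @ pinv_m                         # (T_total, q)
    recon_var = (proj**2).mean(axis=0)        # maps are unit norm
    explained = recon_var / (X**2).mean()

    return ComponentSet(
        maps=maps,
        timecourses=tcs,
        voxel_indices=concat.voxel_indices,
        grid_shape=concat.grid_shape,
        tr=concat.tr,
        explained_variance=explained,
    )


@dataclass
class NoiseDiagnostics:
    edge_fraction: np.ndarray
    highfreq_fraction: np.ndarray
    indeterminate: np.ndarray


def classify_noise(
    cs: ComponentSet,
    mask: np.ndarray,
    z_threshold: float = 2.3,
    edge_fraction_threshold: float = 0.5,
    highfreq_cutoff_hz: float = 0.1,
    highfreq_fraction_threshold: float = 0.5,
) -> tuple[np.ndarray, NoiseDiagnostics]:
    """Automated screen for artefactual components.

    A component is flagged as noise when its supra-threshold voxels
    (|z-scored map| > ``z_threshold``) fall mostly (> 50%) on the
    outermost mask shell, or when more than half of its time-course power
    lies above ``highfreq_cutoff_hz``. Components with an empty
    supra-threshold set are marked indeterminate (not noise). Flags are
    stored on the ComponentSet and returned with per-criterion diagnostics.
    """
    if mask.shape != tuple(cs.grid_shape):
        raise ValueError("mask grid does not match component set")
    shell = mask_edge_shell(mask).ravel()[cs.voxel_indices]
    K = cs.n_components
    edge_frac = np.zeros(K)
    hf_frac = np.zeros(K)
    indet = np.zeros(K, dtype=bool)
    flags = np.zeros(K, dtype=bool)
    fs = 1.0 / cs.tr
    for k in range(K):
        m = cs.maps[k]
        z = (m - m.mean()) / m.std(ddof=0) if m.std(ddof=0) > 0 else np.zeros_like(m)
        supra = np.abs(z) > z_threshold
        if not supra.any():
            indet[k] = True
        else:
            edge_frac[k] = shell[supra].mean()
        # average the spectral criterion over subjects to avoid the
        # concatenation discontinuities
        fracs = []
        for tc in cs.timecourses:
            f, p = sps.periodogram(tc[:, k], fs=fs)
            tot = p[1:].sum()                 # exclude DC
            fracs.append(p[1:][f[1:] > highfreq_cutoff_hz].sum() / tot if tot > 0 else 0.0)
        hf_frac[k] = float(np.mean(fracs))
        edge_noise = (not indet[k]) and edge_frac[k] > edge_fraction_threshold
        flags[k] = edge_noise or hf_frac[k] > highfreq_fraction_threshold
    cs.noise_flags = flags
    return flags, NoiseDiagnostics(edge_frac, hf_frac, indet)


def match_components(
    maps: np.ndarray, true_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of recovered to true maps by |corr|.

    Returns (assignment, |corr|) where ``assignment[i]`` is the true-map
    index matched to recovered map i.
    """
    K, L = maps.shape[0], true_maps.shape[0]
    C = np.zeros((K, L))
    for i in range(K):
        for j in range(L):
            a, b = maps[i], true_maps[j]
            sa, sb = a.std(), b.std()
            C[i, j] = 0.0 if sa == 0 or sb == 0 else abs(np.corrcoef(a, b)[0, 1])
    assignment = -np.ones(K, dtype=int)
    scores = np.zeros(K)
    cost = C.copy()
    for _ in range(min(K, L)):
        i, j = np.unravel_index(np.argmax(cost), cost.shape)
        assignment[i] = j
        scores[i] = C[i, j]
        cost[i, :] = -1.0
        cost[:, j] = -1.0
    return assignment, scores
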