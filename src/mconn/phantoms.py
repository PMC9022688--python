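"""Ground-truthed functional and diffusion phantoms.

The functional phantom plants spatial component maps (Gaussian-profile
spheres) whose time courses share latent cluster factors, so the true
within-cluster correlation is a controllable parameter ``w`` and named
cluster pairs can be given a target inter-cluster correlation (including
anticorrelation). The diffusion phantom embeds geometric fiber bundles in
an isotropic background and synthesizes single-shell DWI signal from the
exact tensor field, optionally with Rician noise. Every generator is
deterministic given its integer seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .image import Image4D, default_affine, ellipsoid_mask, mask_edge_shell

__all__ = [
    "ComponentSpec",
    "FunctionalPhantomSpec",
    "BundleSpec",
    "DiffusionPhantomSpec",
    "DWIImage",
    "GroundTruth",
    "make_parcellation",
    "simulate_rsfmri",
    "simulate_timecourses",
    "simulate_cohort",
    "simulate_dwi",
    "default_functional_spec",
    "default_diffusion_spec",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpec:
    """One planted signal component: a Gaussian blob with a cluster label.

    ``sign`` is the loading sign (+1/-1) of the component's time course on
    its cluster's latent factor; a -1 component is anticorrelated with its
    own cluster.
    """

    center: tuple[float, float, float]
    radius: float
    amplitude: float = 1.0
    cluster: int = 1
    sign: int = 1

    def geometry(self) -> tuple:
        """Geometry key used to check that two specs are comparable."""
        return (tuple(self.center), self.radius, self.cluster, self.sign)


@dataclass
class FunctionalPhantomSpec:
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    n_timepoints: int = 300
    tr_seconds: float = 1.0
    components: list[ComponentSpec] = field(default_factory=list)
    cluster_loading: float = 0.6          # w: squared loading on the cluster factor
    inter_cluster_corr: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sigma: float = 0.2
    n_noise_components: int = 0
    signal_bandlimit_hz: float = 0.1      # low-pass cutoff for signal time courses
    per_cluster_loading: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def loading(self, cluster: int) -> float:
        """Effective squared loading w for one cluster (per-cluster override
        falls back to the global ``cluster_loading``)."""
        return float(self.per_cluster_loading.get(cluster, self.cluster_loading))

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape, dtype=float)
        if len(self.grid_shape) != 3 or np.any(shape <= 0):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0.0 <= self.cluster_loading <= 1.0:
            raise ValueError("cluster_loading w must lie in [0, 1]")
        for cid, w in self.per_cluster_loading.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"per-cluster loading for cluster {cid} must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.n_noise_components < 0:
            raise ValueError("n_noise_components must be nonnegative")
        for c in self.components:
            lo = np.asarray(c.center) - c.radius
            hi = np.asarray(c.center) + c.radius
            if np.any(lo < 0) or np.any(hi > shape - 1):
                raise ValueError(f"component sphere at {c.center} leaves the grid")
            if c.sign not in (-1, 1):
                raise ValueError("component sign must be +1 or -1")
        for pair, r in self.inter_cluster_corr.items():
            if not abs(r) < 1.0:
                raise ValueError(f"|inter_cluster_corr| must be < 1, got {r} for {pair}")
        # positive-definiteness is checked when the factor covariance is built

    def cluster_ids(self) -> list[int]:
        return sorted({c.cluster for c in self.components})

    def factor_covariance(self) -> np.ndarray:
        """Target covariance of the latent cluster factors.

        Unit diagonal; named pairs get the requested correlation. Raises if
        the resulting matrix is not positive definite.
        """
        ids = self.cluster_ids()
        idx = {cid: i for i, cid in enumerate(ids)}
        cov = np.eye(len(ids))
        for (a, b), r in self.inter_cluster_corr.items():
            if a not in idx or b not in idx:
                raise ValueError(f"inter_cluster_corr names unknown cluster pair {(a, b)}")
            cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = r
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("requested factor covariance is not positive definite") from exc
        return cov


@dataclass(frozen=True)
class BundleSpec:
    """A fiber bundle: a tube of anisotropic tensors along a curve.

    ``geometry`` is ``"straight"`` (segment from start to end) or ``"arc"``
    (quarter circle). For an arc the endpoints must differ in exactly two
    coordinates; the arc lies in that coordinate plane with its center at
    the corner that keeps the start point's first differing coordinate.
    Diffusivities are in mm^2/s.
    """

    geometry: str
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float = 2.0
    axial_diffusivity: float = 1.7e-3
    radial_diffusivity: float = 0.3e-3

    def validate(self) -> None:
        if self.geometry not in ("straight", "arc"):
            raise ValueError(f"unknown bundle geometry {self.geometry!r}")
        if not self.axial_diffusivity >= self.radial_diffusivity > 0:
            raise ValueError("bundle requires axial >= radial diffusivity > 0")
        if self.geometry == "arc":
            diff = np.asarray(self.end) - np.asarray(self.start)
            if int(np.count_nonzero(np.abs(diff) > 1e-9)) != 2:
                raise ValueError("arc endpoints must differ in exactly two coordinates")


@dataclass
class DiffusionPhantomSpec:
    grid_shape: tuple[int, int, int] = (20, 12, 12)
    bundles: list[BundleSpec] = field(default_factory=list)
    background_diffusivity: float = 0.7e-3
    b_values: np.ndarray = field(default_factory=lambda: np.array([0.0] + [1000.0] * 12))
    b_vectors: np.ndarray | None = None
    s0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.b_vectors is None:
            self.b_vectors = default_gradient_scheme(len(self.b_values), self.b_values)
        self.b_vectors = np.asarray(self.b_vectors, dtype=float)

    def validate(self) -> None:
        if self.b_vectors.shape != (len(self.b_values), 3):
            raise ValueError("b_vectors must be (n_measurements, 3)")
        if not np.any(self.b_values == 0):
            raise ValueError("at least one b=0 volume is required")
        nz = self.b_values > 0
        norms = np.linalg.norm(self.b_vectors[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("b_vectors for b>0 must be unit norm")
        if self.background_diffusivity <= 0 or self.s0 <= 0:
            raise ValueError("background_diffusivity and s0 must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        for b in self.bundles:
            b.validate()


def default_gradient_scheme(n: int, b_values: np.ndarray) -> np.ndarray:
    """Deterministic well-spread unit gradients (zeros on b=0 rows)."""
    vecs = np.zeros((n, 3))
    nz = np.flatnonzero(b_values > 0)
    # golden-spiral points on the half sphere: reproducible, no RNG
    m = len(nz)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for rank, i in enumerate(nz):
        z = (rank + 0.5) / m            # upper hemisphere
        r = np.sqrt(1.0 - z * z)
        th = golden * rank
        vecs[i] = (r * np.cos(th), r * np.sin(th), z)
    return vecs


@dataclass
class DWIImage:
    """Diffusion-weighted series with its acquisition scheme."""

    data: np.ndarray                      # (X, Y, Z, M)
    b_values: np.ndarray
    b_vectors: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)


@dataclass
class GroundTruth:
    """Everything the generators know, for downstream validation."""

    true_maps: np.ndarray | None = None            # (K, X, Y, Z) incl. noise comps
    true_timecourses: np.ndarray | None = None     # (T, K) or per-subject list
    true_cluster_assignment: np.ndarray | None = None   # (K_signal,)
    true_noise_flags: np.ndarray | None = None     # (K,) bool
    mask: np.ndarray | None = None
    subject_timecourses: list[np.ndarray] | None = None
    bundle_masks: np.ndarray | None = None         # (n_bundles, X, Y, Z) bool
    endpoint_labels: np.ndarray | None = None      # label volume at bundle endpoints
    endpoint_region_ids: list[tuple[int, int]] | None = None


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def make_parcellation(
    grid_shape: tuple[int, int, int], n_regions: int, seed: int = 0
) -> np.ndarray:
    """Partition the brain mask into ``n_regions`` connected labels.

    Random foreground voxels seed a multi-source breadth-first flood fill
    (6-connectivity), which guarantees each label is a nonempty connected
    voxel set. Labels are 1..n_regions, background 0.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    mask = ellipsoid_mask(grid_shape)
    fg = np.argwhere(mask)
    if n_regions > len(fg):
        raise ValueError(
            f"n_regions={n_regions} exceeds {len(fg)} foreground voxels"
        )
    rng = np.random.default_rng(seed)
    picks = fg[rng.choice(len(fg), size=n_regions, replace=False)]
    labels = np.zeros(grid_shape, dtype=np.int32)
    queue: deque[tuple[int, int, int]] = deque()
    for lab, (x, y, z) in enumerate(picks, start=1):
        labels[x, y, z] = lab
        queue.append((x, y, z))
    shape = np.asarray(grid_shape)
    while queue:
        x, y, z = queue.popleft()
        lab = labels[x, y, z]
        for dx, dy, dz in _NEIGHBORS6:
            nx, ny, nz_ = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz_ < shape[2]:
                if mask[nx, ny, nz_] and labels[nx, ny, nz_] == 0:
                    labels[nx, ny, nz_] = lab
                    queue.append((nx, ny, nz_))
    return labels


# ---------------------------------------------------------------------------
# Functional phantom
# ---------------------------------------------------------------------------

def _gaussian_sphere(grid_shape, center, radius, amplitude) -> np.ndarray:
    """Gaussian-profile blob truncated at 2*radius."""
    coords = np.indices(grid_shape, dtype=float)
    d2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
    prof = amplitude * np.exp(-d2 / (2.0 * radius**2))
    prof[d2 > (2.0 * radius) ** 2] = 0.0
    return prof


def _lowpass(x: np.ndarray, cutoff_hz: float, tr: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0; identity if cutoff
    is at or above Nyquist."""
    nyq = 0.5 / tr
    if cutoff_hz <= 0 or cutoff_hz >= nyq:
        return x
    b, a = sps.butter(4, cutoff_hz / nyq)
    return sps.filtfilt(b, a, x, axis=0)


def simulate_timecourses(
    spec: FunctionalPhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw the true signal-component time courses, shape (T, K).

    Each component k in cluster c with loading sign s has
    ``tc_k = s * (sqrt(w) * f_c + sqrt(1-w) * eta_k)`` where the latent
    factors f have the requested inter-cluster correlation (exact in
    expectation via a Cholesky mix) and eta are unique terms. Both f and
    eta are band-limited by the same low-pass filter before standardization,
    which leaves all correlations unchanged.
    """
    T = spec.n_timepoints
    ids = spec.cluster_ids()
    idx = {cid: i for i, cid in enumerate(ids)}
    cov = spec.factor_covariance()
    L = np.linalg.cholesky(cov)
    raw = rng.standard_normal((T, len(ids)))
    eta = rng.standard_normal((T, len(spec.components)))
    raw = _lowpass(raw, spec.signal_bandlimit_hz, spec.tr_seconds)
    eta = _lowpass(eta, spec.signal_bandlimit_hz, spec.tr_seconds)
    raw = raw / raw.std(axis=0, ddof=0)
    eta = eta / eta.std(axis=0, ddof=0)
    factors = raw @ L.T
    tcs = np.empty((T, len(spec.components)))
    for k, comp in enumerate(spec.components):
        w = spec.loading(comp.cluster)
        tcs[:, k] = comp.sign * (
            np.sqrt(w) * factors[:, idx[comp.cluster]] + np.sqrt(1.0 - w) * eta[:, k]
        )
    return tcs


def _noise_component_maps(
    spec: FunctionalPhantomSpec, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Spatial maps for noise components: blobs on the brain-mask edge."""
    shell = np.argwhere(mask_edge_shell(mask))
    maps = np.zeros((spec.n_noise_components,) + tuple(spec.grid_shape))
    amp = float(np.mean([c.amplitude for c in spec.components])) if spec.components else 1.0
    for j in range(spec.n_noise_components):
        anchor = shell[rng.integers(len(shell))]
        d = np.linalg.norm(shell - anchor, axis=1)
        blob = shell[d <= 3.0]
        maps[(j,) + tuple(blob.T)] = amp
    return maps


def simulate_rsfmri(
    spec: FunctionalPhantomSpec, rng: np.random.Generator | None = None
) -> tuple[Image4D, GroundTruth]:
    """Generate one subject's BOLD-like 4D series with known components.

    Voxel signal is ``sum_k map_k(v) * tc_k(t) + eps(v, t)`` with white
    Gaussian eps of scale ``noise_sigma``. Noise components (if requested)
    sit on the brain-mask edge shell with temporally white time courses.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    T = spec.n_timepoints
    mask = ellipsoid_mask(shape)

    signal_maps = np.stack(
        [_gaussian_sphere(shape, c.center, c.radius, c.amplitude) for c in spec.components]
    ) if spec.components else np.zeros((0,) + shape)
    signal_tcs = simulate_timecourses(spec, rng) if spec.components else np.zeros((T, 0))

    noise_maps = _noise_component_maps(spec, mask, rng)
    noise_tcs = rng.standard_normal((T, spec.n_noise_components))

    maps = np.concatenate([signal_maps, noise_maps], axis=0)
    tcs = np.concatenate([signal_tcs, noise_tcs], axis=1)

    flat_maps = maps.reshape(len(maps), -1)
    data = (flat_maps.T @ tcs.T).reshape(shape + (T,))
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    truth = GroundTruth(
        true_maps=maps,
        true_timecourses=tcs,
        true_cluster_assignment=np.array([c.cluster for c in spec.components]),
        true_noise_flags=np.array(
            [False] * len(spec.components) + [True] * spec.n_noise_components
        ),
        mask=mask,
    )
    img = Image4D(data=data, affine=default_affine(), tr=spec.tr_seconds)
    return img, truth


def simulate_cohort(
    spec_sham: FunctionalPhantomSpec,
    spec_hypo: FunctionalPhantomSpec,
    n_per_group: int,
    seed: int = 0,
) -> tuple[list[tuple[Image4D, str]], GroundTruth]:
    """Two-group cohort of independent phantom subjects.

    Both specs must share component geometry (centers, radii, clusters,
    signs); they may differ only in statistical parameters such as the
    cluster loading or inter-cluster correlations. Each subject gets an
    independent substream spawned from ``(seed, subject_index)``.
    """
    ga = [c.geometry() for c in spec_sham.components]
    gb = [c.geometry() for c in spec_hypo.components]
    if ga != gb or tuple(spec_sham.grid_shape) != tuple(spec_hypo.grid_shape):
        raise ValueError("cohort specs must share component geometry and grid")
    spec_sham.validate()
    spec_hypo.validate()
    subjects: list[tuple[Image4D, str]] = []
    subject_tcs: list[np.ndarray] = []
    shared_truth: GroundTruth | None = None
    for i in range(2 * n_per_group):
        group = "sham" if i < n_per_group else "hypo"
        spec = spec_sham if group == "sham" else spec_hypo
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        img, truth = simulate_rsfmri(spec, rng)
        subjects.append((img, group))
        subject_tcs.append(truth.true_timecourses)
        if shared_truth is None:
            shared_truth = truth
    if shared_truth is None:
        shared_truth = GroundTruth()
    shared_truth.subject_timecourses = subject_tcs
    shared_truth.true_timecourses = None
    return subjects, shared_truth


def default_functional_spec(
    n_clusters: int = 4,
    comps_per_cluster: int = 3,
    grid_shape: tuple[int, int, int] = (20, 20, 12),
    w: float = 0.6,
    anticorr: float = -0.5,
    noise_sigma: float = 0.2,
    n_noise_components: int = 2,
    n_timepoints: int = 300,
    seed: int = 0,
) -> FunctionalPhantomSpec:
    """Study-condition phantom: 4 clusters x 3 components, w=0.6, one
    anticorrelated cluster pair (last two clusters, r=-0.5).

    Component centers are laid out on a jittered lattice inside the brain
    mask, amplitude 1 against ``noise_sigma=0.2`` white noise (voxel SNR at
    blob cores around 5).
    """
    K = n_clusters * comps_per_cluster
    mask = ellipsoid_mask(grid_shape)
    radius = 1.6
    # lattice of candidate centers comfortably inside the mask
    nx = int(np.ceil(np.sqrt(K)))
    ny = int(np.ceil(K / nx))
    xs = np.linspace(0.22, 0.78, nx) * (grid_shape[0] - 1)
    ys = np.linspace(0.22, 0.78, ny) * (grid_shape[1] - 1)
    zmid = (grid_shape[2] - 1) / 2.0
    centers = []
    for j in range(ny):
        for i in range(nx):
            if len(centers) < K:
                z = zmid + (1.5 if (i + j) % 2 else -1.5)
                centers.append((float(xs[i]), float(ys[j]), float(z)))
    comps = []
    for k, ctr in enumerate(centers):
        if not mask[tuple(int(round(c)) for c in ctr)]:
            raise ValueError("component lattice leaves the brain mask")
        comps.append(
            ComponentSpec(center=ctr, radius=radius, amplitude=1.0,
                          cluster=k % n_clusters + 1, sign=1)
        )
    icc = {}
    if n_clusters >= 2 and anticorr != 0.0:
        icc[(n_clusters - 1, n_clusters)] = anticorr
    return FunctionalPhantomSpec(
        grid_shape=grid_shape,
        n_timepoints=n_timepoints,
        components=comps,
        cluster_loading=w,
        inter_cluster_corr=icc,
        noise_sigma=noise_sigma,
        n_noise_components=n_noise_components,
        seed=seed,
    )


def lowered_loading_spec(
    spec: FunctionalPhantomSpec, cluster: int, w: float
) -> FunctionalPhantomSpec:
    """Variant spec identical in geometry with one cluster's loading set to
    ``w`` — the hypoperfused arm of a two-group cohort."""
    per = dict(spec.per_cluster_loading)
    per[cluster] = w
    return replace(spec, per_cluster_loading=per)


# ---------------------------------------------------------------------------
# Diffusion phantom
# ---------------------------------------------------------------------------

def _bundle_tangent_field(
    bundle: BundleSpec, grid_shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(inside, tangent) for one bundle: boolean tube mask and unit tangent
    of the bundle curve at the nearest curve point, per voxel."""
    coords = np.indices(grid_shape, dtype=float).reshape(3, -1).T  # (V, 3)
    p0 = np.asarray(bundle.start, dtype=float)
    p1 = np.asarray(bundle.end, dtype=float)
    if bundle.geometry == "straight":
        seg = p1 - p0
        length = np.linalg.norm(seg)
        u = seg / length
        t = np.clip((coords - p0) @ u, 0.0, length)
        nearest = p0 + t[:, None] * u
        dist = np.linalg.norm(coords - nearest, axis=1)
        inside = dist <= bundle.radius
        tangent = np.tile(u, (len(coords), 1))
    else:  # quarter arc in the coordinate plane spanned by the two differing axes
        diff = p1 - p0
        axes = np.flatnonzero(np.abs(diff) > 1e-9)
        a, b = int(axes[0]), int(axes[1])
        fixed = [ax for ax in range(3) if ax not in (a, b)][0]
        # center keeps p0's coordinate on the first differing axis
        center = p0.copy()
        center[a] = p0[a]
        center[b] = p1[b]
        R = abs(p1[a] - p0[a])
        if not np.isclose(abs(p0[b] - p1[b]), R):
            raise ValueError("quarter-arc endpoints must be equidistant from the corner center")
        rel = coords - center
        in_plane = rel[:, [a, b]]
        rho = np.linalg.norm(in_plane, axis=1)
        with np.errstate(invalid="ignore"):
            ang0 = np.arctan2(p0[b] - center[b], p0[a] - center[a])
            ang1 = np.arctan2(p1[b] - center[b], p1[a] - center[a])
            ang = np.arctan2(in_plane[:, 1], in_plane[:, 0])
        lo, hi = sorted((ang0, ang1))
        within_arc = (ang >= lo - 1e-9) & (ang <= hi + 1e-9)
        dist2 = (rho - R) ** 2 + rel[:, fixed] ** 2
        inside = within_arc & (dist2 <= bundle.radius**2) & (rho > 1e-9)
        tangent = np.zeros_like(coords)
        # tangent is perpendicular to the radial direction, in-plane
        tangent[:, a] = -np.sin(ang)
        tangent[:, b] = np.cos(ang)
    tangent = tangent.reshape(grid_shape + (3,))
    return inside.reshape(grid_shape), tangent


def true_tensor_field(spec: DiffusionPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-voxel tensors (X,Y,Z,3,3) and per-bundle masks."""
    shape = tuple(spec.grid_shape)
    d_bg = spec.background_diffusivity
    tensors = np.tile(d_bg * np.eye(3), shape + (1, 1))
    bundle_masks = np.zeros((len(spec.bundles),) + shape, dtype=bool)
    claimed = np.zeros(shape, dtype=bool)
    for i, bundle in enumerate(spec.bundles):
        inside, tangent = _bundle_tangent_field(bundle, shape)
        inside = inside & ~claimed          # first bundle wins in overlaps
        claimed |= inside
        bundle_masks[i] = inside
        t = tangent[inside]                  # (n, 3)
        la, lr = bundle.axial_diffusivity, bundle.radial_diffusivity
        D = lr * np.eye(3) + (la - lr) * np.einsum("ni,nj->nij", t, t)
        tensors[inside] = D
    return tensors, bundle_masks


def simulate_dwi(
    spec: DiffusionPhantomSpec,
) -> tuple[DWIImage, np.ndarray, GroundTruth]:
    """Synthesize DWI from the exact tensor field.

    Signal per voxel and gradient is ``S0 * exp(-b g^T D g)``; Rician noise
    of scale ``noise_sigma`` is applied as ``|S + n1 + i n2|`` with
    independent Gaussian n (sigma=0 returns the noiseless signal). Returns
    the image, the true tensor field, and ground truth with bundle masks
    and an endpoint label volume (spheres of each bundle's radius at its
    two endpoints, labels 1, 2, ... in bundle order).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    tensors, bundle_masks = true_tensor_field(spec)
    g = spec.b_vectors                       # (M, 3)
    b = spec.b_values                        # (M,)
    quad = np.einsum("mi,...ij,mj->...m", g, tensors, g)  # (X,Y,Z,M)
    signal = spec.s0 * np.exp(-b * quad)
    if spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, size=signal.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    labels = np.zeros(shape, dtype=np.int32)
    region_ids: list[tuple[int, int]] = []
    coords = np.indices(shape, dtype=float)
    next_label = 1
    for bundle in spec.bundles:
        pair = []
        for pt in (bundle.start, bundle.end):
            d2 = sum((coords[ax] - pt[ax]) ** 2 for ax in range(3))
            labels[(d2 <= bundle.radius**2) & (labels == 0)] = next_label
            pair.append(next_label)
            next_label += 1
        region_ids.append((pair[0], pair[1]))

    truth = GroundTruth(
        bundle_masks=bundle_masks,
        endpoint_labels=labels,
        endpoint_region_ids=region_ids,
        mask=np.ones(shape, dtype=bool),
    )
    dwi = DWIImage(
        data=signal, b_values=b.copy(), b_vectors=g.copy(), affine=default_affine()
    )
    return dwi, tensors, truth


def default_diffusion_spec(
    grid_shape: tuple[int, int, int] = (24, 12, 12),
    radial_diffusivity: float = 0.3e-3,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DiffusionPhantomSpec:
    """Single straight x-axis bundle through the grid midline."""
    y = (grid_shape[1] - 1) / 2.0
    z = (grid_shape[2] - 1) / 2.0
    bundle = BundleSpec(
        geometry="straight",
        start=(2.0, y, z),
        end=(grid_shape[0] - 3.0, y, z),
        radius=2.0,
        radial_diffusivity=radial_diffusivity,
    )
    return DiffusionPhantomSpec(
        grid_shape=grid_shape, bundles=[bundle], noise_sigma=noise_sigma, seed=seed
    )
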