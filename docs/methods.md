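# Methods

This note documents the models behind `mconn`, the defaults and why they
were chosen, what the phantom generators do and do not emulate, and the
numerical conventions that matter for reproducing results.

## Functional phantom

The generator plants `K` spatial components on a voxel grid and mixes them
with cluster-structured time courses.

**Spatial model.** Each component is a Gaussian-profile sphere
`m(v) = A·exp(−‖v−c‖²/2r²)` truncated at `2r` (beyond which it is exactly
zero). Gaussian blobs are smooth, have controllable overlap, and resemble
the unimodal cores of real ICA maps. The brain mask is a centered
ellipsoid spanning 90% of the grid in each axis, which leaves a
well-defined one-voxel outer shell where artefactual "noise" components
are placed (random blobs on the shell with temporally white courses —
the spatial/spectral signature of motion and pulsation artefacts at the
brain edge).

**Temporal model.** Cluster factors `f` are drawn i.i.d. normal and mixed
by the Cholesky factor of the target factor covariance (unit diagonal,
requested correlations on named cluster pairs), giving the target
correlation exactly in expectation; a non-positive-definite request is
rejected. Component `k` in cluster `c` gets
`s_k = sign_k(√w·f_c + √(1−w)·η_k)` with unit-variance unique terms, so the
within-cluster correlation is `w` and the between-cluster correlation is
`√(w_c w_{c'})·ρ(c,c')`.

Both `f` and `η` are band-limited with a 4th-order zero-phase Butterworth
low-pass (default cutoff 0.1 Hz at TR = 1 s) *before* standardization and
mixing. Resting-state BOLD fluctuations are predominantly slow
(< 0.1 Hz), and the band limit is what lets the automated noise screen's
spectral criterion separate signal from the temporally white artefact
components. Applying the same linear filter to every latent series leaves
all cross-correlations unchanged (for jointly Gaussian series,
`corr(Lx, Ly) = corr(x, y)` under a shared filter `L`), so the `w`
calibration survives filtering; the test suite checks the empirical
within-cluster `r` against `w` to ±0.03 at T = 2000.

**Defaults.** Grid 20×20×12, 4 clusters × 3 components of radius 1.6
voxels laid out on a jittered lattice (blob cores ≳3 voxels apart so
components are spatially distinguishable), T = 300, TR = 1 s, amplitude
1.0 against `noise_sigma = 0.2` white voxel noise (peak-amplitude SNR 5),
`w = 0.6`, one anticorrelated cluster pair at ρ = −0.5 (the last two
clusters) mirroring the sensorimotor–limbic anticorrelation structure of
rodent RSNs. A cohort's "hypoperfused" arm lowers `w` to 0.3 in one
cluster; each subject draws an independent substream spawned from
`(seed, subject_index)` so cohorts are reproducible yet independent
across subjects.

**Not emulated.** Hemodynamic response convolution, motion and
physiological confounds, spatial autocorrelation of the noise, scanner
drift, and between-subject anatomical variability. Passing tests
therefore demonstrate correctness of the estimators under the assumed
mixture model, not robustness to real-data artefacts.

## Group ICA and noise screen

Subjects are voxel-wise demeaned and variance-normalized, then stacked in
time (voxels constant in any subject are dropped and reported). The
time dimension is PCA-reduced to the requested model order (default: the
number of PCs retaining 95% variance) and unmixed with fixed-point ICA
(logcosh contrast) applied over voxels, so the spatial maps are the
independent sources. The unmixing is applied to the uncentered principal
modes, which keeps the map subspace exactly equal to the top-q PCA
subspace (feature centering would otherwise shift each map by a
constant). Maps are unit-norm with the largest-|value| voxel forced
positive — this sign convention plus a fixed seed makes the decomposition
deterministic. Per-subject time courses come from least-squares
regression of each subject's normalized data onto the group maps (the
first dual-regression stage); these define all subject-level edges
downstream.

The noise screen is an automated stand-in for manual component
classification and flags a component if either (a) more than half of its
supra-threshold voxels (|z-scored map| > 2.3) lie on the outermost mask
shell, or (b) more than half of its time-course power (DC excluded,
averaged over subjects to avoid concatenation discontinuities) lies above
0.1 Hz. Components with an empty supra-threshold set are marked
indeterminate rather than noise. All four thresholds are exposed as
arguments. The screen is validated against the generator's ground-truth
noise flags; it is not claimed to reproduce any particular manual
classification of real data.

## Edges, clustering, and group comparison

Edges are Pearson correlations of component time courses per subject,
Fisher-transformed (`z = atanh r`, with |r| ≥ 1−1e−7 clipped under a
warning); group-level `r` is the tanh of the mean subject `z`
(variance-stabilized pooling). Components are clustered by average-linkage
agglomerative clustering on `d = 1 − r` using the *signed* correlation, so
an anticorrelated pair sits at distance 2 — this is what places
anticorrelated networks in different clusters. The dendrogram is cut to a
user-chosen `k` (no automatic selection); cluster ids are renumbered by
descending size with ties broken by smallest member index, making labels
deterministic. Group differences are tested per edge on subject `z`
values with Welch's t (Mann–Whitney U on request; both two-sided), and
Benjamini–Hochberg step-up FDR is applied over the `K(K−1)/2` unique
upper-triangle edges only. Seed-based maps correlate every voxel with the
mean in-seed time course on the temporally concatenated group matrix (or
average per-subject z maps when concatenation is off).

## Diffusion phantom, tensor fit, tractography

Bundles are tubes of radius `r` around a straight segment or a quarter
arc, with tensor `D = λ⊥I + (λ∥−λ⊥)t tᵀ` along the local tangent
(defaults λ∥ = 1.7e−3, λ⊥ = 0.3e−3 mm²/s; isotropic background
0.7e−3 mm²/s — white-matter-like against parenchyma). For an arc, the
endpoints must differ in exactly two coordinates; the arc lies in that
coordinate plane with its center at the corner keeping the start point's
first differing coordinate (one deterministic convention out of the two
geometrically possible quarter circles). The default acquisition is one
b = 0 plus 12 golden-spiral directions at b = 1000 s/mm². Rician noise is
`|S + n₁ + i n₂|` with independent Gaussian `n`; σ = 0 returns the exact
signal.

The fit is voxel-wise log-linear least squares on
`ln S = ln S0 − b gᵀDg`; nonpositive samples are dropped per voxel and
voxels left with fewer than 7 usable measurements (or < 6 distinct
gradient directions) are marked invalid. Negative eigenvalues are clamped
to zero and counted per volume. The noiseless round trip recovers the
true tensors to ~1e−17, far below the 1e−6 tolerance asserted.

Tracking is a simplified probabilistic streamline sampler: at each step
the direction is one von Mises–Fisher draw (Wood's simulation, S²) around
the nearest-voxel principal eigenvector, sign-aligned with the previous
direction; propagation stops on FA below `fa_stop` (default 0.15), a turn
beyond `angle_limit_deg` (default 60°), leaving the grid/valid mask, or
`max_steps`. Each seed voxel spawns `n_samples_per_seed` streamlines
tracked in both directions; the forward half starts along the reversed
first backward step so the angle limit also holds across the seed
junction, and every consecutive segment pair respects the limit by
construction. Steps are 0.5 voxels; points are reported in world mm via
the NIfTI affine with half-open voxel ownership `[i, i+1)` under 0-based
indices. `dispersion_kappa` controls angular spread (κ = 400 ≈ 2.9° s.d.
is used for the "high concentration" connection-rate checks; κ ≈ 60–150
gives visibly dispersed fans).

Connectome edges count each streamline once for the unordered pair of
first and last labeled regions it touches (endpoint convention, stated
explicitly because visitation-based counting is also common); streamlines
touching fewer than two distinct labeled regions are ignored and tallied.
Weights are `ln(1 + count)` so zero counts are defined; the diagonal is
forced to zero.

The synthetic parcellation grows `n` connected regions from random
foreground seeds by multi-source breadth-first flood fill
(6-connectivity), guaranteeing nonempty connected labels partitioning the
brain mask.

## Graph metrics

Networks are binarized at a matched density before metric computation
(proportional threshold: keep the top `⌊d·n(n−1)/2⌋` unique edges by
weight, ties broken lexicographically by `(i,j)` for determinism; −inf
marks absent edges and is never kept), because edge density itself drives
most graph parameters. For functional matrices the default is to
threshold the signed weights (most-positive edges survive); thresholding
|z| instead is the caller's choice. Metrics use the standard binary
definitions — global efficiency as the mean inverse shortest-path length
over ordered pairs with 1/∞ = 0 (disconnection is not an error), local
efficiency as the global efficiency of the neighbor-induced subgraph
(degree < 2 ⇒ 0), transitivity as 3·triangles over connected triples with
0/0 ⇒ 0, and degree as adjacency row sums. Shortest paths come from
scipy's csgraph; the test suite checks all four metrics exactly against a
naive Floyd–Warshall + exhaustive-triangle reference on hundreds of random
graphs (n ≤ 8), plus bounds, edge-addition monotonicity, and isomorphism
invariance.

## Statistics

Welch's unequal-variance t with Welch–Satterthwaite degrees of freedom is
the default two-sample test; Mann–Whitney U (normal approximation, tie
correction) is available where normality is doubtful. Normality
pre-testing is deliberately not automatic — the choice is an explicit
flag, which keeps analyses reproducible. Samples identical across both
groups return p = 1 with a degeneracy flag rather than NaN. BH-FDR is the
step-up rule: the threshold is the largest ranked p with
`p(i) ≤ i·α/m`, and everything at or below it is rejected; the
implementation is cross-checked against statsmodels in the tests, and
1000-replicate null simulations confirm empirical FDR ≤ α + 0.02.

## Problem sizes and determinism

Default phantom sizes (20×20×12 functional grids, T = 300; 24×12×12
diffusion grids, 13 gradient volumes) were chosen so that a full
Monte-Carlo validation — 20-seed recovery runs, 20-replicate power
studies, 200-replicate null calibrations — completes in minutes on a
single CPU while keeping all planted effects comfortably detectable;
they are analysis-scale choices, not estimates of any scanner protocol.
All randomness flows from explicit integer seeds through numpy
Generators (per-subject substreams via spawned SeedSequences), NIfTI
gzip output is written with fixed metadata, and reruns of the demo
pipelines produce byte-identical outputs — the report's SHA-256 checksums
are asserted equal across reruns in the tests.

## Known limitations

- Spatial ICA recovery is evaluated against the planted maps expressed in
  the pipeline's normalized units (map divided by each voxel's total
  temporal s.d.), since per-voxel variance normalization deliberately
  discards amplitude information.
- The tracker uses a single-tensor orientation field: crossing or fanning
  fibers, multi-shell schemes, and anatomical constraints are out of
  scope.
- The noise screen's two criteria target the generator's artefact model
  (edge-shell blobs, white spectra); real artefact taxonomies are richer.
- Voxel-wise FA comparison is a plain mass-univariate test on
  co-registered volumes; no skeletonization, smoothing, or registration
  is performed.
- Negative functional edges are kept on the signed scale throughout;
  whether to exclude or rectify them before graph analysis is exposed to
  the user rather than decided by the package.
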