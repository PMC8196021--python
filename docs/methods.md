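# Methods

This note documents the models, numerical choices, and open design decisions
behind `netdisrupt`, and states precisely what the synthetic phantom does and
does not emulate.

## Phantom model

**Geometry.** The brain is an axis-aligned ellipsoid filling ~46% of each
grid dimension (3768 in-brain voxels on the default 24×24×16 grid).
Seventeen ellipsoidal blob structures are placed at seeded random interior
positions, pairwise disjoint and fully inside the brain: three visual (VIS),
seven executive-control (EX), three sensorimotor (SM) structures, and one
aggregate structure each for the cerebellar (CERE), default-mode (DMN),
salience (SAL), and basal-ganglia (BAS) networks. Default blob semi-axes are
drawn from 1.8–2.8 voxels; placement failure raises an error naming the
structure. A network mask is by construction the exact union of its member
structures.

**Signal.** Every network carries one latent time course shared by all of
its structures — this shared course is what makes networks recoverable by
matrix decomposition. At rest the latent is Gaussian noise band-limited to
0.01–0.1 Hz (rFFT masking, unit sd), matching the classical resting-state
fluctuation band; for block designs it is the stimulus regressor plus a
small band-limited fluctuation (sd 0.2). The block regressor is a boxcar
(15 s dead time, then six 30 s ON / 30 s OFF cycles at TR = 3 s → 125
volumes; rest runs are 305 volumes) convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, via nilearn's
`spm_hrf`) and peak-normalized to 1.

**Voxel model.**

    x_v(t) = baseline + amplitude · jitter_net · f_struct · latent_net(t) + ε_v(t)

with defaults baseline 100, amplitude 1, log-normal per-(subject, network)
amplitude jitter (sd 0.1), and AR(1) Gaussian noise ε (marginal sd 1,
lag-1 coefficient 0.3) independent across voxels. The injury factor
`f_struct` is 1 for controls; for injured subjects it is the configured
multiplicative factor (attenuation < 1 = damage, elevation > 1 =
compensation). A multiplicative effect was chosen because the scientific
question is hypo- vs hyper-activation of an existing network course, not an
additive confound. All outputs are deterministic functions of (inputs,
seed).

**What the phantom does *not* emulate:** realistic neuroanatomy, motion and
susceptibility artifacts, physiological (cardiac/respiratory) noise, spatial
noise correlation, scanner drift, or inter-subject anatomical variability
(registration is identity by construction). Passing tests therefore
demonstrate correctness and calibration of the *analysis machinery* under a
plausible signal model — not performance on acquired data.

## Preprocessing

The first five volumes of each run are dropped (magnetization steady state):
305 → 300 rest, 125 → 120 task volumes. In-brain voxels are rasterized in a
fixed order (ascending linear index, first spatial axis fastest) shared by
every subject, map, atlas mask, and permutation field. Group datasets
temporally concatenate the trimmed runs of one (paradigm, group) cell — six
datasets for the default design: rest 7/5, visual task 6/5, tactile task 4/5
controls/injured, giving 2100/1500/720/600/480/600 columns. Each voxel's
time series is centered and scaled to unit variance **within its subject
span** (both switchable); the sparsity weight λ = 0.15 is calibrated against
this scale. No per-subject global variance normalization is applied.

## Sparse dictionary learning

The group objective is minimized by block coordinate descent:

* **Coding step** — each voxel's LASSO problem
  ½‖s_j − Dα_j‖² + λ‖α_j‖₁ is solved exactly by cyclic coordinate descent
  (`sklearn.decomposition.sparse_encode`, `lasso_cd`, tol 1e-6, ≤1000
  sweeps). Tests pin this to a closed-form single-atom soft threshold and to
  an independent FISTA solver (≤1e-6 relative objective; observed ~1e-16).
* **Dictionary step** — each atom is updated by unit-norm-constrained least
  squares on its active voxel set, `d_k ← E_k a_k / ‖E_k a_k‖` (codes held
  fixed, so the objective cannot increase; the L1 term is untouched).
  Dead atoms (all-zero codes) are re-seeded from the worst-reconstructed
  voxel's residual course.
* **Initialization** — the leading temporal singular vectors of the data
  (surplus atoms from random voxel courses). Energy-ordered initialization
  starts the fit from the shared network courses regardless of how few
  voxels a structure occupies; seeded-random initialization was observed to
  miss small networks in a nontrivial fraction of fits.
* **Termination** — at most `max_outer_iters` outer iterations (default 15;
  10 in the pipeline, 6 in the demo) or relative objective decrease below
  1e-6. Failure to decrease emits a convergence warning, never an error; the
  objective trajectory is recorded and tested to be non-increasing within
  coding-tolerance slack.

Component sign convention (sDL and ICA alike): each component is flipped so
its maximum-absolute-weight voxel is positive, making the positive-tail
z-threshold meaningful and all pipelines deterministic under seed.

**Dual regression.** Stage 1 solves `s_i = D_i α_g` by OLS on the group-map
Gram matrix (Cholesky; on rank deficiency a ridge jitter of 1e-8·tr(G)/k is
applied with a warning), then normalizes `D_i` columns to unit norm —
absorbing scale into stage 2, which sparse-codes `s_i` against `D_i` at the
same λ. The procedure is scale-consistent: scaling `s_i` by c and λ by c
scales `α_i` by c.

## Group ICA and back-reconstruction

The time×voxel group matrix is spatially centered per time point and
SVD-reduced to k components (70 at study scale; fewer in desk-scale runs,
bounded by min(voxels, time)). FastICA (logcosh contrast, tol 1e-6, ≤1000
iterations, seeded; non-convergence warns and returns) unmixes the whitened
spatial signals into independent maps. We use FastICA rather than Infomax:
both maximize non-Gaussianity of spatial sources and FastICA's symmetric
decorrelation keeps maps exactly uncorrelated, which the tests assert.
Back-reconstruction projects each subject's partition of the data through
the stored reduction: `α_i = A⁻¹ · pinv(G_i) · (Y_i − m_i)` with `G` the PCA
basis, `A` the ICA mixing, `m` the stored spatial means. This is the
single-level-PCA analogue of GIFT-style back-reconstruction; for a
single-subject "group" it reproduces the group maps exactly, and for
identical subjects it returns identical maps (both tested). The two-level
per-subject-PCA GIFT variants are intentionally not replicated.

## Atlas metrics and group tests

Subject maps are divided by the maximum **absolute** group-map value of
their group fit (component signs being conventional), then thresholded:
per map, z-scores over in-brain voxels with *population* mean/sd; voxels
with z < 1 are zeroed, survivors keep their normalized value; constant maps
are zeroed with a warning. Both atlas metrics are computed on these
normalized, thresholded maps (switchable). Pearson r is computed against the
binary atlas indicator; it is invariant to positive affine map rescaling,
and the mean ratio (inside mean / outside mean within brain; undefined when
the outside mean is 0) is invariant to positive scaling.

Maximal-map selection: ICA takes the single best-Pearson component; sDL
averages the three distinct best-Pearson atoms (unweighted) and recomputes
both metrics on the average. Ties break to the lowest component index;
undefined correlations rank last. Structure-level metrics reuse the
network's final map; the cerebellar network is reported network-level only.

Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite df) compares
groups per region and metric; undefined values are dropped with a count and
fewer than two defined values per group skips the test. A variance floor of
1e-12 guards the degenerate zero-variance case. The dual-metric rule marks a
region significant only when both metrics have p < 0.05 with agreeing
direction; decreases and increases are reported separately (`*`/`#` in the
report). No multiplicity correction is applied at this stage by design.

## Permutation test

All C(N_C+N_T, N_C) relabelings are enumerated in lexicographic order (the
true assignment first) and T = mean_C − mean_T computed voxelwise for each.
One-sided rank p-values count ties conservatively (≥/≤) and include the true
assignment, so p ≥ 1/n_permutations everywhere; decrease/increase flags are
p ≤ α (default 0.05) and are provably disjoint for α < ½. T_actual is
computed through the same vectorized arithmetic path as the permuted values
so that its self-tie is exact in floating point. Tests run over all in-brain
voxels; percentages are then taken within each region's own atlas voxels.
Swapping group labels negates T_actual and exchanges the flag sets exactly
(tested). No multiple-comparison correction is applied, mirroring the
small-cohort setting where 1/792 already bounds the attainable p-value; a
hook for adding one exists in the calling code but is off by default.

## Standing experiments

**Type-I calibration** (`experiments.null_calibration`): 12 subjects (7 + 5
labels) from identical settings with planted amplitude 0 — pure AR(1) noise
around baseline — each summarized by a continuous voxelwise temporal-sd
amplitude map, then the exact test at every in-brain voxel. Under the null
the rank p-value is uniform on {1/792, …, 1}, so the expected decrease-flag
rate at α = 0.05 is ⌊0.05·792⌋/792 ≈ 4.92%; the test asserts the observed
rate lies in the 99% binomial envelope around 0.05. Continuous maps are
essential here: the pipeline's thresholded sparse maps carry mass ties at
zero that make the exact test strictly *conservative* — that direction is
covered by a separate super-uniformity test on iid maps.

**Attenuation recovery** (`experiments.attenuation_recovery`): the full sDL
pipeline on a phantom whose VIS network is attenuated ×0.3 in 5 injured
subjects vs 7 controls (rest runs of 100 volumes, trim 5, 24 atoms,
λ = 0.15). The dual-metric Welch rule must flag the network as decreased on
both Pearson and mean-ratio metrics. Desk-scale problem sizes (grid
24×24×16 ≈ 3.8k in-brain voxels, 95-volume runs, 24 atoms) were fixed once
as the package's study conditions; study-scale settings remain available
through `RunConfig` defaults.

## Known limitations

* λ = 0.15 is interpreted against unit-variance voxel time series; the
  original calibration scale is unknown, so absolute sparsity levels may
  differ from analyses on raw-scale data.
* Single-level group PCA back-reconstruction; GICA1/GICA3 two-level
  variants are not implemented.
* ICA maximal-map selection is a pure argmax — no artifact-component
  screening.
* The phantom's independence of voxel noise makes the binomial calibration
  envelope tight; spatially correlated noise would widen the variance of
  the flag rate without biasing it.
* Exhaustive enumeration is intended for small cohorts (≲ a few thousand
  assignments); no Monte-Carlo fallback is provided.
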