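# Methods

## The estimators

**FC.** Within-subject functional connectivity is the Pearson correlation
between a subject's node time courses, Fisher z-transformed
(`z = arctanh r`). Optionally (on by default) each subject's off-diagonal
edge vector is standardized to zero mean / unit variance, removing
subject-level global correlation offsets. FC mixes three sources of
covariance: stimulus-evoked signal, intrinsic fluctuations that are
correlated across nodes within a brain, and subject-global artifacts.

**ISFC.** Leave-one-out inter-subject functional correlation replaces the
within-brain pairing: node *i* of subject *s* is correlated with node *j*
of the element-wise mean time series of the remaining group members, for
all ordered pairs (i, j); values are Fisher z-transformed and the two
directions averaged into a symmetric matrix. Because intrinsic dynamics
and artifacts are statistically independent across subjects, they cannot
contribute to the expectation of these cross-brain correlations; only
stimulus-locked components survive. The diagonal of an un-normalized ISFC
matrix is each node's classical inter-subject correlation and is excluded
from all edge statistics. Per-subject edge z-normalization is available
for ISFC but off by default (it is a within-subject global-effect
correction, and ISFC has no within-subject global term to remove).

**Inference.** Per edge, an independent-samples pooled-variance t-test
compares the two groups' z values (Welch available by option); positive t
means first group > second. The null is built by relabeling the pooled
subjects into groups of the original sizes; in ISFC mode the entire
leave-one-out construction is recomputed inside each permuted group, so
the null reflects the full estimator, not just the t-test. Directional
empirical p-values use the standard +1 smoothing,
`p = (1 + #{t_null ≥ t_obs}) / (1 + N_perm)`, which counts the observed
labeling among the relabelings and keeps p strictly positive.
Benjamini–Hochberg FDR is applied across edges separately per direction.
Note the resolution floor: with E edges the smallest attainable BH q is
`E / (N_perm + 1)`, so q ≤ 0.05 over ~400 edges needs on the order of
10,000 permutations (the default; tests and the reproduction script use
1,000 and assess significance on empirical p).

## Preprocessing

Node series are z-scored, a discrete-cosine drift basis is regressed out,
and the residual re-standardized. The basis contains the DCT-II components
with period `2·T·TR/k ≥ cutoff` (default cutoff 128 s; the component whose
period equals the cutoff is included, following the common SPM-style
convention). Order of operations — standardize, filter, re-standardize —
is a fixed convention of this package. Matched runs are averaged
element-wise before connectivity.

## Synthetic data

The generator emulates a block-design visual experiment: per condition,
10 s stimulus blocks separated by 6 s rest, 7 repetitions, conditions
interleaved without overlap, sampled at TR = 2 s; boxcars are convolved
with a canonical double-gamma hemodynamic response (gamma-density
difference, peak ≈ 5 s, undershoot ≈ 16 s, undershoot ratio 1/6,
configurable).

Each node's signal is a sum of three components:

* **Stimulus-locked** (shared within a group): a group-specific mixing
  matrix applied to an orthonormal stimulus basis. The basis is obtained
  from the HRF-convolved condition regressors by mean-centering,
  projection onto the analysis band (the DCT drift space below the 1/128
  Hz cutoff is removed, mirroring the preprocessing filter) and QR
  orthonormalization in condition order, scaled to unit sample variance.
  Consequently the stimulus component of mixing matrix M has sample
  covariance exactly `M Mᵀ`, the implied inter-node correlation is the
  cosine similarity of M's rows — this is the analytic ground truth — and
  the high-pass filter of the analysis leaves it untouched. Building the
  basis inside the analysis band matters: raw interleaved boxcars are
  mutually anti-correlated at low frequencies, and orthogonalizing outside
  the band would leak negative correlation into filtered data.
* **Intrinsic** (private per subject): AR(1) noise in time (ρ = 0.3) with
  exchangeable cross-node correlation (default 0.3; 0.5 in the
  separation check), unit stationary variance, scaled by `intrinsic_sd`
  (default 1.0 — equal in power to a unit-norm stimulus row). This is the
  simplest structure that contaminates FC (through the cross-node term)
  while leaving ISFC unbiased.
* **Artifacts** (private per subject, shared across that subject's
  nodes): a linear drift with N(0, 1)-scaled slope, Poisson spikes
  (rate 0.01/sample, amplitude 3), and a respiratory-like 0.3 Hz sinusoid
  (amplitude 0.3) with random phase.

Randomness is a single seeded `SeedSequence` with per-subject spawned
sub-streams; identical seeds give bit-identical panels.

`planted_pair_mixing` plants a group difference on one edge: the two edge
nodes load on private sources with correlation `r_a` vs `r_b`; background
nodes are spread over graded angles in the leftover source subspace so
their pairwise stimulus correlations take a realistic range in [0, 1)
rather than saturating at 1. The default planted contrast is
`Δz = 0.4` on a base correlation of 0.3 (r 0.61 vs 0.30), between groups
of 10 — the study-scale difference the power analysis targets.

What the generator does **not** emulate: hemodynamic nonlinearity and
vascular heterogeneity, spatially structured (non-exchangeable) intrinsic
correlation, motion-induced spatial interpolation artifacts, and
scanner-specific noise spectra. Passing tests therefore demonstrate the
statistical machinery (estimator identities, calibration, power under the
assumed signal/noise structure), not robustness to every property of real
BOLD data.

Behavior generation: a latent composite
`intercept + group·code + edge·ISFC_edge + noise` (defaults 1, −6, 5,
noise sd 0.5), with each subject's ISFC z on the planted edge as the edge
value; two observed percent-correct measures are the composite plus
independent noise sized to give a target inter-measure correlation
(default 0.7), affine-mapped onto plausible scales. The latent composite
is retained so that regression-recovery checks compare against the
generating coefficients in their own units (the pipeline's composite is
in PC1 units of the z-scored measures, a different scale by construction).

## Parcellation

Seed-correlation maps include a voxel when Pearson r with the seed time
course is ≥ the threshold (boundary included; default 0.5), within the
gray-matter mask. The union of two seed maps carries per-voxel tags
(seed-1-only / seed-2-only / both). Ward agglomeration runs on voxel time
courses under a spatial adjacency constraint (6-connectivity by default,
18/26 available) so every parcel is contiguous; disconnected mask
components are clustered separately with the cluster budget divided in
proportion to component size (each component gets at least one, largest
remainder rule). Clusters below 10 voxels are eliminated; node tags are
the modal voxel tag with exact ties resolved conservatively to "mixed";
node centers are mean MNI-mm coordinates via the volume affine.

## Topology

Strength, gradient and module metrics operate on the non-thresholded
positive part of the contrast's t matrix (direction "negative" negates
first). Ranks are descending with ties broken by node id. The gradient
analysis sorts nodes by ascending MNI Y (posterior → anterior), splits
them into equal-count bins — when the count does not divide evenly the
extra nodes go to the most posterior bins — and Spearman-correlates bin
index with per-bin mean strength over bin counts 10–21 (bin counts larger
than the node count are skipped; an all-tied strength vector returns
rho = 0 with a degeneracy flag rather than an error). Enrichment of
face-tagged nodes among the top ranks uses a df = 1 goodness-of-fit χ²
against the 35% base rate without continuity correction. Module metrics
use the three functional tags as modules: participation
`P_i = 1 − Σ_m (s_im/s_i)²` (isolated nodes get P = 0, flagged) and the
within-module weighted degree z-score (population sd within the node's own
module; singleton or zero-spread modules get z = 0, flagged). The raw
within-module strength is also exposed since "weighted degree" is used
both ways in the literature; the z-score form is the one the hub
threshold (> 2) belongs to. Connector hubs are module hubs with
0.3 ≤ P ≤ 0.75 (bounds inclusive). Where summary rows are averaged (the
anterior-temporal worked example), voxel counts are the weights.

## Behavior link

The two measures are z-scored and PCA is the eigendecomposition of their
2×2 correlation matrix, so PC1's variance explained is exactly
`(1 + |r|)/2`; PC1's sign is fixed by positive loadings (alignment to the
first measure if r < 0), preventing seed-dependent sign flips. The
regression is OLS of the composite on intercept + group (control = 0,
CP = 1) + edge value, with a condition-number guard (> 1e10 rejects
collinear designs).

## Numerical conventions

* Correlations are clipped to ±(1 − 1e−7) before `arctanh`, giving a large
  finite z (≈ 8.4) for degenerate identical series.
* FC diagonals are stored as 0 and excluded from statistics; ISFC
  diagonals hold the inter-subject correlation and are likewise excluded.
* Edge vectors use the upper triangle (i < j); long-format files store
  each undirected edge once.
* Monte-Carlo permutations are drawn as uniform relabelings with
  replacement; an exhaustive mode enumerates all C(n, n_A) splits for
  small cohorts.

## Calibration testing under edge dependence

Edges of one simulated cohort are strongly dependent — they share the
same subjects and the same leave-one-out group means — so goodness-of-fit
tests that assume independent p-values (e.g. a KS test pooled over all
edges) reject spuriously even though permutation p-values are exactly
uniform marginally under exchangeability. The calibration checks
therefore use the replicate as the independence unit: across 10
independently simulated null cohorts (2 × 10 subjects, 30 nodes, 1,000
permutations each), a KS test on one fixed edge's directional p, a t-test
that the replicate-mean p equals 0.5, and the mean BH pass fraction at
q* = 0.05 (required ≤ 5%).

## Problem sizes used in the checks

Estimator identities run at toy scale (4 subjects × 5 nodes × 50 samples
against a brute-force double loop, agreement to 1e−12). Statistical
properties run at the study scale the package targets: 10 subjects per
group; 30 nodes (calibration, FC/ISFC separation at T = 500) or 10 nodes
(power, T = 240); 1,000 permutations; 10 null and 20 power replicates.
The reproduction script (`scripts/acceptance.py`) uses the same sizes.

## Known limitations

* The permutation test's FDR resolution is bounded by `E/(N_perm + 1)`;
  under-permuted runs silently lose q-level significance (empirical p is
  unaffected).
* Exchangeable intrinsic correlation is a deliberate simplification; real
  intrinsic covariance is spatially structured, which would change FC
  contamination patterns but not the ISFC expectation argument.
* With a single planted edge, descriptive strength rankings over many
  nodes are noise-dominated; rankings become informative when differences
  are distributed over many edges, as in real group contrasts.
* Module z-scores are unstable for very small modules; the degeneracy
  flags should be consulted before interpreting hub calls on few-node
  modules.
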