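# Methods

## The measure

For a population of `n` units observed over `S` task states, the activity
matrix `A ∈ ℝ^{n×S}` is summarized by the eigendecomposition of its
unit × unit second-moment matrix `X Xᵀ`, where `X` is `A` after the chosen
per-unit rescaling (below).  Projecting a second task's prepared matrix onto
these components gives per-direction variances
`v_k = Σ_s (u_kᵀ x_s)²`; the normalized running sum
`c_k = Σ_{i≤k} v_i / Σ_{i,s} x_{is}²`, prefixed with an origin point `c₀ = 0`
and plotted over the PC index rescaled to [0, 1], is integrated by the
trapezoidal rule.  Equivalently the AUC is the linear functional
`Σ_k m_k (1 − (k − ½)/K)` of the normalized variances `m_k` — a form used
internally for speed and for reasoning about degenerate cases.

Two exact consequences anchor the implementation: a uniform spread of
variance gives AUC = 0.5 (so 0.5 is the chance level for any data whenever
the basis is independent of it, by linearity of expectation), and variance
concentrated on the first direction gives `1 − 1/(2K)`.  Both are unit
tests.

### Scaling modes

The per-unit preparation is an explicit parameter because different data
call for different second-moment conventions:

* `raw` — no transformation; `X Xᵀ` is the uncentered second moment.  This
  is the default for beta-matrix (fMRI) pipelines, whose natural statistic
  is `B Bᵀ`.
* `centered` — per-unit mean across states removed (covariance convention).
* `zscored` — centered and divided by the per-unit **sample** sd (ddof = 1),
  under which `X Xᵀ = (S−1) ×` the unit × unit correlation matrix.  Default
  for rate-map pipelines, where units differ widely in mean rate.

A unit with zero variance across states cannot be z-scored and raises a
named error rather than propagating NaNs.

### Within/across and the gap

The within-task baseline is the self-projection AUC (data on its own PCs),
the ceiling of the measure; a split-half baseline is not needed for
noise-free simulations and is deliberately not the default.  Across-task
AUCs are symmetrized (both projection directions averaged).  The statistic
throughout is the *gap* = within − across: ~0 under shared subspaces, large
under remapping.

## Rate maps

Standard free-foraging construction: 64 × 64 bins by default, occupancy from
per-sample forward time steps, spike positions from the nearest trajectory
sample, rate = counts / occupancy, then a 5-bin boxcar.  Choices the
literature leaves open, fixed here:

* bin edges half-open `[lo, hi)`, final bin closed;
* occupancy threshold 0.1 s — emptier bins count as unvisited and are
  imputed from the renormalized boxcar mean of visited neighbors (policy
  `"zero"` available), so NaNs never reach the PCA;
* boxcar kernels are renormalized over in-bounds bins at the arena edges
  (no zero-padding bias); mass is therefore conserved exactly only away
  from edges, which the tests pin down;
* normalization is per-cell `peak` (max → 1) or `zscore`; "peak" is the
  default because downstream z-scored PCA is invariant to it while plots
  stay interpretable.

## Grid-module simulator

A grid cell is the rectified sum of three plane cosines with wave vectors
60° apart and magnitude `4π/(√3·spacing)`, evaluated on a 50 × 50 grid over
a 10 × 10 box.  A module places one cell at every node of a 116 × 116 phase
lattice tiling the unit rhombus (13,456 cells), which makes the
module-average map constant over the box up to discretization (coefficient
of variation < 1e-4 in practice).

**Defaults.**  Spacings {1.5, 2.1, 2.95, 4.15} box units (≈√2 progression)
with orientations {0°, 7.5°, 15°, 22.5°}.  The spacing scale was chosen so
each module fits 2.4–6.7 periods into the box, matching typical rodent
arena-to-spacing ratios.  This matters: with ≲2 periods per box, boundary
effects dominate the block-averaged voxel maps and coherent realignment no
longer preserves the voxel-level subspace, i.e. the simulation would fail to
show the very property it exists to demonstrate.  Threshold 0 (plain
zero-clipping of the cosine sum).

**Realignment.**  Between environments a module shifts all its cells by one
common phase offset (optional rotation, default 0), drawn independently per
module.  Shifts are snapped to the phase lattice, under which the realigned
population is *exactly* a permutation of the original — pairwise
correlations are conjugated by a known permutation and the population
subspace is identical, giving the tests an exact oracle
(`realignment_permutation`).  For random (non-lattice) cell subsets the
preservation is approximate, degraded only by finite-box boundary terms.

**Pseudo-voxels.**  Each module is cut into 4 groups (4 modules × 4 groups =
16 voxels; 3,364 cells per voxel at defaults).  A fraction `ratio_random` of
cells is removed first and assigned to groups uniformly at random; the
remainder is sorted lexicographically by rhombus coordinates and cut into
contiguous blocks ("grouped by phase").  Group sizes are equal within ±1
cell and membership depends only on (grouping seed, phases) — never on the
environment — so grouping and realignment commute.  Cell maps are
peak-normalized before averaging, which is what makes the phase-grouped
voxels carry ~10²× more spatial variance than randomly grouped ones.
Measurement noise is i.i.d. Gaussian per voxel per bin, added after
averaging; sd 0–0.1 spans the interesting regime (randomly grouped voxel
signal has sd ≈ 0.005 after averaging 3,364 cells, so sd 0.02 already
swamps it, while phase-grouped signal survives sd 0.1).

## Resampling inference

All p-values use the add-one smoothing `p = (1 + hits)/(1 + draws)` and are
one-sided toward "gap smaller than chance" (generalization); a two-sided
alternative is a flag.

* **Identity shuffle** — the null permutes the unit identities of the second
  environment only; the self-projection terms are permutation invariant, so
  the null isolates the across-environment alignment.
* **Count-matched subsampling** — gap statistics of one population are
  ranked against a null built by repeatedly subsampling a reference
  population (without replacement) to matched per-animal cell counts,
  pooling both projection directions across animals.
* **Low-resolution bootstrap** — per draw and animal, two groups of seven
  cells are sampled *with replacement* (groups independent, the same cells
  used in both environments) and averaged into pseudo-units, which are
  concatenated across animals; both projection directions contribute, so 400
  draws yield an 800-value gap distribution.  This emulates supra-cellular
  (voxel-like) resolution from spike data.
* **Distribution comparison** — two-sample Kolmogorov–Smirnov via
  `scipy.stats.ks_2samp`, with a 50-bin, window-9 smoothed histogram emitted
  purely for display.

## fMRI pipeline

Input: per run r ∈ {1..4} and graph g ∈ {Hl, Hs, Cl, Cs} a voxels ×
conditions beta matrix (10 conditions by default).  For held-out run j and
ordered pair (a, b), PCs come from the mean of graph a over the runs ≠ j and
graph b's run-j matrix is projected; the AUC, averaged over the four folds,
fills entry (a, b) of the 4 × 4 alignment matrix.  PCs and data never share
a run, including on the diagonal.  Scaling default `raw`.

**Rank handling.**  A 100 × 10 source has rank ≤ 10; eigenvectors beyond the
rank are an arbitrary orthonormal completion, and the variance the projected
data puts on *individual* completion directions is solver noise.  The
pipeline takes the informative directions from an economy SVD and assigns
the orthogonal-complement variance uniformly across the remaining K − r
directions — exactly the expected AUC over a Haar-random completion, and
deterministic.  For full-rank sources this equals the generic
eigendecomposition path to machine precision (tested).

**Contrasts** (entry written XY = data graph X on PCs of graph Y):

* visual: [HlHl + ClCl + HsHs + CsCs] − [HlHs + HsHl + ClCs + CsCl]
* structural: [HlHl + HlHs + HsHl + HsHs] − [HlCl + HlCs + HsCl + HsCs]

**Searchlight.**  Per in-mask center, the 100 nearest in-mask voxels by
Euclidean distance on integer grid coordinates (center included; exact
integer distances, ties broken by linear index) define the submatrix; the
alignment matrix and contrast are computed there.  The implementation
batches the per-center SVDs, which is what makes whole-cohort calibration
runs tractable on one CPU.

**Group inference.**  One-sample t per voxel; the null flips each subject's
map sign and records the max t over the mask; FWE p = (1 + #{null max ≥
t})/(1 + flips).  Cluster-enhancement statistics are deliberately out of
scope — the max-statistic variant keeps the identical sign-flip scaffold and
null-max logic without introducing enhancement parameters.  An exhaustive
mode enumerates all 2ⁿ sign patterns (p = hits/2ⁿ, the identity pattern
included), which yields exact small-sample oracles such as p = 1/1024 for
ten concordant subjects at one voxel.  With sd = 0 the t statistic is ±inf;
comparisons are defined so that only sign patterns reproducing the
degeneracy count as extreme.

## Synthetic beta generator

For graph g of family f(g) ∈ {H, C}, run r:

`B_{g,r} = (W_{f(g)} Z_{g,r} + W_{g,r} Z'_{g,r}) / √d + ε`,
`ε ~ N(0, noise_sd²)`.

`W_f` (voxels × round(overlap·d)) is drawn once per subject per family and
supported only on the effect region; all remaining loadings `W_{g,r}` are
redrawn *per run*.  Condition codes Z are fresh per run and graph — there is
deliberately no condition correspondence across graphs or runs, so cross-run
generalization can only come from the run-stable family loadings.
Consequences, both tested: overlap = 0 puts every alignment entry at chance
(the structural contrast is null by construction), and overlap = 1 elevates
all four within-family entries.  The null region for calibration is defined
as the voxels whose own searchlights contain no effect voxel, computed with
the pipeline's neighborhood routine (near box corners a 100-voxel
searchlight reaches much farther than in the bulk, so a fixed distance
margin would misclassify).

Defaults (`fmri_small` preset): 12 subjects, 10 × 10 × 10 volume, 4 runs,
10 conditions, d = 6, overlap = 1, noise_sd = 0.5, effect ball of radius 2.6
centered at voxel (2, 2, 2).  With these settings the structural contrast at
effect voxels is ≈ 0.8 per subject against a null sd of ≈ 0.03, giving
essentially complete detection power at 1,000 sign flips while leaving a
clean 600-voxel null region.  The volume size was set so a full 12-subject
cohort with k = 100 searchlights runs in well under a minute.

The trajectory generator is an Ornstein–Uhlenbeck velocity walk (relaxation
1 s, speed scale 2 units/s) reflected at the walls, with per-step Poisson
spiking from the rate surface and uniform within-step jitter.

## What the generators do and do not emulate

The simulators reproduce the *statistical* structure the measure is
sensitive to: shared low-dimensional loadings, coherent phase realignment,
remapping, supra-cellular averaging, white measurement noise.  They do not
model hemodynamics, temporal autocorrelation, scanner drift or motion,
conjunctive/border cells, theta dynamics, or anatomical geometry; passing
tests therefore demonstrate correctness of the measure and its inference
machinery under the stated generative assumptions, not robustness to fMRI
preprocessing artifacts or to biological heterogeneity beyond the modeled
kinds.

## Numerical choices

* Eigenvalues below 1e-12 × max are clipped to zero; tiny negatives from
  symmetric eigensolvers are clipped at −1e-10.
* Orthonormality and curve-endpoint invariants are enforced at 1e-8.
* Haar-random bases come from QR of a Gaussian matrix with the R-diagonal
  sign fix (without it the distribution is not uniform).
* Ordering among exactly tied eigenvalues is solver-dependent; every
  reported quantity depends only on partial sums over well-separated
  spectral blocks, so outputs are stable, and the rank-handling rule above
  removes the one place where ties (the null space) could have leaked in.
* Cell-map rendering uses float32 (the maps are bounded in [0, 3]);
  all averaging and downstream linear algebra accumulate in float64.
* All randomness flows through `numpy.random.Generator` seeds;
  `SeedSequence.spawn` derives independent child streams for per-module and
  per-subject generators, so outputs are bit-reproducible.

## Problem sizes in the test suite

Unit tests run on desk-scale stand-ins (12 × 12 phase lattices, 25 × 25
boxes, 3-animal bundles of 20 cells); the end-to-end suite uses the full
default simulator (116 × 116 lattices, 50 seeds for the noise sweeps, 20
cohort replications for searchlight calibration), sizes chosen to make the
Monte-Carlo assertions stable while keeping the whole suite in the
ten-minute range on a single core.

## Known limitations

* The AUC compares *linear* subspaces; nonlinear manifold alignment, CCA or
  Procrustes-style fits are out of scope.
* The within-task baseline defaults to self-projection; with very noisy
  data the even/odd split-half baseline (`generalization_gap(...,
  baseline="splithalf")`) is less optimistic but halves the state count.
* The low-resolution bootstrap reuses cells across draws; its distribution
  is a bootstrap, not an exact null, and is used only for distribution
  comparisons, never for calibrated p-values.
* The sign-flip test assumes per-subject contrasts are sign-symmetric under
  the null; searchlight values inherit this from the symmetry of the
  generative construction, but real-data nuisance asymmetries (e.g.
  uncorrected baseline shifts) would violate it.
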