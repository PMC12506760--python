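# Methods

This note records the models, conventions and design choices behind
`wingmorph`, at the level of detail a user needs to interpret results
or reproduce them elsewhere.

## Contours and units

A contour is an ordered closed polygon of pseudo-landmarks digitized
along a wing-element boundary.  Readers apply the digitizer scale on
input, so all internal coordinates are millimetres; the y axis points
up (an `--image-coords` flag flips y for digitizations made in image
coordinates).  Validation drops consecutive duplicate points (a common
double-click artefact; logged), requires at least three distinct
points, and reverses clockwise polygons so every stored contour is
counter-clockwise.  Orientation normalization is idempotent.

## Elliptic Fourier analysis

Coefficients are the exact Fourier integrals of the piecewise-linear
arc-length parameterisation of the polygon (the classical chain-code
formulation generalised to unequal segment lengths).  No resampling is
performed: the unequal-spacing sums are exact for polygons, and
resampling would only add discretization error.

A consequence worth knowing: the arc-length parameterisation of an
ellipse is not the trigonometric one, so the first-harmonic ellipse of
a 2:1 ellipse contour has semi-axes (1.8284, 1.0730), not (2, 1), and a
pure ellipse has non-zero odd higher harmonics.  All reference values
in the test suite were computed with an independent dense-quadrature
oracle under this (correct) convention.

**Size.** The global size variable is the semi-major axis `E` of the
first harmonic ellipse, in mm.  It is exactly linear in uniform
scaling of the contour.

**Normalization.** The start-point phase θ solves
`tan 2θ = 2(a₁b₁ + c₁d₁)/(a₁² + c₁² − b₁² − d₁²)`; among the four
quarter-turn candidates the canonical one puts the major axis at phase
zero.  Harmonic n is rotated by nθ in phase, by −ψ (the ellipse
orientation) in the plane, and divided by E.  This leaves `a₁″ = 1`,
`b₁″ = c₁″ = 0` (dropped); `d₁″`, the signed width-to-length ratio, is
retained as the first shape variable, so a K-harmonic shape vector has
4K − 3 entries.

**Trace-phase (half-period) ambiguity.** Starting the trace half a
period later and rotating the shape by 180° yields a second valid
canonical form that differs by a sign flip of exactly the even
harmonics.  The branch is fixed by requiring the largest-magnitude
even-harmonic coefficient to be positive — a rule that depends only on
the shape itself, never on the input coordinates or start index.
(Branch rules based on first-harmonic signs are coordinate-dependent
and break rotation invariance; this one is exercised by a
property-based invariance suite over random star polygons.)  Shapes
with no even harmonics have coinciding branches, so the rule's
discontinuity only matters for shapes whose even harmonics hover near
zero; the synthetic generator deliberately keeps its templates away
from that boundary (below).

**Harmonic count.** The number of harmonics is chosen per dataset as
the smallest K whose cumulative harmonic power `Pₙ = (aₙ²+bₙ²+cₙ²+dₙ²)/2`
reaches a threshold (default 0.9999), maximised over specimens so all
shape vectors share one length; a fixed K can be forced.  Typical
wing-cell outlines land at K = 8–9.

## Statistics

- **Size summaries** use the sample variance (n − 1).  Group letters
  come from pairwise permutation tests on |mean difference| (default
  unadjusted at α = 0.05, Bonferroni by flag) with a greedy compact
  letter display built from the maximal cliques of the
  non-significance graph.
- **Permutation ANOVA**: classical one-way F, labels permuted
  wholesale, `p = (1 + #{F* ≥ F}) / (R + 1)` with R = 1000 by default.
  The +1 convention keeps p in (0, 1] and makes its granularity
  1/(R + 1).
- **Size classification**: leave-one-out Gaussian maximum likelihood.
  Each group's mean and variance are re-estimated without the held-out
  specimen; ties break toward smaller |z|, then the lexicographically
  smaller label; a zero-variance holdout degrades to nearest mean.
- **PCA** is an eigendecomposition of the covariance matrix (no
  per-variable standardization: coefficients share units).  Components
  are retained to 99% of variance by default.
- **Discriminant analysis** solves `B v = λ W v` with B the
  between-group covariance (denominator G − 1) and W the pooled
  within-group covariance (denominator N − G); axes are W-orthonormal,
  so canonical scores have pooled within-group variance 1.
- **Mahalanobis distances** are D (not D²) between group means under
  W, computed in the retained-PC space.  Pairwise permutation tests
  shuffle only the two groups under comparison (other groups keep
  their labels and their contribution to W); Bonferroni multiplies p
  by the number of pairs.
- **Shape classification**: leave-one-out minimal Mahalanobis
  distance.  The PCA basis is fit once on the full data and held
  fixed — refitting per holdout would change the dimensionality from
  specimen to specimen; group means and W are recomputed per holdout.
- **Adjusted accuracy** is Cohen's kappa with the chance expectation
  from group proportions, `Pe = Σ (nᵢ/N)²`.  Display percentages round
  half away from zero (e.g. 18.505 → 19), matching how classification
  tables are printed.
- **UPGMA** is the classic size-weighted average-linkage
  agglomeration; heights are half the merge distance, ties break on
  the lexicographically smallest pair of cluster labels, and Newick
  children follow the input group order.  It is implemented in-package
  (the tie-break and merge-history contracts are part of the API) and
  checked against scipy's average linkage on random matrices.

## Repeatability and allometry

Repeatability is computed per shape variable from a one-way ANOVA with
specimen as the factor across replicate digitizations:
`s²_A = (MS_among − MS_within)/n₀` (clamped at 0), `Rᵢ = s²_A/(s²_A + s²_w)`,
combined across variables by total-variance weighting — variables that
vary more carry more weight, mirroring how a single percentage is
reported per wing element.  Measurement error is `ME% = 100(1 − R)`.
Repeatability operates on the normalized coefficients rather than PC
scores so that it measures digitizing error before any basis choice.

Allometry is the trace-ratio determination coefficient of the retained
PC scores regressed on size: `r² = Σ SS_explained / Σ SS_total`,
equal to the univariate r² for a single variable.  The direction is
the sign of the correlation between size and the allometric score (the
projection of shape onto the slope vector, canonically oriented so its
largest-magnitude entry is positive — without that orientation the
sign would be identically +1).  Allometric effects are reported but
never removed from downstream analyses.

## Synthetic data

The generator emulates a four-species wing-cell study: groups of
n = (30, 41, 35, 22) specimens; sizes drawn from Normal distributions
with third-posterior-cell scale (means 0.595/0.620/0.626/0.646 mm, SDs
0.035/0.032/0.042/0.025 mm), truncated below at 0.1·mean to guarantee
positivity; group-specific shape templates; iid Normal coefficient
noise (SD 0.008) within groups; an optional allometric shift
proportional to (size − group mean); and per-replicate digitizing
noise (radial point jitter plus a random start index — the start
randomization deliberately stresses the normalization invariance).

**Ground truth lives in measured shape space.**  Polygonizing an
evaluated Fourier series re-parameterises the curve by arc length, so
a polygon's own EFA differs from the planted coefficients by a smooth
shape-dependent map whose kernel is the similarity/start-phase
directions; generic planted vectors are not exactly realisable.  The
generator therefore records, for each specimen, the measured
normalized vector of its realised contour as the true shape, and
rescales the polygon so its measured semi-major axis equals the drawn
size exactly.  Recovery tests compare pipeline output against these
measured truths; size means are recovered to 1e−6 under zero noise.

**Template geometry.** The realisation map transmits different
coefficient directions with different gains (b-coefficients as low as
0.3; d₃ ≈ 1.0) and amplifies within-group noise roughly with a
template's distance from the base shape.  Two layouts are provided,
both on well-transmitted odd-harmonic axes so the even harmonics — and
with them the trace-phase branch — stay fixed:

- `hierarchical_offsets` (the default): groups A and B 30° apart and C
  diametrically opposite on one circle of radius δ around the base
  (equal radii ⇒ comparable noise distortion), D alone at 3δ on an
  orthogonal axis.  Planted template distances are 0.52 δ, 1.98 δ and
  ≥ 3.16 δ, so UPGMA should recover ((A,B),C),D — the analogue of one
  species being most distinct.
- `equidistant_offsets`: a regular tetrahedron with a given edge, for
  experiments where every pair should separate identically (e.g.
  kappa-versus-divergence curves; edge 0.008 at divergence 10 puts all
  pairs 10 noise-SD apart).

The base template is an elongated cell (d₁ = 0.5) with one dominant
even coefficient (d₂ = −0.09, measured margin ≈ 2.6× over the next
even entry) precisely so replicate jitter cannot flip the trace-phase
branch between digitizations of the same specimen.

**Calibration.** Two channels are specified as targets rather than raw
SDs, because their observed magnitude depends nonlinearly on the
realisation map: `calibrate_jitter` bisects log(jitter) until replicate
digitizations carry a requested share of total shape variance (the
within-specimen variance grows much faster than jitter² once the
polygon becomes locally jagged, which rules out one-step scaling), and
`calibrate_allometric_slope` scales the slope by the √-law that holds
because explained variance is ∝ slope² while the residual is
slope-free, averaging several pilot datasets per iteration.  The
defaults (jitter 0.008, slope 0.32) land the measurement error near 6%
and the allometric r² near 12% — inside the 4–8% and 5–15% bands
typical of wing-element studies.

**What the generator does not emulate:** real vein geometry,
correlated (non-iid) digitizing error, outliers, reflection/left-right
asymmetry, and group-specific covariance structure beyond what the
realisation map induces.  Passing tests therefore demonstrate the
correctness and calibration of the estimators under a clean generative
model, not robustness to every artefact of real micrographs.

## Pipeline determinism and problem sizes

Every stochastic step requires an explicit seed; a run derives
per-element, per-step seeds from the run seed, and rerunning with the
same seed reproduces every CSV, Newick and JSON output byte for byte.
Defaults mirror standard practice: 1000 permutation replicates, 99% PC
retention, α = 0.05, Bonferroni on for distance tests.

The statistical-calibration suites use 500 null simulations at 199
permutation replicates (p-granularity 1/200); classifier-behaviour
curves use 10 seeds per divergence level at full study size (N = 128);
parameter-recovery checks average 20 datasets.  These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands
while keeping the default test run fast.

## Known limitations

- Reflection is not normalized: mirrored contours are distinct shapes
  by design (inputs are single-side wings digitized consistently).
- The repeatability aggregation (total-variance weighting) and the
  allometric direction convention are reasonable choices among several
  defensible ones; compare like with like across studies.
- Near-circular first harmonics make the start-phase θ ill-conditioned;
  the canonicalization falls back deterministically but shape vectors
  of near-circles have limited meaning beyond d₁″ ≈ ±1.
- The jackknife recomputes means and W but not the PCA basis; with
  very small samples the retained dimension can exceed what N − 1 − G
  supports, in which case a lower retention threshold is required (a
  clear error says so).
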