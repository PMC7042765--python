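# Methods

This note records the models implemented in `nicheshift`, the assumptions
behind them, the numerical choices that matter, and what the synthetic-data
validation does and does not demonstrate.

## Environmental space and occupancy grids

The realized niche of each range is quantified in the plane of the first two
principal components of the *pooled available environment*: background rows
of both ranges are stacked, z-scored (pooled mean and standard deviation),
and the correlation matrix eigendecomposed.  Using the pooled background —
rather than either range alone or the occurrences — makes the axes identical
for both ranges, which is what allows cell-by-cell comparison of occupancy.
Axis signs are fixed by making the largest-magnitude loading of each axis
positive, so results are reproducible across runs and platforms.

Occupancy is estimated on a shared R×R grid (default R = 100) spanning the
pooled background scores with no margin; scores falling outside (only
possible for occurrences, e.g. under permutation) are clamped to the
boundary cell rather than dropped.  Two product-Gaussian kernel densities
are evaluated at the cell centers: the occurrence density `o` and the
availability density `e`.  Each gets Silverman's per-axis rule on *its own*
sample (`h_i = σ_i · n^(−1/6)`, the 2-D Scott/Silverman exponent), times a
configurable multiplier.  Smoothing `e` with a background-derived bandwidth,
independent of the occurrences, matters twice over: it reflects that the
availability surface is a property of the landscape, not of the sample being
tested, and it is what makes the equivalency permutation statistic a pure
function of the re-split (see below).

The kernel has **compact support**: weights beyond `kernel_cutoff`
bandwidths (default 4, i.e. the kernel retains all but ~6×10⁻⁵ of its mass)
are exactly zero.  With an untruncated Gaussian every cell of the grid has
`o > 0`, so "the set of occupied cells" would always be the entire
background and the expansion/stability/unfilling decomposition would be
degenerate.  Compact support gives the occupancy surface a well-defined
envelope; `kernel_cutoff=None` restores the pure Gaussian for users who only
need the overlap indices.

The default occupancy surface is the availability-corrected
`z ∝ o/e` (zero where `e = 0`), normalized to unit mass; the uncorrected
`z_uncor = o / max(o)` is kept alongside and can be selected everywhere via
`GridParams(corrected=False)`.  The corrected surface is the right default
here because the two ranges' available climates differ — without the
correction, differences in availability masquerade as niche differences.

## Overlap and permutation tests

Schoener's `D = 1 − ½ Σ|z₁ − z₂|` and `I = 1 − ½ Σ(√z₁ − √z₂)²` are computed
on the normalized surfaces.  Both are symmetric, bounded in [0, 1], equal 1
only on identical surfaces and 0 on disjoint supports, and invariant under a
simultaneous permutation of the cells of both grids.

**Equivalency.**  Occurrence scores of both ranges are pooled and randomly
re-split into pseudo-sets of the observed sizes; occupancy grids are rebuilt
against each range's original availability surface and overlap recomputed.
The p-value is `p = (#{null ≤ observed} + 1)/(n_reps + 1)`, lower-tailed:
equivalency is rejected when the observed overlap is *lower* than random
relabelling permits.  Each pseudo-set's bandwidth is recomputed by the same
rule as the observed one, so the statistic is a deterministic function of
the split alone and the p-value is exact under exchangeability — a property
we verify by simulation (200 trials of two samples from the same niche in
the same environment give a uniform p distribution and an α-level rejection
rate).  When the two ranges are distinct landscapes, exchangeability does
not hold exactly even at zero programmed shift — the availability correction
makes the observed overlap systematically *higher* than re-split overlap —
and the test becomes conservative there (rejection below α); the test suite
checks this direction too.  One-sided 95%-quantile flags
(`outside_ci_D/I`) are emitted alongside the p-values.

**Similarity (background test).**  The target range's occupancy surface is
relocated to a center drawn uniformly from its background's occupied
environmental cells, by translating the whole surface; overlap with the
untouched source surface forms the null, upper-tailed.  Translation is
toroidal ("wrap") by default, which keeps the relocated surface's mass
intact and makes a uniform surface exactly invariant (a useful degenerate
check); `mode="clip"` drops off-grid mass and renormalizes instead.  Both
directions (native→invasive, invasive→native) are computed.

**Dynamics.**  Each range's occupied envelope is its occupancy surface
after trimming the cells that jointly hold the lowest `quantile_threshold`
fraction of occupancy mass (default 0.05; 0 keeps every `z > 0` cell).
Expansion is the invasive mass outside the native envelope over the
invasive mass in its own envelope; stability its complement (E + S = 1 by
construction); unfilling symmetrically for the native surface.  The 5%
mass trim is the field's standard guard against the kernel smearing
vanishing densities far beyond the data: without it the envelopes of any
two kernel-smoothed samples on a shared background overlap almost
entirely and E, U collapse toward 0 regardless of how far apart the niches
are.  `analogue_only=True` restricts the whole computation to cells
available (e > 0) in both ranges, the appropriate option when the two
ranges' climates barely overlap.

## Maximum-entropy SDM

The model is the Gibbs distribution over the training background,
`p_λ(x) = exp(λ·f(x))/Z`, fitted by minimizing the L1-penalized negative
mean log raw probability of the presences — a convex problem solved by
monotone FISTA (accelerated proximal gradient with backtracking and
restart), deterministic, iteration cap 10,000.  Convergence is declared at
KKT residual ≤ tol (default 10⁻⁷ for single fits; the tuning grid uses
10⁻⁵, plenty for AICc/AUC comparisons and ~5× faster); a fit that reaches
the cap raises an error carrying the residual rather than returning
silently.

Features are built from predictors rescaled to [0, 1] over the training
sample (with clamping on projection, i.e. "clamped" extrapolation):
linear, quadratic, pairwise products, forward+reverse hinges and step
functions at 20 evenly spaced interior knots per variable.  Fixed knots
trade a little flexibility for a deterministic, bounded feature count.
Penalties are `β_j = RM · b_class / √n_presence` with class constants
`b = {L:1, Q:1, P:1, H:0.5, T:1}` — the Maxent-style shape (hinges cheaper,
everything shrinking as presences accumulate) without reproducing the Java
program's sample-size interpolation tables.  The entropy `H` of the fitted
distribution over the training background converts raw output to the
complementary log-log scale, `cloglog = 1 − exp(−e^H · raw)`; for the
uniform model this is `1 − e⁻¹ ≈ 0.632` everywhere.

Model selection fits the 6 feature-class combinations
{L, H, LQ, LQH, LQHP, LQHPT} × 8 regularization multipliers 0.5–4.0 — 48
candidates — on the full data, computes `AICc = 2k − 2 logL +
2k(k+1)/(n−k−1)` with `k` the count of coefficients `|λ| > 10⁻⁸` and the
log-likelihood of presences under raw probabilities normalized over the
training background, flags candidates with `n ≤ k+1` invalid, and selects
the lowest-AICc candidate within ΔAICc < 2 (ties: fewer coefficients, then
lower RM).  Four-quadrant spatial blocks (median presence latitude, then
per-half median longitude, background assigned by the same three
boundaries) give a transfer-aware test AUC as a secondary diagnostic.

## Evaluation

AUC is the rank probability that a presence outscores a background point
(ties ½).  The continuous Boyce index slides 101 overlapping windows of
width 10% of the pooled score range and takes the Spearman correlation of
window midpoint with the presence-to-background frequency ratio, skipping
windows without background; fewer than three valid windows raises
"undefined index".  Note the windowed CBI is invariant under affine but not
general monotone transforms of the scores (the windows re-partition the
gradient); AUC and TSS are fully rank-invariant.  TSS maximizes
sensitivity + specificity − 1 over thresholds at midpoints of consecutive
distinct scores (plus sentinels), treating background as pseudo-absence.
The reciprocal report evaluates TSS both ways: threshold re-optimized on
the evaluation range (non-negative by construction) and threshold
*transferred* from the model's own training range — the transferability
variant, which goes negative on a failed transfer and is the one to read
when judging cross-range performance.

## Synthetic scenarios

Each range's climate layers are sums of ~60 random low-frequency cosine
modes (wavelengths ≥ the configured autocorrelation length, default 25
cells), empirically whitened over the grid and mixed by the Cholesky factor
of the target correlation matrix, then scaled to per-layer means and
standard deviations that loosely mimic four temperate bioclimatic
predictors (annual and coldest-month temperature, annual and coldest-month
precipitation).  The whitening step makes the realized pairwise
correlations match the target essentially exactly, not just in expectation.
The accessible area is the full extent minus a border frame.

The species occupies a Gaussian niche in the 4-D climate space (diagonal
covariance, breadth defaulting to half of each layer's spatial standard
deviation); cells are sampled with probability proportional to suitability
and points jittered within the cell.  The two ranges' niche centroids are
placed symmetrically about the climate mean and separated by `shift_sigma`
Mahalanobis units, so the programmed shift is known exactly and the
Bhattacharyya coefficient `exp(−δ²/8)` of the two occupied Gaussians is
recorded as ground truth.  Default sample sizes mirror the motivating
study: 79 native and 6,579 invasive presences, 10,000 background points
(capped at the number of accessible cells when the landscape is smaller).

What the generator does *not* emulate: spatially autocorrelated sampling
bias, coordinate error, dispersal limitation or biotic exclusion (the
realized niche equals the suitability-weighted available climate), climate
distributions that differ *between* ranges (only the occupied centroid
shifts, not the available envelope — real invasions often involve both),
and temporal dynamics.  Passing the validation therefore shows the
*method* recovers a known environmental-space shift from sampled points;
it does not certify behaviour under survey bias or non-analogue
availability, which on real data remain the user's responsibility to
assess (the `analogue_only` option exists for the latter).

## Validation problem sizes

The test suite exercises the pipeline at deliberately small scales chosen
to keep the full run in a few minutes of one CPU: 60×60-cell landscapes
with 50/200 presences and 1,000 background points for the statistical
checks; 200 calibration trials at 99 permutation repetitions for the
type-I-error check; 20 replicates per shift in {0, 0.5, 1, 2, 4}σ for the
parameter-recovery check; 80–100-cell landscapes for the tuning-grid and
reciprocal-modelling checks.  `scripts/acceptance.py` runs the analysis
once at the study-scale conditions (79/6,579 presences, 100×100 cells, 999
permutations, two full 48-candidate tuning grids) in about a minute.

## Known limitations

- Only two PCA axes are supported; niches separated purely in higher
  components are invisible to the analysis (a property of the framework,
  not of this implementation).
- The hinge/threshold knot grid is fixed rather than data-driven, so very
  sharp responses may need more knots (`knots=` parameter).
- AICc for presence–background models is a convention, not a likelihood
  theory result; it is used here (as in practice) for ranking, not
  inference.
- The similarity test relocates the whole occupancy surface; resampling
  occurrence-sized sets from the background is a published alternative that
  answers a slightly different question and is not implemented.
- GeoTIFF I/O is not provided; rasters are exchanged as ESRI ASCII grids.
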