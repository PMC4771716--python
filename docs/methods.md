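# Methods

This note records the statistical model behind `memscale`, the defaults
and why they were chosen, and the places where a design decision was
genuinely open.

## Spatial template: Gabriel graph and MEMs

Sites are connected by the Gabriel rule: edge (i, j) exists iff no third
site lies **strictly inside** the open disk whose diameter is segment ij.
Cocircular third points do *not* block an edge (a relative tolerance of
1e−12 on the squared radius guards the comparison); this avoids dropping
edges on symmetric configurations such as regular grids. Candidate edges
are taken from the Delaunay triangulation — the Gabriel graph is always a
subgraph of it — with a brute-force all-pairs fallback for degenerate
(e.g. collinear) inputs that qhull rejects. Distances are Euclidean on
the supplied planar coordinates; the input contract requires projected
units, so no geodesic handling is attempted. Duplicate coordinates are an
error, never silently jittered: jitter would make runs irreproducible.

The Moran's Eigenvector Maps are the eigenvectors of Ω = HWH
(H = I − 11′/n, W the binary Gabriel adjacency — not row-standardized,
as the plain MEM framework specifies). For a connected graph the basis
has exactly n − 1 vectors: all eigenvectors orthogonal to the constant.
On symmetric configurations Ω can carry structurally zero eigenvalues
*inside* the centered subspace (the 3-site path is the smallest case:
W(1, 0, −1)′ = 0); these vectors are retained with eigenvalue 0 so the
basis always spans the centered space — a property the scalogram's
sum-to-one identity depends on. Numerically-null eigenpairs are detected
at |λ| ≤ 1e−9·max|λ|, and the null space is split into its constant and
centered parts by centering and re-orthonormalizing. Determinism is
enforced by fixing each eigenvector's sign (largest-magnitude entry
positive) and breaking exact eigenvalue ties lexicographically.

Each eigenvector's scale is summarized by Moran's I, which for a unit-norm
centered vector reduces to the closed form I(v_k) = n·λ_k/ΣW. The
broad-medium / fine split is by the sign of I; vectors with |I| below
1e−12 go to the fine set with a warning (they carry no autocorrelation
signal either way).

## Transformations and ordinations

Hellinger (y′ = √(y/row total)) emphasizes the abundant species;
chi-square (y′ = √(grand total)·y/(row total·√(column total))) up-weights
the rare ones. Sites or species with zero totals are rejected by name —
both transforms are undefined there, and silently dropping rows would
desynchronize the spatial template.

PCA is the column-centered SVD, eigenvalues λ = s²/(n − 1). RDA fits the
multivariate least squares Ŷ = Q(Q′Y_c) through an orthonormal basis Q of
the centered, standardized design, and ordinates Ŷ; R² = SS(Ŷ)/SS(Y_c).
PRA ordinates the residuals Y_c − Ŷ. Explanatory columns are standardized
before fitting — the design mixes °C, km and proportions, and although
R² is invariant to column scaling, conditioning is not. Rank-deficient
designs are rejected with the offending columns named (pivoted QR).

Site scores are reported in scaling 1 (distance-preserving, scores = US);
axis signs are fixed so the largest-magnitude species loading is
positive. For RDA the default site scores are the fitted ("LC") scores —
they *are* the constrained pattern, which is what the scalogram should
decompose — with weighted-average scores also computed for users who
prefer them. Variance proportions are reported against the total inertia
of the input table (so RDA proportions sum to R²), with
`proportion_constrained` summing to 1 within the constrained share.

Adjusted R² uses Ezekiel's formula R²ₐ = 1 − (1 − R²)(n − 1)/(n − m − 1);
negative values are legitimate and reported as computed.

## Scalograms and the R²max test

For a centered score vector s, R²_k = (v_k′s)²/(s′s); because the MEMs
are an orthonormal basis of the centered space these shares sum to one.
Smoothing partitions the eigenvalue-ordered sequence into consecutive
blocks whose values are **summed** (block sums preserve the unit total;
for equal blocks the argmax is the same as for means). With 328 MEMs and
8 components every block holds 41 successive MEMs; when n − 1 is not
divisible by the component count the earlier (broader) blocks take the
extra vectors. Block 1 is therefore "very broad" (most positive Moran's
I) through block G "very fine".

The null hypothesis — no spatial pattern — is simulated by permuting the
raw score values across sites; each permutation's smoothed maximum is
compared with the observed R²max and p = (1 + #{max_perm ≥ max_obs})/
(nperm + 1). Permuting raw scores (rather than residuals of some model)
matches the null actually stated: the scores carry no spatial
arrangement at all. The per-component 95% null quantile is recorded as
the confidence limit usually drawn on scalogram figures. The test is
exact by exchangeability, which the calibration suite confirms (rejection
rate at α = 0.05 inside the binomial CI over 200 unstructured replicates).

## Forward selection

The two-stop criterion is implemented as: (gate) nothing is selected
unless the global model on all candidates passes a row-permutation test
at α — without this gate the procedure is strongly anticonservative,
because testing the best of m candidates is a minimum-p statistic (with
40 null candidates an ungated selection admits a variable in roughly 85%
of runs); (stop 1) the best candidate is admitted only if its marginal
pseudo-F, conditional on the already-selected set, has permutation
p ≤ α; (stop 2) selection halts once the selected subset's cumulative
adjusted R² exceeds the global model's adjusted R². Stop 2 is evaluated
on the *selected subset* at the top of each step, not as a veto on the
candidate under test: the veto form spuriously blocks the first variable
whenever the remaining candidates are noise, since a single strong
predictor's adjusted R² essentially equals the global model's.

The marginal test permutes rows of the reduced-model residuals
(Freedman–Lane), the accepted scheme for partial canonical tests. Ties in
marginal R² are broken toward the lower variable index. When the
candidate set saturates the centered space (all n − 1 MEMs: R² ≡ 1), the
global gate and stop 2 are vacuous and only the α criterion binds.

## Variation partitioning

Two or three variable sets are partitioned by inclusion–exclusion on the
adjusted R² of every union; all fractions plus the residual sum to 1 by
construction, and negative adjusted fractions are reported as computed —
clipping would break the identity. Unique fractions (the only individually
testable ones) are tested by the same reduced-model residual permutation,
conditioning on the union of the other sets. Union projections use an
SVD column-space basis, so overlap *between* sets (one set inside
another's span) degrades gracefully to a zero semipartial instead of
erroring; each set must still be internally full rank.

## Synthetic generator

The generator emulates the study design the pipeline targets, at desk
scale, with one master seed spawning independent streams per stage:

- **Layout**: 329 sites uniform over 300 × 350 km (both configurable).
  Gabriel graphs on such layouts are connected (they contain the
  Euclidean minimum spanning tree); the pipeline still asserts it.
- **Temperature**: 50 synthetic stations carry a linear west→east
  gradient per month (June: 20.5 → 25.5 °C; May/July/August analogous)
  plus 0.3 °C station noise, interpolated to sites by IDW with power 2.
  Fewer stations than the ~430 real ones a regional network would offer,
  but enough for a smooth interpolated field.
- **Land use**: one smooth latent field per class (deciduous, evergreen
  and other forest, developed-open, corn/soy) shared across the 7 buffer
  scales, plus scale-specific noise that shrinks with buffer radius
  (σ 0.6 at 100 m down to 0.15 at 10 km), pushed through a softmax with
  an implicit "other" class — proportions stay in [0, 1] and named
  classes sum to ≤ 1 per scale. The cross-scale correlation structure of
  real buffer compositions is unknown; the shared-latent construction is
  an explicit assumption, not an estimate.
- **Counts**: negative binomial (size 1.5 — sweep-net counts are
  overdispersed; Poisson is recoverable by raising the size) with
  log-linear means in natural units. The invasive species declines with
  June temperature (−0.7/°C) and distance from the source corner
  (−0.004/km), rises with developed-open and deciduous cover at 250 m,
  and its mean is multiplied by zero above the 23.5 °C June cutoff — a
  hard threshold mirroring the empirical statement it models, with a
  logistic alternative available in the config. Natives rise with July
  temperature and forest cover. The joint per-site count vector is
  zero-truncated (redrawn until positive): the transforms are undefined
  on empty sites and the emulated survey has none.

What passing tests on these data do **not** show: robustness to
irregular site layouts (clustered sampling), to land-use fields with
scale-dependent correlation different from the shared-latent assumption,
to detection error in counts, or to temperature fields with non-linear
structure. The generator is a statistical emulation, not a re-creation
of any real dataset.

## Problem sizes and numerical choices

Permutation defaults are 999 everywhere (CLI and pipeline), with tests
using 99–199 to keep the suite fast; p-values are always
(1 + hits)/(nperm + 1) with a 1e−12 slack on the ≥ comparison so exact
ties count as hits. The calibration suite uses 200 replicates of a
100-site graph; the recovery suite uses 50 full-size (329-site) surveys.
Scalogram permutations are vectorized (one matrix multiply per test), so
a full-size pipeline run with nperm = 999 takes a few seconds. Degenerate
inputs — constant scores, uncentered scores, disconnected graphs, empty
candidate sets, saturated designs — raise informative errors rather than
producing silent nonsense.

## Known limitations

- Only binary Gabriel adjacency is supported; no distance-decay weights,
  k-nearest-neighbor or distance-band alternatives, and no AIC-based
  selection among candidate spatial weighting matrices.
- Variation partitioning stops at three sets.
- The scalogram smoothing is the non-overlapping block-sum reading of
  "G components of consecutive MEMs"; overlapping-window variants exist
  and would give smoother profiles.
- Forward selection of MEMs from the saturated candidate set relies on
  the α stop alone; like any stepwise procedure it remains optimistic
  about marginal significance of later additions.
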