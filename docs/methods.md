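# Methods

## Scope and data model

The package analyzes two-dimensional point patterns of bacterial cell
centroids extracted from calibrated micrographs of surface-attached
communities.  A micrograph is an 8-bit grayscale or RGB array with a
µm/pixel calibration; all downstream quantities are in µm, µm², µm⁻¹ or
cells/mm².  Coordinates use pixel centers at (col + 0.5, row + 0.5) and a
Cartesian frame with the origin at the image's lower-left corner
(y = (H_px − row_center) × calibration), so object tables read naturally as
maps of the field of view.

Segmentation is deliberately simple: a global intensity threshold (fixed or
Otsu) for grayscale images, and a channel-dominance rule for RGB reporter
images (a pixel is "red" when R − max(G, B) ≥ margin; default margin 30 of
255, suitable for dark-background fluorescence).  Connected components use
8-connectivity by default (bacterial cells are compact); components smaller
than `min_pixels` (default 5) are discarded as debris.  The per-object
record is: centroid (arithmetic mean of member pixel centers), area
(pixel_count × calibration², exact by construction), channel tag and mean
8-bit luminosity.  Analyses of projected 2-D images cannot resolve
out-of-plane structure; cells that overlap in projection merge into one
object, which bounds the resolvable minimum separation at roughly one cell
diameter.

## Nearest-neighbor battery

Per-cell 1st/2nd nearest-neighbor distances (NND₁, NND₂) are exact
Euclidean distances (k-d tree; an optional toroidal mode measures distances
periodically for edge-free simulation work).  Stored distances are raw — no
edge correction is applied to the per-cell table.  Coincident centroids
would make the cluster index CI = 1/NND₁ infinite; NND₁ is clamped at half
the pixel calibration (one half-pixel, the localization limit) with a
warning.

The CSR battery interprets each index against the homogeneous Poisson
null (intensity λ = n/A):

- **Clark & Evans** R = mean(NND₁)/(0.5/√λ).  The default significance test
  uses the Donnelly edge-corrected expectation and SE; toroidal distances
  are used in simulation batteries where the generator lives on a torus
  anyway.  Raw R in small windows is biased high, which is why an edge
  treatment is the default.
- **Holgate** A = mean(d₁²/d₂²).  The default follows the classical
  formulation: d₁, d₂ are measured from m random sampling locations
  (default m = n) to the nearest and second-nearest cell.  Under CSR,
  πλd₁² and πλ(d₂² − d₁²) are independent unit exponentials, so the ratio
  is exactly U(0, 1) and E[A] = 0.5; in aggregated patterns sampling
  locations fall in gaps and both distances point at the same cluster,
  driving the ratio toward 1.  An event-based variant (each cell's own
  NND₁²/NND₂²) is available as `method="event"`; note that this ratio is
  locally scale-free, so it stays near 0.5 for cluster processes whose
  clusters are internally Poisson-like and is useful mainly as a
  descriptive index.  The normal score z = (A − 0.5)√(12m) is reported, but
  the default p-value is a 99-replicate Monte-Carlo rank test: the normal
  approximation is anti-conservative (measured type-I ≈ 0.07 at n = 200)
  because nearby sampling locations share neighbors.
- **Hopkins & Skellam** h = Σxᵢ²/Σrᵢ², with xᵢ the distances from m random
  sampling locations to the nearest cell and rᵢ the NND₁ of m randomly
  chosen cells; h ~ F(2m, 2m) under CSR.  The F reference assumes the 2m
  distances are independent, which fails when m is a large fraction of n;
  the default m = clip(⌊n/10⌋, 10, 100) follows the sparse-sampling rule
  under which the measured type-I error is ≈ 0.05 (m = n/2 gives ≈ 0.09).
  m can be set explicitly when a fixed sampling effort is required.
- **Russ randomness** is reported as the mean over k ∈ {1, 2} of
  mean(NNDₖ)/E_CSR[NNDₖ] with E_CSR[NND₁] = 0.5/√λ and
  E_CSR[NND₂] = 0.75/√λ.  No published closed form exists for this index's
  null distribution, so significance is a two-sided Monte-Carlo rank test
  against 99 CSR simulations of the same n and window.
- **EDF**: empirical G(r) of NND₁ against G₀(r) = 1 − exp(−λπr²).  The
  envelope is simultaneous — G₀ ± d*, where d* is the 95th percentile of
  the maximum absolute deviation over 99 CSR simulations — so a CSR pattern
  falls entirely inside it with probability ≈ 0.95, and the p-value is the
  Monte-Carlo rank of the observed maximum deviation.
- **Fractal dimension**: box counting over a power-of-2 ladder from 2 px to
  a quarter of the shorter image side, least-squares slope of log N(ε)
  against log(1/ε).  A filled frame measures ≈ 2, a 1-px line ≈ 1; values
  above 1 for a cell mask indicate scale-dependent aggregated structure.
  The specific multi-scale intersection variant used by older ecology
  packages is not publicly specified; standard box counting carries the
  same >1 interpretation.

Verdicts ("aggregated" / "random" / "uniform") combine the printed decision
rule for each index (>0.5, <1.0, <1.0, >1.0 aggregated for Holgate, Russ,
Clark & Evans, Hopkins & Skellam) with two-sided significance at α = 0.05.

## Distributional inference

NND and cluster-index samples from biofilms are typically right-skewed, so
the comparison battery is Shapiro–Wilk normality (scipy backend),
a moment skewness test (g₁ = m₃/m₂^1.5, SE = √(6n(n−1)/((n−2)(n+1)(n+3)))),
medians, and Mann–Whitney U (midrank ties, tie-corrected normal
approximation; the smaller U is reported together with which sample's
median is larger).  All tests are two-sided at α = 0.05; no multiple-testing
correction is applied across features.

## Geostatistics

The Z-variate (default: cluster index) is analyzed isotropically.  The
empirical semivariogram uses equal-width lag bins up to `active_lag_max`
(default: half the diagonal of the sample's bounding box, a common
geostatistics default); bins without pairs are excluded.  Model fitting is
weighted least squares with pair counts as weights over the requested
families (spherical, exponential, gaussian, linear), best family by
weighted residual sum of squares.  The range parameter is capped at
`active_lag_max` during fitting — ranges beyond the sampled lags are not
identifiable and uncapped fits occasionally run away on noisy variograms.
Effective ranges at 95% of the asymptote: a·ln 20 ≈ 3a (exponential),
a√(ln 20) (gaussian), 0.8109a (spherical, the numeric root of
1.5x − 0.5x³ = 0.95); the linear model has no asymptote and reports
0.95 × active_lag_max.  A fit is flagged `no_structure` (effective range 0)
when the partial sill is below 1% of the total sill or when the model
explains less than 30% of the pair-count-weighted binned variance
(weighted R² < 0.3): on iid fields the weighted R² measured ≤ 0.28 over
replicates while genuinely structured fields measured ≥ 0.92, so 0.3
separates the regimes with margin.

Moran's I uses inverse-distance weights by default (optionally cut off at
the fitted effective range, or binary within a bandwidth), with
E[I] = −1/(n − 1) and the randomization variance for the z-score.  Reported
index values from legacy geostatistics packages sometimes exceed +1 and are
not comparable to the raw index; both the raw I and its z-score are always
emitted, and the z-score is the recommended intensity measure when
comparing samples.

Ordinary kriging solves the standard system (γ(0) = 0 on the diagonal,
Lagrange multiplier enforcing weights summing to 1) on the k = 16 nearest
data per node over a regular grid (default spacing: window/100).  With zero
nugget the predictor is exact at data locations with zero kriging variance;
far beyond the effective range the prediction tends to the neighborhood
mean and the variance to the sill.  Exact duplicate locations are jittered
by 0.05 µm with a warning to keep the system nonsingular.  Isopleths are
marching-squares contours at the quintiles of the predicted surface by
default.  Leave-one-out cross-validation reports the mean standardized
squared error (≈ 1 when kriging variances are calibrated).

## Communication analysis

Calling distances default to centroid-to-centroid nearest-source matching
("single pixel resolution"); a boundary mode (minimum pixel-to-pixel
distance via the Euclidean distance transform) is provided because the
shortest distance between extended cells is ambiguous — boundary distances
are never larger than centroid distances.  A user-supplied binary ROI mask
excludes manually flagged objects (e.g. cells on root hairs or off the
optical section) before matching.  Calling-distance histograms use 1 µm
bins (mode bin and maximum are reported); expression histograms bin mean
luminosity in 16-level bins over [0, 256) and report occupied bins plus
local maxima after 3-bin smoothing as modality flags.

## Synthetic scenes

The generators define the study conditions for every statistical check:

- `gen_poisson` — conditional (fixed-n) CSR by default so simulation
  batteries have constant sample size; unconditional via `intensity`.
- `gen_thomas` — Poisson parents (drawn from the window dilated by 3σ so
  edge clusters are not under-represented), Poisson(µ) offspring per parent
  with isotropic Gaussian sd σ; expected count ≈ κ·A·µ.  An optional
  `min_separation` applies sequential hard-core thinning, emulating
  physical exclusion between cell bodies; without it, offspring may fall
  arbitrarily close together and the cluster index becomes unboundedly
  heavy-tailed — a regime projected micrograph data cannot produce, since
  touching cells merge during segmentation.
- `gen_hardcore` — sequential inhibition (dart throwing) with a feasibility
  guard; the uniform/over-dispersed reference.
- `render_cells` — anti-aliasing-free filled disks (disk cells only:
  cocci/short rods at high magnification are near-circular).  Rendered
  cells clipped by the field edge shift the recovered centroid, so scene
  generators accept an `inset` keeping cells fully inside the field.
- `gen_communication_scene` — red source disks and green sensor disks
  placed with a hard-core separation of 2·radius + 2 px (so segmentation
  recovers every cell); sensor luminosity L(d) = round(L_max·e^(−d/d₀)) for
  d ≤ d_thresh, baseline (default 2, basal expression) beyond it.  Defaults
  (40 sources and 80 sensors in 200×200 µm, L_max = 255, d₀ = 20 µm,
  d_thresh = 60 µm, 1 µm cells at 0.2 µm/px) give mostly-active sensors
  with luminosities spanning most of the 8-bit range.  Every generator is
  seed-deterministic and logs its parameters.

What the generators do *not* emulate: optics (point-spread function, noise,
uneven illumination), rod-shaped or dividing cells, 3-D structure, and
root-surface texture.  Passing tests therefore demonstrate correctness of
the statistics and of the pipeline plumbing under known geometry, not
robustness to acquisition artifacts — thresholds and margins must be tuned
for real micrographs.

## Simulation sizes and numerical choices

The shipped checks use problem sizes chosen to keep every statistic's
sampling error well inside its tolerance: CSR calibration and type-I runs
use n = 200 points in 100×100 µm (200 and 500 replicates); aggregation
detection uses Thomas patterns with κ = 10 parents/mm², µ = 20, σ = 2 µm in
1 mm²; effective-range recovery uses 600-point exponential-covariance
Gaussian fields (range 10 µm, i.e. effective range 30 µm) in 200×200 µm
with 20 lags to 50 µm, summarized by the median over 20 replicates (the
single-replicate estimator has a heavy right tail); the rendered fractal
scene uses 10 expected parent clusters in a 1000×1000 px field at
0.2 µm/px.  Monte-Carlo significance uses 99 simulations and rank p-values
throughout (two-sided, (1 + #{≥})/(n_sim + 1)).

Known limitations: all tests are two-dimensional and isotropic; the Russ
index is a constructed variant (documented above) satisfying the
conventional decision rule rather than a published formula; kriging with a
nonzero fitted nugget is not exact at data points (standard behavior); and
the CSR battery's asymptotic p-values are only trustworthy at the default
sampling fractions — prefer the Monte-Carlo options near n < 50.
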