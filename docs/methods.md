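# Methods

## Model

`vsp` treats a variant screen as a spatial dataset.  A variant at residue
position *p* of a protein of length *L*, with functional measurements
(*y*, *z*), becomes an observation at coordinates (*x* = *p*/*L*, *y*)
carrying response *z*.  The response is modelled as a realisation of a
second-order stationary random field over that plane: its covariance
between two locations depends only on their Euclidean separation
*h* = √(Δx² + Δy²).  Everything downstream — variogram, kriging weights,
prediction variance — follows from that single assumption.

The biological reading: *x* orders variants along the polypeptide as
transcription/translation would, *y* places them on a functional axis, and
spatial correlation in the plane expresses the observation that variants
close in sequence *and* close in one functional readout tend to share
their effect on a second readout.  The method makes no mechanistic claim;
it interpolates whatever covariance structure the screen exhibits.

## Variogram estimation

For all n(n−1)/2 unordered pairs we compute *h* and the semivariance
γ = ½(zᵢ − zⱼ)².  Pairs are averaged in uniform lag bins; by default 12
bins up to an active lag of half the maximum pair distance (beyond that,
pair counts thin out and the empirical variogram is noise).  Both knobs
are configurable (`n_bins`, `active_lag`).

Four model families are supported, with γ(0) = 0 by convention and the
nugget *c₀* applying to any h > 0:

- spherical: c₀ + c·(1.5 h/a − 0.5 (h/a)³) for h ≤ a, else c₀ + c
- linear (with sill): c₀ + c·h/a for h ≤ a, else c₀ + c
- exponential: c₀ + c·(1 − e^(−3h/a))
- gaussian: c₀ + c·(1 − e^(−3h²/a²))

Exponential and gaussian use the practical-range convention (γ reaches
~95% of the sill at h = a), matching the major geostatistics packages, so
fitted ranges are comparable across families.  The spherical family is the
default; `vsp.validation.family_comparison` ranks all four by
leave-one-out error on the dataset at hand, and on fields simulated from a
spherical model the spherical family wins (checked in the test suite).

**Fitting.**  The fit minimises the unweighted residual sum of squares over
populated bins.  For a fixed range the nugget and partial sill enter
linearly, so they are profiled out by non-negative least squares; the
remaining one-dimensional problem in the range is solved by a fixed
400-point grid over [0.01·h_max, 3·h_max] followed by bounded scalar
minimisation bracketed by the best grid point's neighbours.  The procedure
has no random element and reproduces bit-for-bit.  Noiseless inputs are
recovered to ~1e−8 relative error.  A constant empirical variogram (e.g. a
constant response) yields a pure-nugget model with a warning.

## Kriging

Ordinary kriging, covariance form: C(h) = (c₀ + c) − γ(h) with
C(0) = c₀ + c.  The (k+1)×(k+1) augmented system is solved by dense LU
with partial pivoting (`scipy.linalg.solve`); neighbourhoods are small
(k ≤ 25) so cost is irrelevant.  Properties the tests pin down: weights
sum to 1 within 1e−10; predictions interpolate the data exactly when the
nugget is zero (σ² = 0 at observations); translation and scale
equivariance; agreement to 1e−8 with an independently coded dense solve in
semivariogram form.

Neighbourhood policy: the `max_n` (default 20) nearest observations within
a search radius that defaults to the variogram range; if fewer than
`min_n` (default 5) fall inside, the `min_n` nearest are used regardless
of the radius.  The floor-overrides-radius rule keeps predictions defined
everywhere on the grid, at the cost of extrapolating with weakly
correlated neighbours far from data — which the kriging variance then
reports honestly (σ² ≥ sill out there).

Numerical choices: exactly coincident observations would make the
covariance matrix singular, so within matrix assembly only, the second
point's x is nudged by 1e−9 (reported coordinates never change; the load
step warns about such duplicates).  A kriging variance that comes out
negative by less than 1e−12 + 1e−9·sill is clamped to zero as float
round-off — the relative term matters because round-off scales with the
covariance magnitude; anything more negative raises an error, since it
means the model and system disagree.  A degenerate zero-sill model (fitted
to a constant field) short-circuits to the neighbourhood mean with zero
variance instead of solving a singular system.

## Landscapes and confidence

The landscape evaluates the predictor on a regular grid — default 100×100,
x over [0, 1], y over the observed functional range padded 5% per side.
Confidence regions are empirical quantiles of the gridded kriging
variance: the "top 25%" region is the quarter of cells with the smallest
σ², ties included, so masks nest by construction.  Quantiles (rather than
fixed σ² levels) are used because they are reproducible across datasets
whose absolute variance scales differ.

Delta landscapes (treated minus control) subtract predictions cell-wise
and add variances, treating the two runs' errors as independent — a
convention, since the two conditions share coordinates; it overstates
delta uncertainty when errors correlate, which is the conservative
direction.

Kriging is an exact interpolator but not shape-preserving: weights may be
negative, so landscape values can overshoot the observed z range,
especially outside the data's convex hull.  Accuracy claims in the tests
are therefore made for the interpolation regime (grid cells inside the
sampled region): on a plane z = 2x + y sampled at 250 points the interior
of the landscape is reproduced to < 0.05 absolute at 50×50 resolution,
while edge cells extrapolate and are not held to that bound.

## Cross-validation and weighted correlation

Leave-one-out keeps the variogram fitted once on the full dataset and
re-predicts each held-out point from the remainder with that fixed model —
the spatial structure is treated as a property of the whole screen, not of
each training fold.  A `refit_per_fold` flag provides the stricter
variant.  k-fold partitions are seeded, near-equal (sizes differ by at
most one), every observation validates exactly once per repeat, and for
k < n the partition is repeated (default 5×) with mean r and p reported;
k = n reproduces leave-one-out exactly.

The observed–predicted correlation is Pearson's r with inverse-variance
weights ωᵢ = 1/σᵢ², normalised to sum to one.  r is invariant to the
weights' overall scale; the p-value is not, hence the fixed normalisation.
Significance is the F-test of the weighted-least-squares slope (predicted
on observed) with 1 and n−2 degrees of freedom, computed by direct
summation and cross-checked against statsmodels WLS in the tests.  Zero
variances are replaced by the smallest positive variance present (all-zero
variances fall back to equal weights); a constant observed or predicted
vector flags the correlation as undefined rather than emitting NaN.

## Synthetic data

`simulate_field` draws z = mean + L·ε with L the Cholesky factor of the
model covariance matrix (diagonal jitter 1e−10 scaled by the sill, so a
zero-variance spec yields an exactly flat field) — the exact generative
model the estimator assumes, making simulated fields valid ground truth
for recovery tests.  Dense factorisation is used throughout; at the
hundreds-of-points scale this package targets, spectral or turning-bands
simulation would add complexity for no benefit.

`make_variant_fixture` emulates the shape of a two-condition variant
screen: 48 variants at distinct residues of a 1278-residue protein, a
response in [0, 1] drawn from a spherical field with range 0.19 and sill
0.05 around mean 0.35 over the (sequence, cholesterol-score) plane —
parameters chosen to match the scale of a real trafficking screen — and a
cholesterol coordinate (mean 1.0, s.d. 0.3, as for a score normalised to a
reference variant).  A negative response–coordinate correlation (target
−0.36) is induced by a linear trend of z on y whose slope follows from the
target correlation.  The treated condition multiplies range and sill by
`condition_effect` (default 0.6) while re-using the control innovations,
so an effect of 1 reproduces the control exactly and smaller effects model
a treatment that compresses both the correlation length and the variance.

What the generator does *not* emulate: measurement error structure
(replicate s.e.m.s), class imbalance across protein domains, non-Gaussian
response distributions, and the mild variogram inflation its own trend and
[0, 1] clipping introduce (clipping affects ~5% of draws at the default
mean; the end-to-end recovery tests use bands wide enough to absorb both).
Passing tests therefore demonstrate correctness of the machinery under its
own assumptions, not that any particular real screen satisfies them.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes — fields of
100–400 points, 20–50 replicates, grids of 30–50 cells per axis — which
keep every stochastic band stable while completing in seconds.  All
randomness flows through explicit `numpy.random.default_rng` seeds; CLI
outputs embed the package version and a configuration fingerprint, and
identical config + seed yields byte-identical files.

## Known limitations

- Isotropy in (x, y) is assumed; no directional variograms.
- Ordinary kriging only — no trend models, co-kriging or universal
  kriging; the two functional axes are handled by running the pipeline
  twice with axes swapped rather than jointly.
- The residue annotation step picks the single best-confidence cell per
  column; at grid resolutions below ~protein_length/10 several residues
  share a column (the CLI warns).
- The trafficking-class boundaries (0.2, 0.5) are reported in the
  literature as approximate; this package fixes [0, 0.2) / [0.2, 0.5] /
  (0.5, 1] and documents the choice rather than guessing intent.
- The Chol "normalised to reference" convention is implemented as division
  by the reference variant's raw value (reference ↦ 1.0); a min–max
  alternative is available via configuration and recorded in the output
  metadata, since published descriptions of such normalisations are often
  ambiguous.
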