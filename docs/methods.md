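# Methods

This note documents the models and procedures implemented by `isomatch`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Grid conventions

All geographic rasters share a regular lon/lat (WGS84) grid. Row 0 is the
northernmost row; cell (r, c) covers the half-open box
[lon_min + c·res, lon_min + (c+1)·res) × (lat_max − (r+1)·res, lat_max − r·res],
and all values are interpreted at cell centers. The default resolution is
0.33°, the standard assignment resolution for continental-scale multi-isotope
work. Cell areas use the small-cell approximation
(res · 111.320 km)² · cos(latitude), adequate for the tropical and
subtropical latitudes these analyses cover; over a mixed-latitude mask, total
area from this formula agrees with mean-area × cell-count to well under 1 %.

Rasters are stored as single-band ESRI ASCII grids (a plain-text, widely
readable format) with a JSON sidecar carrying the isotope label, reference
scale, CRS and an optional constant or per-cell SD. Only geographic lon/lat
rasters are accepted; projected inputs are rejected with an explicit error
rather than silently misinterpreted. Regridding samples cell centers via
`scipy`'s regular-grid interpolator; bilinear resampling never extrapolates
beyond the source cell-center hull, and any target cell supported by an
invalid source cell becomes invalid.

## Feather-equivalent isoscapes

Assignment compares feather measurements with *feather-equivalent* isoscapes
derived from source isoscapes:

* **Hydrogen.** A linear transfer function δ²H_f = a·δ²H_p + b rescales the
  precipitation isoscape to expected feather values; its residual SD is
  added in quadrature to any per-cell isoscape SD. The transfer parameters
  are required configuration, not constants: published regressions for
  insectivorous passerines vary by region and species, and the values used
  by any particular study are part of its design. The shipped default
  (a = 0.95, b = −25 ‰, residual SD 12 ‰) is a documented placeholder in the
  typical range for insectivorous songbirds; the synthetic generator uses
  its own known calibration.
* **Carbon and nitrogen.** Plant isoscapes shift by fixed diet-to-feather
  discrimination offsets, +2 ‰ for δ¹³C and +5 ‰ for δ¹⁵N, each with a
  configurable residual SD (default 1 ‰ in the synthetic world, 0 when not
  stated).

## Probability-of-origin surfaces

For a sample **x** (the three-isotope set 2H/13C/15N, or the two-isotope
subset 13C/15N when δ²H is unavailable or distrusted), the likelihood that
cell *i* is the moult origin is the multivariate normal density at the
cell's feather-isoscape means. The covariance is diagonal by default, with
per-isotope variance composed transparently in quadrature:

    var_i = isoscape sd² (per cell) + calibration residual sd² + analytical sd².

Analytical (method) SDs default to 2 ‰ for δ²H, 0.1 ‰ for δ¹³C and 0.2 ‰
for δ¹⁵N — one-SD repeatability figures typical of IRMS feather work. A full
k×k covariance can be supplied as a hook for off-diagonal error structure;
it is added to the per-cell diagonal. Cells invalid in any required layer
are excluded (the density is undefined with missing components).

The posterior is the normalized likelihood over valid cells — deliberately
**no spatial prior** (a uniform-prior hook exists), so the assignment is
driven by isotopes alone and can be compared fairly against tracking.

**Odds-ratio masks.** The "upper 50 % (1:1 odds)" and "upper 75 % (3:1
odds)" maps are read as *cumulative posterior mass*: cells are ranked by
posterior (ties broken deterministically by row then column) and the
smallest prefix reaching mass q is marked likely, with the whole boundary
tie class included. This credible-region construction makes the odds ratio
literal — inside-to-outside posterior mass is q : (1−q). The alternative
reading, a quantile of per-cell density values, exists in the literature
and is available as `odds_mask(..., method="density_quantile")`; the mass
interpretation is the default. Mask nestedness (the 1:1 set is contained in
the 3:1 set) follows by construction. Individual binary maps are summed
into a population count map.

## Cluster assignment (linear discriminant posteriors)

When continental baselines are summarized as k isotopic clusters with
per-cluster, per-isotope mean and SD, a sample is assigned by Bayes' rule
under per-cluster Gaussians sharing a pooled covariance — the linear-DFA
construction. With only means and SDs available, the pooled covariance is
diagonal: the prior-weighted mean of per-cluster variances. A full pooled
covariance can be supplied in the cluster-stats file. Priors default to
equal; hard labels break posterior ties toward the lowest cluster id.
Grid cells are classified to their maximum-posterior cluster from the
feather-isoscape means, and the cluster composition of any cell set (e.g. a
KDE range) is reported as percentages, rendered as integers to match the
reporting dialect of published tables (raw probabilities are kept
alongside).

**Correspondence rule.** An individual's DFA assignment "corresponds" with
its tracked range when the hard-labeled cluster holds at least a threshold
share (default 50 %) of the range's cells. Both the inclusive (≥) and
strict (>) readings are implemented; the inclusive rule is the default
because one published composition sits exactly at 50 and only the inclusive
reading reproduces the published correspondence counts (8 at the 50 % KDE,
7 at the 75 % KDE for the five-cluster model).

## Kernel-density non-breeding ranges

Geolocator fixes (optionally filtered to the stationary October–March
window; undated fixes are kept) are projected to a per-individual
azimuthal-equidistant plane centered on their centroid, so the metric
bandwidth is honored without global equal-area distortion. The density is
the mean of quartic (biweight) kernels

    K(r) = 3/(π h²) (1 − (r/h)²)²,  r < h,

with the 300 km "search radius" as the kernel's support — matching the
kernel-density definition of the classic GIS tool the field used — evaluated
on a 10 km working grid (both configurable; a Gaussian kernel is offered as
an alternative). The 50 %/75 % volume contours are the smallest sets of
highest-density working cells reaching that probability mass, with the same
tie rule as the odds masks; their areas are cell count × cell area. For a
single fix the contour area has a closed form — the kernel's mass within
radius r is 1 − (1 − (r/h)²)³, so the 50 % and 75 % contours are circles of
radius 0.4542·h and 0.6083·h — which the implementation reproduces within
the discretization error of the working grid (≈1–2 % at 10 km).

Contours are projected back onto the 0.33° assignment grid by cell-center
membership (default) or by requiring a minimum overlapping fraction of a
5×5 interior lattice (`mode="overlap"`), since which rule the original GIS
workflow used is not knowable.

## Concordance

Per individual, overlap = |KDE mask ∩ assignment mask| in cells, and as a
percentage **of the KDE's cells** — the denominator choice is inferred from
the published per-individual arithmetic (21/207 = 10.1 %) and asserted in
tests. The matched pairing compares the 50 % KDE with the 1:1 mask and the
75 % KDE with the 3:1 mask. Summaries report column means (areas and cell
counts to the nearest integer, overlaps to one decimal, half away from
zero — the printed convention) and match counts (individuals with any
overlap). Medians are computed alongside means because summary-statistic
labeling in source material can be ambiguous; both are exposed.

## Synthetic data

The generator builds a world in which the assignment model is *correct by
construction*, so calibration properties can be tested:

* **Isoscapes** are planes (per-isotope gradients in ‰ per degree, default
  continental-scale magnitudes: 1.2 ‰/° latitude for δ²H, ~0.2 ‰/° for C
  and N) plus a Gaussian random field (smoothed white noise, restandardized;
  the smoothing scale is set so the autocorrelation e-folds at the requested
  correlation length, default 3°). A smooth field thresholded at a quantile
  supplies a land mask with the requested land fraction (default 0.9).
* **Feather values** are the feather-layer value at the true site's cell
  plus Gaussian noise. By default the noise SD is *matched* to the
  assignment model (isoscape sd² + analytical sd², with the calibration
  residual already in the layer SD); explicit SDs can be given instead —
  setting them away from the model, or assigning with a calibration offset
  from the generating one ("misspecification mode"), demonstrates coverage
  collapse, the qualitative failure mode of too-coarse or mis-calibrated
  isoscapes. That experiment is documented, not asserted.
* **Fixes** scatter around the true site with 150 km latitudinal and 60 km
  longitudinal SD (light-level latitude is the noisier coordinate), 50
  fixes per bird across October–March.
* All outputs are pure functions of (spec, seed); per-replicate seeds are
  derived from a `SeedSequence` so streams never collide.

**Coverage experiment.** With true sites drawn uniformly from valid cells —
the same prior the posterior uses — the true cell falls inside the q-mass
mask with probability equal to the mask's expected mass (slightly above q
because the discrete mask overshoots). The packaged experiment (500
replicates on a 60×60-cell world at 0.33°) lands within ±4 percentage
points of 50 % and 75 %. Restricting true sites to the interior while the
posterior normalizes over all cells breaks this prior-matching and biases
coverage low by a few points; the experiment therefore samples the full
valid mask.

Problem sizes (60×60 grids, 500 coverage replicates, 32-bird end-to-end
runs) were chosen so the whole suite and the acceptance script each run in
seconds while keeping Monte Carlo error well inside the stated tolerances.

## What the synthetic tests do and do not show

Passing coverage and recovery tests show the estimator chain is correctly
implemented and calibrated *when its model is true*. They do not show that
real-world assignments are accurate: real isoscapes carry structured,
unknown error (sparse calibration stations, interannual variation, habitat
effects below the landscape scale), diet may be spatially displaced from the
residence site, and transfer functions are borrowed across species and
continents. The package's concordance machinery exists precisely to measure
that gap; on the packaged study tables it reproduces mean overlaps of only
0.3 %/1.4 % (three isotopes) and 3.6 %/8.5 % (two isotopes) between isotope
assignments and tracked ranges.

## Known limitations and open points

* The end-to-end localization test uses complementary gradient directions;
  with near-collinear gradients (as in the default world) multi-isotope
  assignment leaves a weakly constrained ridge — itself an instructive
  failure mode.
* KDE areas are planar approximations on the working projection; distortion
  is negligible at range scales (≲1,000 km) but grows for ranges spanning
  tens of degrees.
* The per-individual table fixtures are transcriptions of printed values and
  inherit their rounding quirks (a few percentages 0.1 off their own
  cells/denominator arithmetic; one row whose printed overlap cells are not
  monotone across nested pairings; composition rows summing to 99–101).
  Tests treat these as documented exceptions rather than smoothing them.
* Light-level processing (twilight detection, equinox handling) is out of
  scope: positions are inputs.
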