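# Methods

## Data model

A time-series stack is a cube `(n_nodes, n_rows, n_cols)` of integer NDVI
scaled by 10,000 with a parallel pixel-reliability cube (0 good, 1 marginal,
2 snow/ice, 3 cloud, 255 fill) and a node calendar. Sensor A composites
start at DOY 1 + 16k, sensor B at DOY 9 + 16k (23 nodes each per year);
their interleave is a strictly (year, DOY)-sorted 46-node annual series
with an 8-day cadence. Node timestamps are composite *start* DOYs — the
products' own naming convention; mid-period timestamps would shift every
node by the same 8 days and change nothing downstream. Leap years keep the
nominal grid.

On disk a stack is a multiband int16 TIFF plus a uint8 reliability TIFF and
a JSON sidecar holding the calendar and a 6-number affine geotransform.
The sidecar, not TIFF tags, is authoritative for georeferencing; full
GeoTIFF CRS metadata is a known limitation of this container choice, which
buys bit-exact, tool-agnostic round trips with no heavyweight raster
dependency.

## Gap filling

Flagged nodes (codes 2, 3, 255) are replaced by linear interpolation over
node index between the nearest earlier and later anchor nodes (codes 0 and
1 — marginal data are deliberately usable anchors, they are retained, not
replaced). Node-index and calendar-time interpolation coincide because the
merged cadence is uniform; the 8-day spacing is asserted in tests. The
multi-year series is treated as continuous, so interpolation crosses the
December–January boundary; leading/trailing flagged runs take the nearest
anchor value (constant extension avoids extrapolation overshoot). A pixel
flagged at every node cannot be repaired: it keeps its values and is
counted in a log message rather than aborting a whole-scene run.

## HANTS

The smoother fits `y(t) = a0 + Σ a_i cos(2πit/T) + b_i sin(2πit/T)` for
`i = 1..nf` by least squares (SVD-based `lstsq`), then iterates: under
"low" suppression the accepted point lying furthest *below* the fitted
curve by more than the fit error tolerance (FET) is rejected and the curve
refit. Iteration stops when no accepted point violates the tolerance
(convergence), when another rejection would leave fewer than
`2·nf + 1 + dod` points, or at `max_iter`. Out-of-valid-range values are
rejected before the first fit. Rejecting a single point per iteration is
the classic, gentler behaviour; at convergence the curve is guaranteed to
sit no more than FET below any accepted observation.

Defaults: valid range −2000…9000 (scaled), nf = 3, FET = 1000, DoD = 8,
so a fit needs ≥ 15 accepted points. The "degree of overdeterminedness"
admits several readings across HANTS implementations; `2·nf + 1 + dod` is
used here as the minimum-point rule. Smoothing is applied per pixel per
calendar year by default (46 nodes against a nominal T = 368-day base
period, frequencies = the first nf annual harmonics); a whole-series mode
fits all years at once on a continuous day axis with the same annual
period. Per-year is the default because phenology is annual and it keeps
a wet year's outliers from leaking into a dry year's fit. Both the
per-year and whole-series question and the suppression side are not
settled by convention alone; low suppression is chosen because clouds and
snow only depress NDVI — the synthetic generator enforces exactly that
bias, which is what justifies the choice being testable.

Pixels that fail to converge (or lose too many points) keep their
gap-filled values — the pipeline never emits NaN rasters. In `hants_stack`
a vectorised first pass fits all pixels at once and accepts those that are
fully in range with no violation; only the remainder go through the
iterative path. The batch path is algebraically identical to a first-pass
convergence of the per-pixel path (asserted in tests).

Note the truncation limit: with nf = 3 a narrow Gaussian peak (σ ≈ 20
days) is not band-limited, so the fit smooths peaks down by more than FET
in places. Accuracy statements about "restoring to within FET of truth"
therefore hold for band-limited signals; for the bimodal crop curve the
same truncation applies identically at training and prediction time, which
is all classification requires.

## Synthetic scenes

The generator emulates the study conditions of a 250 m double-cropping
landscape: five classes (wheat–maize rotation, one-season crop,
forest/grass, water, built-up) in defaults of 40/15/20/10/15 % of the
scene, laid out in rectangular patches (default 4 px); 13 years
(2004–2016) of dual-sensor composites; cloud probability 0.2 per node,
snow 0.3 at winter nodes (DOY < 60 or > 330); contamination depresses the
value by U(0.2, 0.6) in NDVI units and sets the reliability code — it
never raises a value. Clean nodes are good, or marginal with probability
0.1. Class curves are a baseline plus Gaussian bumps with N(0, noise_sd)
observation noise (noise_sd 0.02 NDVI for crops; functional form chosen
for directly controllable peak DOY/height). The wheat peak DOY is redrawn
each year from 108–123 and the maize peak from 221–228, reproducing the
observed interannual spread of peak timing inside the broader 60–170 /
180–270 crop windows. The rotation class additionally expands by ~2 % of
its extent per year (converted from one-season pixels), matching the
sustained area growth a multi-year cropping record shows; set
`expansion_rate=0` for a static landscape. Everything derives from one
`numpy` Generator seeded once, so scenes are bit-reproducible.

What the generator does **not** emulate: mixed pixels at field boundaries,
geolocation error, BRDF/view-angle residuals, spatially correlated cloud
fields (contamination is i.i.d. per pixel-node), and class spectra that
drift between regions. Passing tests therefore demonstrate that the
pipeline recovers what its own model family generates — near-ceiling
accuracies on these scenes are expected and say nothing quantitative about
survey-grade accuracy on real imagery.

## Classification

Features are the raw 46-node smoothed curve of one year — no derived
phenology metrics, so the classifier sees exactly what the reconstruction
produced. Training points are drawn per 50 km grid tile (default 5 per
class per tile; real studies weight by land-cover complexity, which is
exposed as configuration because no universal counts exist) and pooled
across years by relative node position into one forest: 100 trees,
bootstrap per tree, √p candidate features per split (⌊√46⌋ = 6), majority
vote, ties resolved to the lowest class code. Samples are sorted
canonically before fitting so sample order cannot change the model. The
forest is scikit-learn's; the contract (trees, feature rule, determinism)
is pinned by tests.

## Assessment

Confusion matrices use rows = mapped, columns = reference, so user's
accuracy is a row quantity. Kappa uses the standard chance-corrected form.
The consistency index `c = (1 − |x − y|/y)·100` is left unclamped
(negative when the mapped area more than doubles the statistical area) and
binned into >80 / 60–80 / 40–60 / 20–40 / <20, lower edge inclusive.
The printed form of this index in the literature this package follows is
typographically garbled; the implemented reading is the only one
consistent with its verbal description and the published bin tables. Area
regression is free-intercept OLS of mapped on statistical area (a forced
zero intercept is a plausible alternative; the free intercept is reported
so the choice is visible). A constant mapped series has undefined
correlation; R² is reported as 0 in that degenerate case.

## Spatiotemporal products

Areas are pixel counts × 6.25 ha at 250 m, reported in Mha. "Average
growth rate" over a span is the arithmetic mean of the annual percentage
changes (not CAGR — the two differ in the third digit at these rates).
Change maps code each pixel gain/loss/stable/absent between two epochs and
satisfy the conservation identities `stable + loss = area(t1)`,
`stable + gain = area(t2)`. Planting frequency is the percentage of study
years a pixel is mapped as the rotation, so its raster equals the
per-pixel indicator mean × 100; the companion histogram partitions all
pixels (0, five 20 %-wide bins, exactly 100). Peak metrics report the
maximum smoothed value over nodes inside a DOY window (wheat 60–170,
maize 180–270) at node (8-day) resolution — sub-node interpolation would
claim precision the composite grid does not have.

## Problem sizes and numerics

The end-to-end fixture and the acceptance script use a 64 × 64 pixel,
13-year dual-sensor scene (598 nodes, ~4.9 M value cells) — large enough
for ≥ 1,600 validation points and stable per-class statistics, small
enough to run the whole chain in well under a minute. Integer NDVI is
carried as float during fitting and rounded half-to-even back to int16 on
output. Harmonic fits use `numpy.linalg.lstsq`; the test oracle solves the
normal equations independently. Degenerate inputs (all-flagged series,
single-class training sets, empty confusion rows, zero prior-year areas,
out-of-extent validation points) raise informative errors or are reported
as missing rather than silently patched.
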