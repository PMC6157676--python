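# Methods

This note documents the statistical procedure `charcomp` implements, the
defaults and why they are what they are, what the synthetic generator does
and does not emulate, and the numerical corner cases.

## Data model

A charcoal record is an irregular series of (age, value) samples, age in
calendar years before present (present = 1950 CE; ages may be slightly
negative for post-1950 samples and no lower clamp is applied), value
nonnegative in record-specific units. Records are canonicalized on read:
samples sorted by age, replicate samples at identical ages merged by
arithmetic mean (equal-depth subsamples are replicate measurements of the
same stratum), rows with missing values dropped and counted. Records left
with fewer than two samples cannot be standardized and are dropped with a
count. No cross-record unit conversion is attempted — the transform chain
removes units — and no influx computation from concentrations is done:
values are taken as provided. Age-model uncertainty is out of scope; ages
are used as given.

## Standardization chain

Per record, in order:

1. **Min-max rescale** to [0, 1]. Constant records are degenerate and are
   excluded (with a count) rather than propagated.
2. **Shift** by +0.01. Box-Cox needs strictly positive input and min-max
   produces an exact zero; a fixed small constant preserves ranks and
   keeps the distortion of the unit interval bounded. Exposed as
   `boxcox_shift`.
3. **Box-Cox** with exponent λ fitted per record by maximizing the normal
   profile log-likelihood
   `ℓ(λ) = −(n/2)·log σ̂²(λ) + (λ−1)·Σ log x`
   over the grid λ ∈ [−2, 2] step 0.01, ties broken toward 0. A grid
   search is exactly reproducible and directly checkable against an
   independent likelihood evaluation; tests verify agreement with scipy's
   `boxcox_llf` grid argmax and with its unbounded MLE. Note that when a
   record is already near-normal the profile likelihood is nearly flat in
   λ and the argmax is unstable — harmless here, since any λ in the flat
   region produces nearly the same transformed shape.
4. **Z-score against the base period** 12,000–250 cal yr BP: moments
   (mean, n−1 standard deviation) are computed from samples inside the
   base period and applied to *all* samples, so industrial-era samples are
   expressed relative to the pre-industrial reference without inflating
   it. Records with fewer than two base-period samples (or zero
   base-period variance) fall back to full-record moments rather than
   being dropped — dropping would bias short-record regions — and carry a
   `basis="full-record"` flag so the fallback stays auditable.
5. **Pre-binning** into half-open bins [k·w, (k+1)·w) of width w = 20 yr
   inside the analysis window 12,000–0 cal yr BP, per-bin mean, empty bins
   omitted, bin ages at centers. 20 yr is fine relative to the 250-yr
   smoothing half-window, so smoothing, not binning, controls resolution.

Every stage is strictly increasing in the value, so within-record ranks
are preserved exactly end to end; this is asserted as an exact test, and
is the reason rank-based trend statistics downstream are unaffected by the
transform choices.

## Compositing and uncertainty

Binned points from all records in a subset are pooled and smoothed at each
target age t (a regular grid, default step = bin width) by a local-linear
fit over points with |age − t| ≤ 250 yr, tricube weights in |age − t|/250.
Local-linear reproduces linear signals exactly (a plain weighted-mean
kernel is available via `kernel="mean"` for sensitivity runs, but shrinks
trends near window edges). Windows with fewer than two distinct ages fall
back to the tricube-weighted mean; empty windows are undefined (NaN, with
`n_sites = 0`). A fitted value outside the window's data range extended by
one range-width triggers the weighted-mean fallback — a guard against
extrapolation blow-up in one-sided edge windows. Edges (near 0 and 12,000
cal yr BP) use one-sided windows with no reflection padding; edge bands
are consequently wider and composite values there rest on fewer sites,
which `n_sites` makes visible.

The confidence band is a site-level bootstrap: each replicate draws
`n_records` whole records with replacement, rebuilds the smoothed
composite, and the band is the pointwise (1−conf)/2 and 1−(1−conf)/2
percentile envelope (percentile intervals, n_boot = 1000 by default,
conf = 0.95). The site — not the sample — is the exchangeable unit for a
"CI around the mean" across sites; within-record autocorrelation then
never crosses the resampling boundary. Replicates are computed by a
vectorized smoother that exploits the shared bin grid (precomputed tricube
weight matrices over (target, bin) pairs, with centered moment weights to
avoid cancellation); a test pins its equality with the generic pooled
smoother to ~1e−10. Results are bitwise reproducible given the seed.

## Trend and changepoint inference

**Trend** is Spearman's rank correlation between the composite and
calendar time (time = −age), on the defined composite ages, midranks for
ties, two-sided p from the large-n t approximation. ρ > 0 means burning
increases toward the present. The test is applied to the smoothed
composite; smoothing induces autocorrelation that the plain Spearman p
does not correct for, so p-values are interpretive, not exact — the ρ
magnitude and its cross-scheme comparison carry the weight.

**Changepoints** minimize `Σ_segments SSE/σ̂² + penalty·m` over
segmentations with segments of at least `min_seg` bins (default 5) and at
most `max_cp` changepoints, σ̂² estimated from lag-1 differences
(`mean(diff²)/2`) so the penalty is dimensionless. The optimum is exact: a
layered dynamic program over (number of changepoints, right endpoint),
vectorized over split positions. Changepoint ages are reported at the
midpoint between the flanking bin centers (= the shared bin edge on a
regular grid), oldest first. An exhaustive enumeration oracle with the
identical objective verifies the DP on short series; equality is asserted
over hundreds of random series. Two caveats are deliberate: the
first-difference σ̂² of a *smoothed* series is small, so the default
penalty segments smooth curves finely — `max_cp` (default 10 in pipeline
runs) is the practical regulator, and penalty/min_seg/max_cp are all
config-exposed; and a smoothed step becomes a ~250-yr ramp, so a
mean-shift segmentation may bracket a true step with two nearby
boundaries rather than one.

## Biome schemes and selection

A scheme is either a regular lon/lat grid of integer class codes (read
from Esri ASCII-grid text) or a mapping from contributor biome labels to
codes, plus the set of codes treated as grassland (and optionally an
explicit forest code list; "forest" subsets are membership in that list).
Grid containment is half-open [west, east) × [south, north); points on the
outer north/east boundary belong to the last cell; longitudes are wrapped
by 360° into the grid domain; points outside coverage (e.g. coastline
no-data cells) get the no-data sentinel and land in a `not_classified`
list instead of raising — the lookup rule at cell boundaries is this
package's own deterministic convention, since map products do not define
one. Selection summaries carry per-continent counts and percentages, and
scheme agreement is reported as pairwise Jaccard fractions plus the share
of the union selected by every scheme.

## Hovmoller band matrices

Each binned sample is classified into five contiguous half-open Z-score
bands centered on −1, −0.5, 0, +0.5, +1 with half-width 0.25 (dark blue,
light blue, gray, light red, dark red), lower edge closed, extreme bands
unbounded so |z| > 1.25 clamps and the partition is total. The dark-blue
band is the mirror image of dark red (centered at −1). Default row order
is record span, longest first, so the sites contributing most sit on top.

## Synthetic generator

Each site draws a span (youngest endpoint U(0, 500), oldest
U(9000, 12000) cal yr BP by default), sample ages from a renewal process
with exponential gaps (mean 100 yr — a typical compilation's sampling
resolution), and values `exp(c·g(age) + log s_i + ε)` with trend g on the
Z-scale, amplitude c = 1, per-site scale `log s_i ~ N(0, 1)` (an
order-of-magnitude between-site spread, which is what the min-max/Box-Cox
stages exist to absorb), sample noise ε ~ N(0, 0.5²), and exact zeros with
probability 0.05 to exercise the shift path. Trends: constant, linear
(slope per kyr toward the present), step, piecewise-constant. The paired
truth object exposes the trend on the bin grid, true changepoint ages and
site factors.

What it does **not** emulate: age-model uncertainty and age reversals,
serially correlated noise within a record, spatially clustered site
locations, taphonomic regime shifts, or secular changes in sampling
density. Passing recovery tests therefore demonstrate that the pipeline's
logic is correct and calibrated under clean heterogeneity — not that real
compilations meet these assumptions.

## Validation experiments and problem sizes

The experiment drivers (`charcomp.experiments`) use bin width 50 yr
(100 yr for the coverage study) and a few hundred bootstrap replicates so
the full battery runs in about a minute on one core; these sizes are the
package's own desk-scale choices and leave the conclusions unchanged at
finer settings. The battery: exact rank preservation over 100 random
records; base-period moment identities to 1e−10; λ-oracle agreement within
one grid step over 100 series; linear-trend recovery (+0.1 Z/kyr, 40
sites, noise sd 0.5: ρ ≥ 0.8 expected in ≥ 18/20 seeds); step recovery
(+1 Z at 4,000 BP, noise sd 0.3: located within ±250 yr in ≥ 90% of 50
seeds); DP-vs-enumeration equality on 200 short series; and 95%-band
pointwise coverage within [0.90, 0.98] over 200 simulations of 30 i.i.d.
sites (observed ≈ 0.93 — the familiar mild anticonservatism of percentile
bootstrap at n = 30).

## Known limitations

- Spearman p-values ignore smoothing-induced autocorrelation (above).
- The penalized segmentation's penalty scale interacts with smoothing;
  comparisons across differently smoothed curves should fix the
  bin width and half-window.
- Percentile (not BCa) bootstrap intervals; slightly anticonservative at
  small site counts.
- Grid-scheme selection is raster lookup only: polygon products must be
  rasterized upstream at a user-chosen resolution, and no map projections
  beyond geographic lon/lat are supported.
- Composite values where `n_sites` is small (edges, sparse subsets) are
  dominated by few records; the Hovmoller matrix and `n_sites` column are
  the intended diagnostics.
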