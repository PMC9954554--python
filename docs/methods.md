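# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data validation does and does not show.

## Interface extraction and boundary length

The epithelium–stroma interface is traced on the inter-pixel "crack"
lattice: every 4-adjacent epithelium/stroma pixel pair contributes the unit
lattice segment between the two pixels. Pairs involving artifact or
background are never traced, so cautery edges, necrosis and slide borders
generate no interface bands. Cracks sharing lattice corners are chained
into maximal polylines (open chains start at odd-degree corners; at
degree-4 corners the walk continues straight through, a deterministic
tie-break), then smoothed — crack midpoints as vertices, terminal corners
kept on open chains — and simplified with Douglas–Peucker at 0.8 px
tolerance. The smoothing/simplification step is what makes traced lengths
meaningful: a raw crack (city-block) perimeter overestimates a digitized
circle's circumference by ~27%, the simplified polyline by +0.2% (straight
and 22.5° interfaces are exact). Boundaries shorter than 1000 µm (summed
segment length of the stored polyline, threshold inclusive on the keep
side) are removed as classifier noise before any band is formed; the
filter is applied after artifact-edge exclusion, per maximal polyline.

## Band ranking

Distances are Euclidean, from each pixel center to the nearest retained
boundary polyline, computed with an exact distance transform on a 2×
supersampled lattice on which the polylines are densely sampled (0.25 px
spacing). The measured distance error against exact point-to-segment
minima is ≤ 0.36 px, so rank disagreements with the exact-distance oracle
can occur only for pixels within half a pixel of a band edge (and then by
at most one rank) — the oracle test asserts exactly this. Band magnitude is
`ceil(d / w)` with half-open intervals `((|r|−1)·w, |r|·w]`; a pixel at
distance exactly 0 belongs to band 1. Sign comes from the pixel's
compartment label. Pixels near several boundaries take the nearest one
(distance-transform semantics, measured globally across all retained
boundaries rather than per epithelial region). Artifact and background
pixels, and pixels beyond the zone width, carry a sentinel (−128 in
exports). Default geometry: 10 µm bands, 150 µm zone per side (extended to
300 µm when the variant grid requires it), 0.5 µm/px rasters.

## Densities and indicators

A CD8+ centroid contributes to the band of the pixel containing it
(deterministic containing-pixel rule; CD8− cells are carried through I/O
but never counted). Band densities are counts/area in cells/mm²;
compartment densities exclude artifact pixels from denominators by
construction. Zero-area bands and zero-denominator ratios are NaN with a
recorded reason, and propagate to the survival stage as missing values
(complete-case per model) rather than errors; an explicit pseudocount was
considered and rejected as it would bias exactly the small bands it would
rescue. In the center of mass the band index is the integer rank, not the
µm midpoint, making both indicators dimensionless. The variant grid emits
ID(r) and CM(R′) for every rank with `r·w ≤ max width` with µm-range
labels; when several variants are screened downstream, the one with the
lowest univariable p-value wins, ties breaking toward the smaller zone
width (closest to the interface).

## Survival pipeline

Cox models are partial-likelihood fits with the Efron tie correction
(times are continuous months, so ties are rare but handled). The pipeline:
administrative censoring at 60 months; an event-stratified random split
(117/40 by default, largest-remainder allocation so event proportions
differ by less than one event's worth); univariable screening at strictly
p < 0.05 (grade enters screening as three separate dummies; only G3 is
eligible for multivariable models); exhaustive enumeration of covariate
subsets of size ≥ 2 — redundant combinations (both indicators, both
history-flag variants) are fitted and left to fail the filter rather than
pre-excluded; the all-covariates-significant filter; event-stratified,
seeded 5-fold cross-validation scoring the held-out fold's Harrell C with
the linear predictor as risk (ties in mean validation C break toward lower
AIC, then fewer covariates); and a final refit-on-train evaluation on the
hold-out set. Harrell's C counts concordant comparable pairs with risk
ties at ½; pairs whose earlier time is censored are not comparable.
Leave-one-out folds are rejected (single-subject folds carry no comparable
pairs). Log-rank p-values are reported pairwise without multiplicity
correction. Tertiles are equal-sized groups, remainder to the lower groups
first (n = 10 → 4/3/3), boundary ties broken by stable input order, with a
warning when all values coincide. The combined risk score adds one point
each for G3, positive reTUR or recurrent tumor, and medium-or-high ID
tertile; {0,1} → low, 2 → intermediate, 3 → high.

For coefficient-recovery validation the package uses 95%
profile-likelihood intervals (fixed-offset refits of the partial
likelihood, chi-square(1) cutoff) rather than Wald intervals: the
immunodrop covariate is right-skewed and measured Wald coverage was ~94%
versus ~95% nominal.

## Synthetic data: what it emulates

**Masks** emulate thin, elongated papillary fronds: gently bending thick
polylines (flat caps, round joins) in a stroma background, with optional
artifact disks. A straight frond is exactly a rectangle, pinning the
traced-length check (perimeter within 5%). **Cell patterns** are band-wise
Poisson: per band, counts ~ Poisson(density × area), placed uniformly over
the band's pixels, with plateau densities outside the zone. The programmed
band density is `ρ_plateau · exp(−λ·(|r|−1))` per side (defaults: stromal
plateau 300 /mm², epithelial 100 /mm², epithelial decay λ = 0.3, stromal
decay 0 — a stromal-excess profile, ID > 1 and CM < 0). Band-wise sampling
(not a continuous spatial intensity) makes the programmed densities
exactly the estimands of the band-density profile, so parameter recovery
is exact in expectation. **Cohorts** draw covariates at prevalences typical
of a BCG-treated NMIPUC series (54.1% G3, 36.9% positive reTUR, 29.9%
recurrent tumor, drawn independently; their OR then has prevalence 55.8%),
immunodrop values log-normal(0, 0.35) unless measured values are supplied,
and event times exponential with rate `1.5e-4 · exp(β·x)` per month under
administrative censoring at 60 months. The baseline rate was calibrated
once, numerically, so the expected event fraction under the default hazard
ratios (4.4492 history, 2.3672 G3, 5.5072 ID) is ~24.8%. All generators
are bit-exact reproducible per seed.

What passing synthetic tests does *not* show: real tissue classifiers make
spatially correlated errors near the interface (the generators' masks are
exact); real CD8+ patterns are clustered beyond Poisson; and recurrence
hazards are not exactly proportional or exponential. The validation
demonstrates correctness of the measurement and selection machinery under
its own assumptions, not clinical performance.

## Problem sizes in the validation studies

Replicate-heavy studies are sized for a single CPU. Cohort simulations use
n = 400 (200 replicates for coefficient recovery, 1000 univariable fits
for the null error rate, 50 replicates for model selection with a 300/100
split preserving the 3:1 train:test proportion). Slide replicates use
800 µm square tiles with 8 fronds at a 1 µm raster and a 500 µm boundary
filter — tile-scaled so that each replicate carries ~4–5 mm of interface
and rank-2 band counts of ~10+ cells; with fewer fronds or smaller tiles
the immunodrop ratio is dominated by Poisson zeros in the epithelial
bands, a tissue-quantity artifact (a real slide carries two orders of
magnitude more interface), not a property of the method. Mean-of-ratios
immunodrop estimates are biased upward at low counts, so flat-control
checks pool counts across replicates before forming the ratio and use
Poisson / delta-method error bands.

## Known limitations

* Interface tracing assumes a clean two-phase epithelium/stroma labeling;
  heavily fragmented masks produce many short boundaries that the length
  filter removes wholesale.
* The 0–10 µm band pair is measurable but known to be sensitive to
  classifier jitter at the interface; no correction is applied.
* The EORTC clinical risk algorithm is not implemented (out of scope), so
  comparisons against routine risk tables are left to the user.
* Only the recurrence-free survival endpoint is supported.
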