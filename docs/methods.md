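# Methods

This note documents the models and conventions behind `retmosaic`, the
parameters that matter, and what the synthetic-data tests do and do not
demonstrate about real retinal images.

## Coordinates, units, windows

All geometry is computed in µm.  Coordinate tables follow the ImageJ export
convention (origin top-left, y downward); every statistic here is
orientation-agnostic, so the convention only affects plotting.  Each point
pattern carries an axis-aligned rectangular observation window.  When no
window is declared the tight bounding box of the points is used and a
warning is raised: the bounding box underestimates the true field of view,
which matters for edge correction and for the overall density estimate
`D = n / window area`.

## Density recovery profile

For every ordered pair of distinct cells, the pair distance is tallied into
uniform annular bins `[r, r+Δ)` around the reference cell.  Distances within
`1e-9·Δ` below a bin edge are snapped onto the edge before binning — exact
lattice spacings otherwise land one bin low through floating-point rounding,
which would truncate a perfect lattice's exclusion zone.  A pair distance at
or beyond the maximum radius is excluded.

**Edge correction.**  Each annulus's area is intersected with the window
*exactly*, per reference point, using a closed-form disk–rectangle
intersection area (the four-corner decomposition of the disk integral over
quadrants; verified in the tests against a high-resolution polygonal
oracle).  Per-annulus density is `count / Σ_ref (annulus ∩ window)`.  Without
correction the profile decays artificially near the maximum radius; a test
documents this bias.  The grid fallback mentioned for non-rectangular
windows is not needed: windows are rectangles throughout.

**Normalization.**  The profile is divided by the overall density so the
far field sits at 1; mosaics dip toward 0 near the origin, clusters exceed 1.

**Effective radius.**  The dead-space volume is the deficit
`(D − raw_k)` summed over the initial run of bins where the profile sits
*below* the overall density — i.e. from the origin up to the first bin at
which the profile recovers to `D` — weighted by the geometric annulus area
`π(r²_{k+1} − r²_k)`.  Two deliberate choices here:

1. *Stop at first recovery.*  Accumulating every below-average bin across
   the whole profile would count ordinary sampling fluctuation (roughly half
   of all far-field bins of a random pattern sit slightly below `D`) and
   the empty troughs between the spikes of a lattice profile, inflating the
   effective radius of patterns with no exclusion zone at all.  With the
   first-crossing rule a random pattern's effective radius is near zero and
   a perfect lattice's is its spacing, as the definitions require.
2. *Weight by the full annulus area.*  Edge correction belongs in the
   density estimate; the deficit is a density and its volume integrates over
   the geometric annulus.  Weighting by the clipped areas instead would
   shrink the dead space of boundary-adjacent reference cells and bias the
   packing factor low in small fields (observed as PF ≈ 0.86 instead of 1
   for a perfect lattice in a 20×23-cell window).

Then `r_e = √(V / (π·D))`, clamped at 0.

**Packing factor.**  `PF = (r_e / r_max)²` with `r_max = √(2/(√3·D))`, the
nearest-neighbour spacing of the triangular lattice at density `D` — the
densest packing, so PF = 1 marks perfect order and PF = 0 no exclusion zone.
The ratio is clipped to [0, 1]: binning discretization can push `r_e`
slightly past `r_max` for a perfect lattice.

**Defaults.**  `bin_width` defaults to a quarter of the mean
nearest-neighbour distance and `max_radius` to 40 bin widths; both are
routinely overridden (the tests and examples use 5 µm bins to 200 µm in
1000 µm fields, which resolves exclusion zones of 20–50 µm).  A warning is
raised when `max_radius` exceeds half the shorter window side.  Note that
for a hard exclusion zone the discretized `r_e` equals the exclusion
distance exactly, so PF then varies only through density.

## Voronoi domain analysis

The planar tessellation is computed with GEOS (`shapely.voronoi_polygons`)
and clipped to the window; clipped domains partition the window to machine
precision (asserted at 1e-6 relative).  Domains touching the window
boundary are excluded from the statistics — their areas are truncated by the
field of view — and the exclusion count is always reported.  The headline
statistic is the variance-to-mean ratio of interior domain areas with
sample (n−1) variance.  The VMR carries units of µm² and controls for
density only up to scale, so the dimensionless CV² (variance/mean²) is
reported alongside: CV² is invariant under uniform rescaling while VMR
scales as the square of the factor (both asserted in tests).  Duplicate
points are rejected rather than merged: two cells at one coordinate is a
digitization error upstream.

## Nearest-neighbour regularity

NNRI = mean/SD (sample SD) of nearest-neighbour distances.  A perfectly
regular pattern has SD → 0; this is signalled as a degenerate-regularity
condition rather than returned as a number.  The measured NNRI is divided by
the mean NNRI of `n_reps` random arrays of equal count in the same window
(default 99; `n_reps=1` reproduces the literal single-array normalization
but is noisy).  No edge correction is applied on either side: the window is
identical for measured and random arrays, so the boundary bias cancels in
the ratio.  For an unbounded Poisson process NNRI → 0.5·√(4π/(4−π)) ≈ 1.913;
the test suite recovers this on interior (edge-buffered) points.

## Elo tournament

Every image starts at rating 0.  After a matchup the winner gains
`Δ = K·(1 − E_winner)` and the loser loses the same `Δ`, where
`E = 1/(1+10^((r_b−r_a)/s))` is the chess-standard logistic expected score.
This satisfies the two defining requirements — exchange depends on
pre-matchup ratings, and upsets move more points — and conserves the total
rating exactly (asserted after every matchup in tests).  Defaults `K = 32`,
`s = 400`, initial rating 0; only rating differences enter the update, so
the conventional 1500 offset is irrelevant.

Live tournaments draw uniformly random distinct pairs in sweeps of ⌈n/2⌉
matchups and stop once the genotype mean-rating rank order has been stable
for 5 consecutive sweeps (200-sweep cap).  A recorded comparison log is
replayed in order and in full; convergence is tracked but never truncates a
replay.  All raters' choices pool into one rating in arrival order; per-rater
tournaments on the same simulated latent scores correlate at Spearman ≥ 0.8
(tested), supporting the pooling.  Retinal means of ratings are compared
across genotypes by Wilcoxon rank-sum (exact null when combined n ≤ 20 and
tie-free, normal approximation with continuity correction otherwise) under
Benjamini–Hochberg correction.

## Image metrics

"Above threshold" is strict (`>`) everywhere.  Percent area is a pure
histogram statistic (permutation-invariant).  The overlap ratio intersects
the two thresholded masks and divides by the channel-1 (marker) mask area —
the deterministic equivalent of a threshold-and-multiply colocalization
workflow, and deliberately asymmetric in the channels.  Line profiles sample
bilinearly at pixel pitch, endpoints inclusive, and must lie entirely inside
the image; on axis-aligned integer-pixel segments the mean equals the plain
pixel average.  Inputs are already-projected 2D images; 3D reconstruction
and cropping are upstream of this package.

## Group statistics

The retina is the experimental unit: per-image values are averaged to
retinal means (genotype consistency within retina enforced), and retinal
means enter the tests.  One-way ANOVA with Tukey HSD (studentized range,
Tukey–Kramer correction for the unequal retina counts typical of this data,
N ≈ 4–8); Student's equal-variance t for two-genotype designs (Welch behind
a flag); two-way ANOVA (type II, equivalent to type I on the balanced
layouts used) for genotype × threshold level; step-up BH for families of
rank-sum tests.  A calibration suite draws 500 null datasets per test and
checks the p-values against Uniform(0,1) by Kolmogorov–Smirnov.

## Synthetic data: what it does and does not show

The generators reproduce the *spatial signatures* the statistics must
distinguish: sequential-inhibition (`dmin`) patterns have a hard exclusion
zone; Neyman–Scott clusters (uniform parents, Poisson offspring, Gaussian
dispersal) have elevated near-origin density; jittered triangular lattices
interpolate between perfect order and noise; Bradley–Terry raters pick
winners with logistic probability in the latent-quality gap, matching the
Elo model's own assumptions.  Demo cohorts draw per-image cell counts from a
Poisson around the nominal count, as fields of real retinas do.

None of this emulates the *measurement* process of real images: soft
(graded) exclusion zones, segmentation and click errors in cell positions,
uneven illumination, or rater idiosyncrasies beyond a shared latent scale.
Passing tests therefore demonstrate that the estimators recover known
ground truth under their own model assumptions — they do not validate cell
detection or rater behaviour on real micrographs.

## Numerical conventions and degenerate inputs

Half-open bins with edge snapping (above); duplicate points are errors in
the Voronoi and NN modules; fewer than 2 (DRP), 3 (NNRI, Voronoi) points are
errors; collinear point sets are rejected before tessellation; an empty
marker mask makes the overlap ratio undefined (error, not 0); zero overall
density makes the packing factor undefined.  Every stochastic routine takes
an explicit seed and is reproducible byte-for-byte; the pipeline writes a
manifest with seeds, config and input digests.  Problem sizes in the test
and acceptance suites (fields of 300–2000 cells in 1000 µm windows, 10–20
seeds per stochastic check, 500-replicate calibration) were chosen as the
smallest at which the Monte-Carlo error is comfortably inside each
tolerance.

## Known limitations

- Rectangular windows only; no support for masked or circular fields.
- Single-population DRP; no cross-correlograms between two cell types.
- The packing factor of hard-core (dmin) patterns is discretization-exact
  at the exclusion distance, so its within-genotype variance comes from
  density alone — real (soft) mosaics vary more.
- No automatic threshold selection for the image metrics; the three
  threshold levels are required configuration.
- No tie handling in comparisons (forced choice by design).
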