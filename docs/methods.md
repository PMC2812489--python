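# Methods

This note documents the models, algorithms and design choices behind
`mosaicpop`: what each stage assumes, which parameters matter, and what
the synthetic setting can and cannot say about real landscapes.

## Synthetic landscape generator

The generator emulates the statistical structure of an intensively
mapped agricultural mosaic at desk scale.  The default raster is 200×200
cells of 50 m (standing in for a 10×10-km map at finer resolution; the
cell size is metadata, so the quarter-decade size-class binning
`floor(4·log10(area in m²))` applies unchanged).  Barrier elements —
a road grid, a meandering river, scattered buildings and lakes, ~5% of
cells — are stamped first and never altered afterwards.

Habitat patches are laid out by stochastic region growing.  Because
barriers wall the free space into compartments that patches cannot
cross, patch counts and target areas are allocated per compartment:
each compartment receives seeds in proportion to its size and target
areas drawn log-uniform over 3–300 cells (two orders of magnitude,
right-skewed on the raw scale) rescaled to tile the compartment exactly.
Growth claims one uniformly chosen free 4-adjacent cell at a time, with
the growing patch selected with probability proportional to the fraction
it remains to grow, so nearly finished patches grow slowly.

Two structural features make the reference mosaic behave like a real
landscape rather than a random tessellation:

* **Type clustering.**  Types are assigned to patches greedily by
  remaining cover deficit, weighted by proximity to a per-type random
  attraction center (length scale 0.4×extent).  Real mosaics aggregate
  same-type patches through soil, hydrology and management; without this
  aggregation, arrangement randomization would have nothing to destroy
  and same-type separation would not rise from A to C.  The deficit
  weighting still drives per-type cover to its vocabulary target within
  about one percentage point.
* **Field margins.**  With `field_margins=True` (the study default) the
  `field_boundary` and `hedgerow` cover targets are realised by carving
  one-cell rims off rotational fields, split into short angular segments
  of ~18 cells.  These thin, elongated, field-adjacent patches are the
  corridors and overwintering habitat of the reference landscape; they
  are exactly what shape homogenization destroys.  Segments (and the
  cores they are carved from) can occasionally be 4-disconnected; the
  data model does not require patch contiguity and every transform
  handles arbitrary shapes.

Default cover fractions (of the non-barrier area): rotational field
0.45, grassland 0.15, forest 0.12, field boundary 0.10, roadside verge
0.10, hedgerow 0.08 — a reduced six-type vocabulary sufficient to drive
all four archetypes' mechanisms, with the five barrier types alongside.

## Complexity-reduction transforms

**B — shape homogenization** re-grows every habitat patch from its
original centroid (snapped to the nearest original member cell) with the
same remaining-fraction growth rule, conserving identifiers, types and
areas while producing compact shapes.  Growth deadlocks (a patch walled
in before reaching its target) are unavoidable; a rebalancing pass then
shifts surplus cells back to deficit patches one unit at a time along
shortest paths in the patch-adjacency graph, choosing donated boundary
cells that keep every donor 4-connected (backtracking over alternative
paths when a donation would disconnect a donor).  On the 50-patch
reference configuration the transform conserves every area exactly or
nearly so (≥95% exact, residual drift a handful of cells); at the
200×200 study scale the residual is ~1% of the grid.  Patches sealed
away from any surplus keep their deficit and are reported.

**C — arrangement randomization** permutes type labels uniformly at
random among habitat patches within each quarter-decade size class.
Geometry never changes; per-type patch counts are conserved exactly and
per-type cover up to the within-class area spread (a 5% relative
tolerance is checked and logged, configurable).  Size classes with one
habitat patch keep their label.

**D — size randomization** permutes labels across all habitat patches,
so the expected cover of a type equals its patch-count frequency times
the habitat area — composition change by construction.  Because margins
are numerous and small while fields are few and large, D enlarges
boundary/hedgerow cover and shrinks mean field size, the same signature
the study landscape shows.

## Individual-based models

One annual cycle: **breed → disperse → overwinter → census**, with the
census at the start of the year (so a perturbation applied right after a
census leaves that year's record pre-removal).  The models are
deliberately minimal: only yearly censuses are analyzed, so the yearly
cycle is the smallest faithful unit.

* *Breeding.*  Each adult on habitat type *h* in patch *p* produces
  Poisson(r_max · fec[h] · w_y · max(0, 1 − n_p/(κ[h]·area_p)))
  offspring, where n_p is the patch's current adult count — logistic
  density dependence emerges at patch level.  Avoidance species do not
  breed within d_t cells of avoidance habitat.
* *Dispersal.*  Every juvenile draws a uniform direction and a uniform
  distance on [0, d_max] and follows the cell-center rasterized straight
  line.  Short dispersers stop at the cell before the first barrier cell
  (or the grid edge); fliers cross barriers at no cost and settle on the
  last non-barrier cell of the path.  Each disperser dies with
  probability `dispersal_mortality`.
* *Overwinter.*  Survival is a per-habitat-type probability; for the
  complementation species it is additionally zero unless habitat of the
  complementation set lies within d_w cells.  Semelparous species
  (beetle, spider) lose all post-breeding adults; iteroparous adults
  (vole, skylark) face the same overwinter survival as juveniles.

Archetype parameters ship in `mosaicpop/data/archetypes.yaml`
(version 1).  The absolute values are desk-scale choices; only the
ordinal relations are meaningful — beetle and spider reproduce faster
than vole and skylark, beetle and vole disperse far less than skylark
and spider, and the spider pays much higher dispersal mortality.  The
spider's dispersal range (150 cells) is deliberately landscape-scale:
ballooning makes its settlement distribution nearly uniform over the
mosaic, which is what renders it indifferent to patch arrangement while
still sensitive to composition.  Weather multiplies fecundity through a
fixed cycle of ten log-normal(σ = 0.15) year multipliers, giving the
"weather year" grouping used by the fits.

A closed single-patch population under this scheme is exactly the scalar
stochastic-logistic model (Poisson births, binomial survival); the test
suite verifies distributional agreement against an independently coded
scalar oracle and against the matched deterministic map's fixed point.

## Perturbation protocol

Defaults: 181 years, 11-year burn-in, removal fraction 0 / 0.80 / 0.95,
removal every 17th year.  Removal retains exactly
round((1−fraction)·N) survivors chosen uniformly without replacement, so
removal intensity adds no extra variance.  The k-th removal is applied
immediately after the census of year 11 + 17k (k = 0…9), making the
first post-perturbation census t = 1 and the analyzed window exactly ten
17-year recovery segments over 170 yearly records.  Census-then-remove
ordering means a flagged year's recorded N is always pre-removal.
Zero-count years keep their records with an undefined-log marker and are
excluded from fitting but counted.

## Recovery fitting

Stage 1 fits the pooled fixed curve by bounded nonlinear least squares
(starting values: ln K₀ = max ln N, m₀ = first t with ln N ≥ ln K₀/2,
φ₀ = L/8; bounds φ ∈ [0.05, 10 L]).  Stage 2 estimates weather-year
asymptote offsets b_y from label means of late-window (t ≥ m̂ + φ̂)
residuals with empirical-Bayes shrinkage λ_y = σ_b²/(σ_b² + σ_e²/n_y),
variance components by one-way method of moments.  This two-stage scheme
reproduces the target quantities (K, φ, among-year variation) with a
transparent, dependency-light algorithm; the pinned contract is the
estimates, intervals and convergence flag, not the estimator.

Confidence intervals come from a 200-replicate parametric bootstrap of
the fitted mixed model; each replicate redraws the label effects with a
σ_b scaled by an inverse-chi-square draw so the intervals carry the
sampling uncertainty of the variance component (without this the K
intervals undercover).  The optimizer failing, φ pinned at a bound, a
flat series, or mass bootstrap failure all yield `converged=False`
without an exception — mirroring how a non-converging mixed model is
reported rather than raised.

At the study design (10 segments × 17 years, 10 labels, σ_e = 0.1,
σ_b = 0.2) the suite checks median relative errors of K̂ and φ̂ below
10% and interval coverage of at least 85% over 200 replicates; noiseless
data are recovered to 1e-4 relative error for both the 3- and
4-parameter forms.  The four-parameter form adopts a lower-asymptote
logistic, A + (ln K − A)/(1 + e^((m−t)/φ)); `auto` selection selects it
when the 3-parameter fit leaves one-sided early-time residual structure
(binomial sign test at z > 1.645).  φ's meaning as a return time is
pinned by the tail e-folding property: the fitted curve's log-scale
deviation from its asymptote decays by a factor e per φ years
(asymptotically; the ratio equals e to 1e-4 already at m + 10φ).

Unperturbed runs use per-label means of ln N with K the exponential of
the label-mean average.  Per-segment asymptotes (for the
incomplete-recovery analysis) share (m, φ) across segments with free
per-segment ln K_j; their standard errors come from the Gauss–Newton
covariance, and the decline verdict is a weighted linear trend whose
confidence interval must lie entirely below zero.

## Scales, runtimes and what the tests do not show

The package's study conditions are a desk-scale emulation: 200×200 cells,
1000 grown patches plus carved margins, populations of 10⁴–10⁵
individuals.  The directional-mechanism checks (beetle K non-increasing
from A to C, beetle collapse when complementation habitat is pushed
beyond d_w, spider arrangement-insensitivity within replicate
Monte-Carlo noise) are seed-averaged over ten replicate mosaics;
equilibria there are estimated from 40-year unperturbed runs (mean
census over the last 18 years), which is ample at these growth rates.
Absolute K and φ values are properties of the synthetic mosaic and the
archetype defaults, not of any real landscape or species; only
directions, orderings and calibration properties transfer.  Real-data
features the generator does not emulate include crop rotation dynamics,
within-year phenology, irregular field geometry and long-range spatial
trends in soil quality.

## Numerical details worth knowing

* All logs are natural; zero counts are flagged, never log-transformed.
* 4-neighborhood defines contiguity, growth and patch adjacency
  throughout; straight-line barrier checks use cell-center rasterization
  (diagonal corners do not block).
* Centroids are unweighted means of member-cell centers, (row, col),
  row 0 at top; a centroid outside its (concave) patch is snapped to the
  nearest member cell when used as a growth seed.
* Every stochastic stage takes a seed derived from the master seed and a
  stage label (`mosaicpop._rng`), so any cell of a factorial design is
  independently replayable; sub-seeds are collision-checked in the test
  suite.
* ESRI ASCII grid + CSV is the only interchange format; areas and
  centroids are always recomputed on read, never trusted from file.
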