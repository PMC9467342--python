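# Methods

This note documents the models, numerical choices and limitations of
`mareyscape`, in the order the pipeline applies them.

## The Marey-map model

A Marey map for one chromosome is the set of markers (x_i, d_i) with
x_i the physical position (bp, treated as 1-based inclusive on input
and converted to 0-based half-open internally; all window output is
BED-convention) and d_i the genetic position (cM).  The underlying
Marey function d(x) is assumed monotone non-decreasing; the local
recombination rate is its derivative.  Maps whose marker cloud
decreases (Spearman rho of cM vs bp < 0) are reflected
(d_i → max d − d_i); orientation is an involution, so re-orienting an
oriented map is a no-op.  Duplicate genomic positions are collapsed to
their mean genetic position before any fit, because loess needs
distinct abscissae.

### QC filters

A map is dropped when it has fewer than `min_markers` (default 50)
markers, or when either chromosome end is missing more than
`max_end_gap_frac` (default 10%) of the chromosome.  The marker
threshold can be lowered to admit hand-validated sparse maps (~30
markers).  These thresholds are conventions for curated linkage-map
collections, not estimates; both are exposed as parameters.

### Outlier removal

Published criteria for outlying markers are usually visual.  The
automated proxy here: fit the loess Marey function, remove markers
whose absolute residual exceeds `resid_frac` (default 0.05) of the raw
map length, refit, and iterate to a fixed point (max 5 passes).  Two
details matter in practice:

- the fit used for residuals is *robustified* (two Cleveland bisquare
  reweighting iterations) so a gross outlier cannot drag its own
  neighbourhood and implicate genuine markers around it;
- the bisquare scale is floored at the removal threshold itself.  The
  classical 6×median-|residual| scale assumes residuals are noise; on
  sharply distal maps with little marker noise, systematic local
  lack-of-fit would otherwise be down-weighted as if it were outlying,
  flattening the fit near the telomeres.  With the floor, only actual
  removal candidates lose weight.
- when no span is supplied, a short hold-out calibration picks it, so
  sharply distal maps are not over-smoothed into spurious boundary
  residuals.

Removing more than 20% of markers aborts with an error — such a map is
more likely mis-assembled than noisy.  On generator fixtures with
injected outliers (displacements of 0.2–0.4 map lengths), recall is
≈ 1 and the false-positive rate well below 2% (asserted in the tests).

### Map-length correction

Undetected terminal recombination is compensated by adding twice the
average marker spacing to each linkage group: s = raw length / (n − 1),
corrected = raw + 2s.  Marker coordinates and inter-marker distances
are unchanged.  `s` as total length over gaps is the natural reading of
"average marker spacing"; users preferring per-gap means can substitute
their own.

## Loess interpolation and window rates

The Marey function is interpolated by local quadratic regression with
tricube weights (`mareyscape.loess`): for each evaluation point the
q = ceil(span·n) nearest markers are weighted by
(1 − (|Δx|/max|Δx|)³)³ and a degree-2 weighted polynomial is solved.
This is the standard loess definition; it was written in-package (a
batched, vectorised normal-equations solver) and is cross-checked in
the tests against exact polynomial reproduction and against
statsmodels' local-linear lowess on linear data.  Degenerate
neighbourhoods (fewer weighted points than coefficients) degrade to a
lower local degree.

**Span calibration.**  The span is chosen on a grid in [0.2, 0.5]
(default step 0.05) by repeated hold-out partitioning: markers are
split 2/3 train / 1/3 test, the smooth fitted on the training set and
scored by test MSE; the library default is 1,000 partitions (the
analysis drivers use fewer — 20–100 — which is where the chosen span
stabilises on the synthetic maps; sizes are stated in each driver).
Ties resolve toward the *larger* (smoother) span, which matters for
noiseless maps where all spans fit exactly.  The span is calibrated
once per map and reused across bootstrap replicates.

**Monotone adjustment.**  Predictions are evaluated on a grid of ~1 kb
spacing capped at 4,096 points (loess is smooth at the calibrated
spans, so linear interpolation between grid points is exact far below
window resolution), clipped to [0, raw map length], and made
non-decreasing by cumulative maximum.  This implies the published
convention of clamping negative window rates to zero, and guarantees
it for every derived statistic.

**Window rates.**  rate[a,b) = (d̂(b) − d̂(a)) / ((b−a)/1e6) cM/Mb in
non-overlapping 100 kb (default) or 1 Mb windows; the terminal partial
window is retained with its actual span.  By telescoping, the
length-weighted mean window rate equals fitted map length / chromosome
length exactly — the genome-wide consistency identity asserted in the
tests — and 100 kb rates aggregated to 1 Mb rank-correlate ≥ 0.99 with
direct 1 Mb estimates on smooth synthetic batches.

**Bootstrap CIs.**  Markers are resampled with replacement, the map
refitted (same span) and window rates recomputed; per-window 95%
percentile intervals are attached to the original-fit point estimates.
Replicates with fewer than 3 distinct positions are redrawn and
counted.  Replicate smooths are evaluated directly on the window edges
(the edge sequence is itself a dense monotone grid at window
resolution), which keeps 1,000 replicates per chromosome at a few
seconds.  Percentile intervals quantify sensitivity to marker noise and
sampling, not smoothing bias; coverage of the generator truth pooled
over smooth noisy fixtures is ≥ 90% at the 95% level, but can dip in
the sharpest distal regions of an individual chromosome where the local
quadratic is biased.  Landscapes with excessive CI width can be
filtered by the user; no fixed cutoff is imposed because none is
standard.

## Landscape statistics

- **Gini**: standard Lorenz construction over window rates, windows
  weighted by length.  0 for a homogeneous landscape, (n−1)/n for a
  single recombining window.  Scale-invariant; undefined (error) for
  an all-zero landscape.
- **Relative-rate profile**: the chromosome is cut into k = 10 equal
  genomic segments; value_i = log10(genetic length of segment i /
  (total/k)).  Segments with zero genetic length are reported missing
  (NaN) rather than −∞ to keep profiles finite and plottable.
- **Periphery-bias ratio**: length-weighted mean rate within the
  terminal `tip_frac` (default 10%) regions over the chromosome mean;
  windows straddling the tip boundary contribute proportionally to
  their overlap, which makes the uniform-landscape ratio exactly 1.
  Modes: pool both tips, or sample one tip at random per chromosome
  (seeded).  A sensitivity helper recomputes the ratio over a grid of
  tip fractions (ratio → 1 as the tip grows to the whole chromosome).
- **Telomere profiles**: each chromosome is split at its midpoint and
  one side is sampled at random (window midpoints decide membership);
  relative distance to the nearest telomere (0–0.5) is divided into 20
  equal bins, windows assigned by midpoint; rates are z-scored within
  species before per-bin averaging.  Chromosomes contribute with equal
  weight regardless of length — how real pooled profiles should weight
  chromosomes is not standardised, and this is the simplest choice.
- **Pattern classification** replaces visual calls with a rule on the
  20-bin profile: *distal* when the profile peaks at relative distance
  < 0.1; *sub-distal* when it peaks in [0.1, 0.2) with the most distal
  bin below the peak; *exception* otherwise (central peaks land here).
  The thresholds mirror the verbal definitions of the two patterns.
  On generator fixtures the rule recovers the generating pattern for
  ≥ 95% of simulated species at default noise.

## Centromere/telomere allocation models

With centromeric index c (short arm / total, oriented onto the side of
the landscape's rate trough when the orientation is unknown), the three
competing allocation models predict:

| model | assumption | statistic | prediction |
|---|---|---|---|
| M1 | telomeres only | d(1/2)/d(1) | 0.5 |
| M2 | + centromere, obligate CO per arm | (d(c)−50)/(d(1)−100) | c |
| M3 | + centromere, obligate CO per chromosome | d(c)/d(1) | c |

d(1/2) and d(c) are read from the monotone fitted Marey function (not
nearest markers), consistent with the landscape estimates.  The M2
statistic is undefined when an arm carries less than its obligate
50 cM (d(1) ≤ 100 or short-arm map < 50 cM); such chromosomes are
excluded from M2's regression but retained for M1/M3, with per-model n
reported.

Each model is scored by OLS of observed on predicted across
chromosomes: adjusted R², AIC and BIC from the Gaussian residual
likelihood (k = slope, intercept, variance).  M1's prediction is a
constant, so regressing on it is degenerate; its "fit" is scored
against the fixed 0.5 line (R² = 1 − RSS₀/TSS, k = variance only) and
its p-value is a one-sample t-test of the mean against 0.5 — reported
as an interpretation, since a regression F-test does not exist for a
constant regressor.  Species-level support counts the best
within-species adjusted R² over species with ≥ 5 chromosomes.  On
synthetic datasets with per-chromosome excess coefficients, the
generating model (M2 or M3) is selected in ≥ 90% of replicate datasets;
identifiability comes from the excess varying between chromosomes,
which decorrelates the wrong model's statistic from c.

**Suppression test.**  Bootstrap replicates of the markers give the
distribution of (rate in the centromere window − chromosome mean);
suppression is significant when the 95% percentile interval lies below
zero.  Chromosomes with zero estimated centromeric rate are flagged
separately.  A wrong-side check flags centromeres whose oriented
position has a *higher* rate than its mirror (never for metacentrics,
c = 0.5).

## Gene density

Gene structures are read from GFF3 (`gene` features); splice variants
are implicit and genes with overlapping spans collapse to one record.
Counts use gene *start* positions in the same half-open windows as the
landscape, so totals are conserved.  Windows with zero genes are kept
in correlations — they carry signal.  Association is summarised by
per-chromosome Spearman rho (significance from scipy's large-sample
approximation at the two-sided 5% level), a bootstrap CI (over
chromosomes) of the mean rho, and a within-species standardized
rate-versus-count curve with a quadratic least-squares fit, pruning
windows with more than 20 genes where counts get sparse and
high-variance.  Gene-density telomere profiles reuse the crossover
profile machinery and classifier, enabling a concordance table of
gene-density versus crossover patterns.

## Genetic shuffling

r̄_intra = Σ_{i<j} r_ij / (Λ(Λ−1)/2) over Λ = 1,000 pseudo-markers
evenly spaced along the chromosome, where r_ij is the recombination
fraction between loci i and j from the reverse mapping function of the
source map: Haldane r = (1 − e^(−2d/100))/2, or Kosambi
r = tanh(2d/100)/2 (always > Haldane below saturation, both bounded by
the free-recombination optimum 0.5).  Maps with no recorded mapping
function default to Haldane with a warning.  Summation is the exact
O(Λ²) pairwise mean (~5×10⁵ pairs, milliseconds); the tests pin it to
an explicit double-loop oracle at 1e-12.

For gene distances, a position's coordinate is the cumulative number
of gene starts at or before it divided by the total; pseudo-markers
are spaced evenly in cumulative gene count (the symmetric analogue of
the genomic procedure) by interpolating bp against the step-function
cumulative count.  Homogeneity on either scale is the RMSE of the
rescaled map (both axes to [0, 1]) to the diagonal; the scale with the
lower RMSE is labelled the more homogeneous landscape.  Comparisons
are on relative scales, so the label is not an automatic consequence of
changing units.

## The synthetic generator

The generator emulates curated plant linkage-map data at the map level
(no genotype or pedigree simulation):

- **CO density** on [0, 1]: uniform; distal = plateau (0.2) + exponential
  decay from each telomere with scale 0.1 (levelling off by ~20% of the
  chromosome); sub-distal = depressed tip + gamma-shaped bump peaking
  at 0.15; central-peak = interior Gaussian bump (the documented
  exception pattern).  All are multiplied by a Gaussian centromeric dip
  1 − h·exp(−(x−c)²/2w²) (default depth 0.8, width 0.03) and
  normalized.
- **Marey truth**: arm genetic lengths follow the allocation model
  exactly — M3: d(c) = c(50 + a); M2: d(c) = 50 + a·c with total
  100 + a — and cM accumulate along the normalized cumulative density
  within each arm, so observed statistics match the model predictions
  identically at zero noise.
- **Markers**: uniform positions (terminal anchor markers at 0 and L by
  default, as in maps that pass the end-gap coverage filter), additive
  Gaussian cM noise (default 1 cM) that is deliberately *not*
  re-monotonised — the QC and fitting stages must absorb the disorder.
  Injected outliers (a configurable fraction) are displaced by 0.2–0.4
  map lengths toward the opposite half of the map (so they cannot clip
  back onto the trend at the boundaries) and their ids recorded.
- **Genes**: positions drawn from the mixture
  (1 − |γ|)·uniform + |γ|·shaped, where the shaped part is the CO
  density (γ > 0) or its floored reciprocal (γ < 0; floor 0.1× the mean
  keeps the intensity bounded in deep dips).  γ maps monotonically, not
  linearly, onto the realized rate-count correlation.
- Default sizes describe a typical mid-sized plant chromosome: 50 Mb,
  500 markers (published maps average near a thousand), ~150 cM map,
  2,000 genes.

What the generator does *not* emulate: assembly errors and inversions
(beyond isolated outliers), heterogeneous marker density along the
chromosome, gene-annotation artefacts, interference-aware CO placement,
or any phylogenetic structure between species.  Passing tests therefore
demonstrate correctness of the estimators under the stated generative
assumptions, not robustness to every pathology of real curated maps.

## Problem sizes and determinism

Analysis drivers and tests use scaled-down Monte-Carlo sizes chosen as
their study conditions: span calibration with 20–100 hold-out
partitions, bootstraps of 200 replicates, 20-chromosome batches for the
cross-scale check, 20 replicate datasets for model recovery, 100
simulated species per pattern for classifier recovery.  Library
defaults keep the reference sizes (1,000 partitions / 1,000
bootstraps / 1,000 pseudo-markers).  All randomness flows through
`numpy.random.Generator`; per-chromosome streams derive from a master
seed plus a CRC of (species, chromosome), so multi-chromosome runs are
reproducible regardless of iteration order.
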