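# Methods

## The screen model

A chemical-genomic fitness screen compares colony growth of a deletion
library on agar with a compound against growth on solvent-only control
plates. The quantitative read-out is the growth score value

GSV(s, c) = (d_treated(s) / d_untreated(s)) / (d_treated(wt) / d_untreated(wt)),

the treated/untreated colony-density ratio of a strain normalized by the
wild-type ratio on the same plate pair. The score is dimensionless and
scale-free: any global rescaling of either plate's densities (exposure,
scanner gain, incubation time) cancels, so only relative densitometry is
required. GSV = 1 is wild-type-like growth; values at or below 0.5 call a
strain sensitive and at or above 2.0 resistant, both boundaries inclusive.
Replicate trials are combined by the arithmetic mean of the defined
per-trial GSVs before classification; screens that call each trial
separately can instead use an m-of-t consensus (defaults: 2 of 2 for a
duplicate genomic screen, 3 of 4 for a focused rescreen), with ties and
insufficient evaluable trials resolved to NO_CALL. A strain whose untreated
density is zero or flagged has no defined GSV and is carried as NO_CALL
rather than silently stored; unusable wild-type densities invalidate the
whole plate pair.

Per-plate wild-type normalization uses the mean over all wild-type
positions on the plate, which damps positional noise in the reference.

### Screening-dose selection

The screening concentration is chosen so that roughly 10% of mutants retain
wild-type growth while more than 10% can still grow — the regime in which
the screen separates hypersensitive mutants without killing the library.
"Wild-type growth" and "able to grow" are operationalized as relative
growth ≥ 0.75 and ≥ 0.10 respectively; these cutoffs are package choices
(the underlying criterion is visual in practice) and are exposed as
parameters. Among concentrations passing the growth constraint the one
minimizing |fraction_wt_like − 0.10| is returned, ties to the lower dose.

## Plate densitometry

Grid location works on 1-D marginal projections of the image. Each
projection is detrended with a 10th-percentile filter (window ≈ 1.5×
expected pitch) — a low percentile tracks the background even where spot
tails cover most of the window, which a running median does not — and peaks
are called with a prominence ladder (50%, 25%, 10% of the peak scale, never
below 4× the valley noise). Peak positions are refined to subpixel accuracy
by a re-centered intensity centroid over a window just under half a pitch.
Two acceptance checks guard against spurious fits: the peak scale must
exceed 8× the noise of the inter-peak valleys (rejects blank images), and
the detected spacings must be uniform to within 15% CV (rejects the smeared
projections of a rotated plate). If the unrotated image fails, an
exhaustive small-rotation search (default ±2° in 0.5° steps) is tried;
plates skewed beyond the tolerance raise an error by construction. On
synthetic plates at default rendering parameters the detected centers land
within ~0.1 px of ground truth.

Each spot is integrated over a disk (default radius 0.35× pitch) after
subtracting the median of an annulus spanning radii (r, 1.6r); the
annulus-median background removes the smooth plate gradient locally and
makes the measurement invariant (to <1%) under a constant offset on the
whole image. Flags: SATURATED (any disk pixel at the ceiling), EDGE (the
measurement window leaves the image), EMPTY (integral below a 5σ bound on
a pure-background integral estimated from the annulus scatter, unless an
absolute threshold is configured). A dilution series collapses to the sum
of integrated densities over usable spots: summation uses the whole series
and is monotone in fitness. EMPTY spots are excluded from the sum — no
growth legitimately contributes zero — while SATURATED/CONTAMINATED/EDGE
spots are disqualified; only when every spot is disqualified is the strain
reported as missing data. Because the erf-smoothed spot edge puts a fixed
fraction of each spot's mass into the annulus, the background estimate
carries a bias proportional to the spot's own density; this cancels in any
density ratio and appears only as the single global scale factor that the
round-trip contract allows.

## Profiles, overlaps, clustering

Cross-compound overlap accounting is exact set arithmetic on the
per-compound sensitive sets; pairwise intersection counts are reported
inclusive of the higher-order intersection, the convention under which
unique counts follow as |A| − |A∩B| − |A∩C| + |A∩B∩C|. The
inclusion–exclusion identity is asserted on every summary. When only
printed marginal counts are available, the solver recovers whatever those
marginals determine (e.g. a two-compound union from one unique count) and
reports undetermined quantities as None instead of guessing.

Profile entries are log₂(max(GSV, floor)) with floor 0.05: the log makes
sensitivity (0.5 → −1) and resistance (2.0 → +1) symmetric around 0, and
the floor keeps full kills finite while staying below every realistic
score. Rows containing a NO_CALL are dropped and reported. Clustering is
agglomerative via SciPy (Euclidean distance, average linkage by default,
both configurable); determinism follows from SciPy's lowest-index
tie-break, so permuting input rows changes nothing but leaf labels. Trees
serialize to Newick; heatmaps use a red (sensitive) to blue (resistant)
diverging scale.

## Enrichment

Over-representation of a gene set of size K in a query of size n from a
universe of N, with overlap k, is scored by the upper-tail hypergeometric
probability P(X ≥ k), including the observed k — the standard convention
when the available primitive is the pmf. The tail is summed in log space
from log-gamma binomials for stability at genomic sizes; it agrees with an
exact rational enumeration to 10⁻¹² for every valid geometry with N ≤ 30
and with an independent survival-function implementation at larger sizes.
Correction is Bonferroni by default (matching the conservative behavior of
the common GO web tools), Benjamini–Hochberg by flag, with significance
reported at α = 0.05; binary gene flags (human ortholog, disease
associated, kinase, essential) are tested alongside the GMT terms in the
same correction family. The universe is a required input: whether to
condition on screened genes or the whole genome is a study decision the
package does not make.

A note on calibration: the raw p-value of any discrete test is
super-uniform, with steps on the scale of the modal pmf (~1/σ of the
overlap distribution). The null-calibration check therefore uses a
fine-grained geometry (universe 20,000, query 5,000, terms 1,000–5,000,
500 terms) where that granularity is negligible and a KS test against the
continuous uniform is meaningful; in coarse geometries (say terms of 20–200
genes against a 300-gene query) the same statistic is visibly super-uniform
— conservative, not miscalibrated.

The bubble layout places each significant term on a circle of radius
s_r·k at radial distance s_d·k (defaults s_r = 1, s_d = 4, the same linear
function of gene count up to the two scale constants), colored by corrected
p-value bin (edges 10⁻¹⁰, 10⁻⁵, 10⁻³, 10⁻², 0.05). Angles start
rank-ordered by gene count and are jittered by a deterministic pairwise
azimuthal repulsion until no circle boundaries overlap; the placement is
therefore reproducible, which matters more than aesthetics here.

## Dose response

Growth inhibition is 100·(1 − OD_treated/OD_control) relative to the
solvent-matched control, floored at 0. IC_x estimation offers:

* **interp** — linear interpolation of inhibition against
  log₁₀-concentration between the bracketing observed points (dose-response
  is conventionally log-linear near IC50); the cumulative-max envelope is
  used so noisy wiggles cannot produce multiple crossings; an exactly
  observed level returns that concentration; the zero-dose anchor, having
  no logarithm, is bridged linearly in concentration. Levels outside the
  observed span raise an extrapolation error rather than extrapolate.
* **logistic** — least-squares fit of g(c) = 1/(1 + (c/IC50)^h) (needs ≥4
  points), inverted as IC_x = IC50·(x/(100−x))^(1/h).

Both invert a noiseless generator curve to within 1% and agree within 5%
on noiseless logistic data.

## The synthetic-data generator

The generator emulates the statistical structure of a deletion-library
screen, not its biology. Measured density is base × ρ(strain, compound) ×
lognormal(1, cv) for treated plates and base × lognormal(1, cv) for
controls, with independent draws per strain, replicate and plate. Defaults:
1,000 strains, 10% sensitive with ρ uniform on [0.1, 0.4], resistant on
[2.5, 6] (bracketing the ~0.1–24 dynamic range such screens report),
multiplicative noise cv = 0.15 (replicate-to-replicate colony densitometry
scatter), 3 replicates. Noise is multiplicative lognormal because
densitometry errors scale with intensity; in the noiseless limit the whole
downstream pipeline reproduces the planted truth exactly, which is the
generator's principal test contract.

Plate images are hard disks with Gaussian edge smoothing (σ = radius/4) on
a linear background gradient with additive pixel noise, clipped at a
16-bit saturation ceiling — analytically simple shapes whose integrals are
known, chosen so the render→quantify round trip has an exact expected
answer. The generator does not model colony morphology, agar texture,
uneven pinning, or spatial plate effects beyond the smooth gradient, so
passing tests demonstrate correctness of the measurement chain, not
robustness to every real-scanner artifact.

Annotation universes draw terms uniformly from the gene universe (null
terms are then exactly hypergeometric against any fixed query); planted
terms are constructed to overlap the query by round(fold × nK/N), fold
times the null expectation. Dose-response curves come from the same
logistic form the estimator fits, plus Gaussian noise clipped at zero.

## Problem sizes

Defaults used by the test suite and the acceptance script: 1,000-strain
screens with 3 compounds and 3 replicates, 96-spot (8×12) rendered plates,
500-term annotation universes, and the full hypergeometric enumeration to
N = 30 (≈46,000 geometries). These sizes give stable statistics for every
recovery criterion while keeping a full run in the seconds-to-minutes
range on one CPU.

## Known limitations

* Sensitivity calling is purely quantitative (GSV thresholds); screens
  whose primary calls are visual, with densitometry only confirmatory, are
  approximated by the quantitative path alone.
* Grid detection assumes an approximately axis-aligned, uniformly pitched
  grid; it rejects (rather than solves) rotations beyond the configured
  tolerance and does not handle barrel distortion.
* The enrichment engine tests user-supplied flat gene sets; it does not
  parse ontology graphs or propagate annotations along them.
* IC estimation offers only the two-parameter logistic; asymmetric
  (4-parameter) dose-response shapes are out of scope.
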