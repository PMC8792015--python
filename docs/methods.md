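# Methods

## Single-molecule crosslink-EM occupancy model

A traced molecule is two ordered 2D polylines (one per DNA strand) in
pixel units; the first point of each marks the traced molecule end.
Analysis assumptions:

* Both strands span the full template, so arc length maps linearly to
  base pairs. The per-strand scale is total arc length divided by the
  template length (461 bp for the reconstituted promoter used
  throughout the defaults), and base *k* sits at arc (*k* + ½)·scale,
  interpolated linearly along the polyline. The half-offset treats the
  first and last base symmetrically and matches the 0-based half-open
  coordinate convention used package-wide.
* Strand orientation is resolved by choosing the endpoint pairing
  (start–start + end–end vs start–end + end–start) with the smaller
  summed distance. Pairings closer than a configurable margin
  (default 10⁻⁶ px) are ambiguous and the molecule is excluded.
* The per-base inter-strand distance is the Euclidean distance from the
  base point to the closest point on the opposite polyline, computed
  point-to-segment rather than point-to-vertex so that uneven tracing
  density does not inflate distances. "Reference" mode anchors bases on
  the longer-arc strand; "symmetric" mode averages the two directions
  and cancels the first-order arc-calibration shift that the two offset
  strands acquire with opposite signs on curved molecules. The pipeline
  driver defaults to symmetric for exactly that reason (a planted
  bubble at the minimal 91-bp nucleosome length can otherwise lose an
  edge base to the ~½-bp reference-mode shift and fall to 90 bp);
  reference mode remains available and cheaper. Molecules whose strand arc lengths disagree by more than
  15% (configurable) are likely tracing errors and can be screened with
  `arc_length_mismatch`.

Bubble calling: a base is single-stranded iff its distance **strictly
exceeds** a threshold; maximal single-stranded runs are bubbles; a
bubble is a nucleosome iff its length is **strictly greater than
90 bp**. Both inequalities are deliberate and unit-tested at the
boundary. Bubbles longer than 240 bp (~1.6 nucleosome footprints,
configurable) are flagged as fusion suspects but still count as one
nucleosome under the default policy; a "divide" policy
(count = ⌊length/147⌋) exists for sensitivity analysis only.

The threshold is calibrated from the pooled distance histogram by a
two-class Otsu criterion implemented directly (256 bins). Between-class
variance is exactly constant across an empty gap between two
well-separated modes, so the argmax is a plateau; the implementation
takes the plateau middle, placing the threshold mid-gap instead of
hugging one mode. A degenerate (single-mode) distribution raises an
error directing the user to supply a fixed threshold, which is also
accepted directly.

Morphological cleanup (close label gaps ≤ 2 bp, drop runs ≤ 3 bp,
both configurable, 0 = literal run-length behavior) absorbs isolated
label flips from tracing noise without moving bubble boundaries by more
than the gap size.

## Statistical layer

Counts per molecule are modeled as Poisson; λ̂ is the sample mean (the
MLE). The 95% interval on λ is a nonparametric percentile bootstrap of
the mean with 10,000 resamples (BCa available by flag). Conditions are
compared with the exact conditional test: under equal rates,
Kₐ | (Kₐ+Kᵦ) ~ Binomial(Kₐ+Kᵦ, nₐ/(nₐ+nᵦ)); the two-sided p-value
doubles the smaller tail and caps at 1 (the minimum-likelihood
two-sided convention is available by flag). Unequal molecule counts
enter through the binomial proportion. Calibration measured by the test
suite: empirical type-I error ≤ 0.06 at α = 0.05 (the test is slightly
conservative, as exact tests are), bootstrap coverage 95% ± 3% for
Poisson(1.3) at n = 150.

## Synthetic trace generator

The generator emulates spread, metal-shadowed molecules, not
micrograph pixels. Per molecule:

* The nucleosome-sized bubble count is Poisson(λ, default 1.3),
  rejection-resampled together with freshly drawn bubble lengths until
  the bubbles pack onto the template with at least `min_gap_bp` of
  duplex between them. Packing truncates the distribution: with
  ~147 ± 15 bp bubbles (normal, truncated to > 90 bp) on 461 bp at most
  3 fit, so the realized planted mean is ≈ 1.10 at λ = 1.3; the
  ground-truth table and metadata record the realized counts. Shorter
  sub-threshold bubbles (rate 0.3/molecule, 15–60 bp) are planted the
  same way.
* `min_gap_bp` defaults to 5 bp. At a 1-bp gap the rendered separation
  at the single duplex base between two bubbles sits so close to the
  label threshold that sub-base-pair calibration wobble could fuse the
  bubbles; 5 bp keeps gap bases unambiguously duplex while remaining
  far smaller than linker lengths of interest.
* The backbone is a smoothed bounded-curvature random walk (heading
  increments N(0, 0.02 rad), Gaussian-smoothed over 10 bp), rendered at
  2 px/bp. Curvature is zeroed within bubbles and their shoulders:
  on a curved backbone the two offset strands traverse different arc
  lengths through a bubble, which would bias the arc-length base
  calibration precisely where boundaries matter.
* Strands are offset ± sep(x)/2 along the backbone normal. The
  separation field is `duplex_sep_px` (2) outside bubbles and opens to
  `open_sep_px` (10) inside with a flat top and raised-cosine shoulders
  of half-width 3 bp whose 50% point sits exactly on the planted span
  boundary. Consequently, with zero coordinate noise every base inside
  a planted span is strictly above the open/duplex midpoint and every
  base outside strictly below — the property the threshold calibration
  and label tests rely on. (A plain ellipse spanning the planted span
  would fall below the midpoint over its outer ~13% and cannot satisfy
  this.) Overlapping shoulder tails of adjacent bubbles combine by
  maximum. The backbone advance is shortened inside shoulders so each
  strand keeps a uniform arc length per base pair.
* Gaussian jitter (default 0.6 px) is added per vertex; configs where
  `open_sep_px − duplex_sep_px < 2 × coord_noise_px` are rejected as
  unresolvable. The second strand's tracing direction is randomized to
  exercise orientation recovery. One RNG seeded from the config drives
  everything; outputs are bit-reproducible.

What the generator does **not** model: micrograph image formation,
psoralen chemistry or UV dose, tracing-density variation, partially
crosslinked or broken molecules, and sub-nucleosomal particles. Passing
tests therefore demonstrate the correctness of the geometric and
statistical machinery given faithful traces, not robustness to every
real-micrograph pathology; the noise and QC parameters are the knobs to
probe that robustness.

## MNase fragment layer

All intervals are 0-based half-open; TSS-relative position 0 is the
first transcribed base and positive offsets run with transcription
(minus-strand windows are reversed in genomic coordinates). Coverage
counts full fragment overlap per base (1-bp bins); a midpoint/dyad mode
is not the default since whole-fragment occupancy matches
nuclease-protection logic. Insert-size filtering keeps 120–180 bp by
default (a symmetric window around the ~150 bp mononucleosome insert).
Aggregate profiles scale each gene's window to unit mean (all-zero rows
excluded) before column averaging, so deeply covered genes do not
dominate. Fold enrichment is a deliberately simple surrogate for peak
calling: library-size-normalized IP/control fragment counts in a TSS
window with +1 pseudocounts, thresholded at 4.7-fold; it preserves the
thresholding logic without re-implementing a peak caller. Windowed
occupancy differences between samples use a gene-level bootstrap
(10,000 resamples) of the difference of mean normalized occupancy,
two-sided percentile p with add-one smoothing.

The fragment generator plants a +1 nucleosome dyad at
TSS + 110 bp (strand-aware) with Gaussian positional fuzziness
(default σ 20 bp) and ~150 ± 20 bp fragments centered on the jittered
dyad. The IP sample concentrates positioned fragments on enriched
genes (background fraction 0.1); the input sample doubles as the
enrichment control and is background-dominated (fraction 0.9) with a
weak positioned component at every gene, reflecting that a control
library samples chromatin without factor selectivity. Per-gene totals
are exact by construction.

## Binding layer

The depletion-aware quadratic model is the default because the probe
(20 nM) need not be negligible relative to Kd; the hyperbolic model is
a flag. The bound-fraction root is evaluated in the numerically stable
form 2R/(R+L+K_d+√disc) to avoid catastrophic cancellation when
R ≫ L. Kd is optimized on log₁₀ scale, bounded to
[min titrant/100, max titrant × 100], from a multistart grid of 7
initial Kd values spanning the titration; the returned optimum is never
worse than any start. Standard errors come from the pseudo-inverse of
JᵀJ at the optimum scaled by the residual SD. A fit is reported as "no
binding detected / Kd above bound" when the fitted amplitude is below
3× the residual SD (or numerically zero) or Kd exceeds 10× the top
titrant concentration — mirroring how nonbinding titrations are called
in practice rather than reporting a meaningless extrapolated constant.
A reportable fit requires ≥ 4 distinct concentrations spanning ≥ 2
orders of magnitude.

The titration generator defaults to a 3-fold, 9-point dilution series
from 30 µM plus a zero-titrant well, 20 nM probe, triplicate, Gaussian
noise of 2 mP on a 100 mP amplitude (2%).

## Numerical and design choices

* Closest-distance computation uses an exact vertex-distance prescreen:
  segments whose nearer endpoint is farther than (best vertex distance
  + longest segment) cannot contain the closest point, so the
  point-to-segment evaluation runs only on a small candidate set. This
  is an exact optimization, verified against the brute-force
  all-segments computation.
* Problem sizes in the test suite (100 simulated datasets of 150
  molecules for recovery; 500 datasets for bootstrap coverage; 2,000
  pairs for type-I error; 200 fits for Kd recovery) were chosen so
  Monte-Carlo error is small relative to the asserted margins while a
  full run stays inexpensive on a laptop; `scripts/acceptance.py` uses
  slightly smaller but statistically equivalent sizes.
* Degenerate inputs have defined behavior throughout: single-molecule
  bootstrap returns a degenerate interval with a warning; zero total
  events give p = 1 with a warning; all-equal distances refuse Otsu
  calibration; flat titrations are nonbinders, not fit failures.

## Known limitations

* The empirical distance threshold of the original tracing analysis is
  unreported; Otsu is a deterministic stand-in and a fixed threshold is
  accepted. Likewise the original insert-size bounds, heat-map
  normalization, and the test behind windowed occupancy comparisons are
  unreported; all are config-exposed with the defaults documented here.
* Reference-mode profiles on strongly curved molecules can misplace a
  bubble boundary by ~½ bp (opposite-sign shifts of the two strands);
  the symmetric pipeline default cancels this. Counts are unaffected at
  default geometry except for bubbles within 1 bp of the 90-bp rule.
* The exact conditional test conditions on total counts and so is
  slightly conservative; the bootstrap CI is percentile, not BCa, by
  default.
* Pixel-scale and spread-geometry defaults are placeholders for an
  unreported experimental geometry and should be recalibrated against
  real micrograph tracings before quantitative use on real data.
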