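# Methods

`valvemorph` re-creates, on fully synthetic data, a quantitative-taxonomy
workflow for three morphologically similar Southern Ocean *Fragilariopsis*
species (*F. ritscheri*, *F. obliquecostata*, *F. sublinearis*): morphometric
feature extraction from valve outlines and masked light-microscope images,
consensus analysis of multiexpert identifications, group statistics under the
consensus labels, and multivariate species classification. This note records
the models, the parameter choices that matter, and the limits of what the
synthetic experiments can show.

## Synthetic valves

A valve outline is generated from a half-width profile on `t in [-1, 1]`
(`t = 2x/L` along the apical axis):

    r(t) = (W/2) * [ (1 - t^2)^(1/(2 + h*t)) + B * (1 - t^2) * exp(-t^2 / (2*sigma_b^2)) ]

* `L`, `W` — valve length and width (um).
* `h >= 0` — heteropolarity dial. `h = 0` gives an exact ellipse; `h > 0`
  blunts the `+x` apex and sharpens the `-x` apex, the classic
  one-rounded-one-pointed-end asymmetry.
* `B >= 0` — central-expansion (bulge) amplitude; the `(1 - t^2)` factor
  forces `r(+-1) = 0` so contours close cleanly at the apices.
* `sigma_b` — bulge width on the `t` axis (default 0.25).

Outlines are sampled at `n_points = 60` uniform angles (`t = cos(phi)`),
counterclockwise from the `+x` apex, matching the 60-point outline exports the
pipeline ingests from segmentation software.

**Ground-truth asymmetry.** The generator reports the area asymmetry
`|A(x>0) - A(x<0)| / A` about the major-axis midpoint, computed by trapezoid
integration on >= 20,000 panels with the split point on the grid, so the
symmetric case is exactly zero. This is the oracle the polygon-clipping
heteropolarity index is verified against (they agree to < 1e-4 at 60 points).

**Striated textures.** Inside the hard-rasterized outline polygon (no
anti-aliasing, so background pixels are exactly 0) the intensity is
`128 + A*cos(2*pi*(x*cos(theta) + y*sin(theta))/p)` plus Gaussian noise,
clipped to `[1, 255]`. The period is `p = 10*pixel_scale/d` for a stria
density of `d` per 10 um (default pixel scale 9.8 px/um, a 63x oil-immersion
setup), and `theta` is the wavevector's angle off the apical axis. Defaults:
amplitude 60 gray levels, noise SD 5.

**Vote tables.** Each specimen draws a true species from the class priors;
each participant votes through their experience group's 3x3 confusion matrix,
with additional per-vote probabilities of answering "ambiguous" or giving no
identification. Defaults (8 experienced: 93% diagonal, 3% ambiguous, 3%
missing; 4 novices: 82% diagonal, 10% ambiguous, 12% missing) produce an
agreement cascade similar to the published panel: roughly a quarter to a
third of specimens unanimously labeled, experienced participants agreeing
more often than novices.

**Cohorts.** Per-species parameter distributions are truncated normals whose
length/width/stria statistics follow the published per-species summary table
(e.g. *ritscheri* length 50.7 +- 12.9 um on 20.3-93.7; *sublinearis* width
6.21 +- 0.49 um). The heteropolarity dial has no published scale, so species
means were set through the (numerically computed, approximately linear)
map from `h` to the asymmetry index — `h = 0.55, 0.24, 0.11` reproduce the
published index means of 3.9%, 1.7%, 0.8% for *ritscheri*,
*obliquecostata*, *sublinearis*. Default group sizes follow the study's
majority-vote groups (293/135/67); the analysis scripts and the acceptance
harness run a 60/40/30 scaled-down cohort so a full run stays within a few
minutes on one core.

What the generator deliberately does **not** emulate: optics (PSF, focus
stacking artifacts), poroid/fibula substructure, outline segmentation errors,
allometric coupling (parameters are drawn independently, so e.g. the
published increase of heteropolarity with valve length in *F. ritscheri* has
no synthetic counterpart — the group-wise regressions on synthetic cohorts
have slopes near zero and only exercise the machinery), and annotator
behavior beyond a per-vote confusion model (no specimen-difficulty
correlation between participants). Passing tests therefore demonstrate
correctness of the measurement and analysis chain, not performance on real
micrographs.

## Outline alignment

Heteropolar outlines make elliptic Fourier coefficients bimodal within a
group unless every valve points the same way. Alignment: (1) rotate the
principal axis of the 60 outline points (eigen-decomposition of the point
covariance) onto x; (2) translate the midpoint of the two extreme-x vertices
to the origin; (3) enforce counterclockwise traversal; (4) regress `|y|` on
`x` by ordinary least squares — a negative slope means the broader apex sits
at `-x`, in which case the outline is mirrored (`x -> -x`) and the point
order reversed to restore orientation; (5) normalize the start vertex to the
one nearest the `+x` apex. The procedure is idempotent to 1e-9 and leaves
all scalar features rigid-motion invariant.

## Elliptic Fourier descriptors

Coefficients `(a_n, b_n, c_n, d_n)` follow the classical closed-contour
formulation applied to the polyline's tangent increments. The Fourier
parameter treats the sampled vertices as **equally spaced** (uniform
parameterization) rather than traversing at constant speed. This was a
deliberate choice: with uniform parameterization an ellipse sampled at
uniform angles is represented exactly by its first harmonic with
`(a1, d1)` equal to the semi-axes, so coefficients stay interpretable in
length units and the harmonic-power calibration measures true shape
complexity. Under arc-length parameterization an elongated ellipse's
x-signal approaches a triangle wave and leaks double-digit percentages of
power into higher harmonics (a 30:4 ellipse yields `a1 ~ 24.8` instead of
30), which entangles the calibration with elongation instead of shape
detail; this also means calibrated harmonic counts are not comparable with
constant-speed implementations. `arc_length` remains available as an option.
No size or rotation normalization is applied after alignment, so
coefficients are comparable across specimens. The default 14 harmonics
(56 coefficients) matches the feature-set layout of the classification
experiments; on generated cohorts the 99.9% cumulative-power criterion is
already reached at N = 1 because of the uniform parameterization and the
smoothness of the synthetic outlines.

## Scalar shape features

* **Heteropolarity index**: the valve is split along the minor-axis direction
  of its best-fitting ellipse and the index is
  `|A1 - A2| / (A1 + A2)` via exact polygon clipping (shapely). The split
  line is placed at the **midpoint of the major axis** — i.e. the center of
  the best-fitting ellipse constrained to share the valve's apical extent,
  the same center used by the alignment. The unconstrained moment-equivalent
  ellipse is centered on the area centroid instead; for the generator's
  profile family the centroid split is area-balanced to ~1e-4 for *every*
  `h` (mean and median of the width profile nearly coincide), which would
  make the index blind to the asymmetry it is meant to measure and
  incompatible with the percent-scale values reported for real valves. The
  midpoint split restores a monotone `h -> index` response (0.7%-5.9% for
  `h` in 0.1-0.8).
* **Eccentricity of the broadest position**: width profile `w(x)` sampled at
  512 equally spaced apical positions by linear interpolation of contour
  crossings; the result is `(x_apex - argmax w) / L` measured from the
  broader (`+x`) apex, ties resolved toward the valve center. 0.5 means the
  broadest point is mid-valve.
* **Convexity indices** (against the shapely convex hull):
  `convexity_by_perimeter = hull perimeter / outline perimeter`;
  `convexity_by_area = outline area / hull area`;
  `PCAF = (hull area - outline area) / hull area * 100`;
  `CHMDF = max vertex-to-hull distance / L`;
  `CDF = mean vertex-to-hull distance / L`. The originating segmentation
  software does not publish closed formulas for these five names; the
  definitions above are fixed here, unit-tested against hand-constructed
  notched polygons, and reproduce the expected qualitative behavior (all
  extreme for convex outlines, monotone in notch depth).
* **Heuristic descriptors**: `rectangularity = area/(L*W)`;
  `form_factor = 4*pi*area/perimeter^2`; `compactness` its reciprocal;
  `roundness = 4*area/(pi*L^2)`; ellipticity and triangularity from the
  affine moment invariant `I1 = (mu20*mu02 - mu11^2)/mu00^4` with the
  standard piecewise normalization peaking at 1 for the ideal ellipse
  (`I1 = 1/(16*pi^2)`) and triangle (`I1 = 1/108`), computed from exact
  polygon moments.

Degenerate outlines (collinear, zero area, fewer than 3 points) degrade to
missing values in batch extraction, with a logged warning, never to a crash.

## Stria texture

**Density.** The masked image is binarized by an adaptive local-mean
threshold computed **over foreground pixels only** (a pair of uniform
filters), window 41 px — about twice the largest plausible stria period at
9.8 px/um. Restricting the mean to the foreground matters: with the zero
background included, windows overlapping the valve margin have depressed
means, which fattens and fragments the detected virga runs and can push the
spectral peak to the duty-cycle harmonic. The central 80% of a line along
the apical axis (nearest-neighbor sampling through the foreground centroid)
is scanned for runs; run centers become 5-px-wide marks in a 1-D artificial
signal, smoothed with the binomial kernel (1,4,6,4,1)/16, Hann-tapered
(otherwise spectral leakage from a non-integer cycle count can favor the
second harmonic of the pulse train), and transformed by a forward DFT. The
peak of the magnitude spectrum, searched over periods in [3 px, span/2],
gives the mean virga distance; density is `10 * pixel_scale / distance`.
An estimate is accepted only if the peak exceeds 3x the median spectrum
magnitude — an objective surrogate for the study's manual accept/reject
overlay check, for which `density_overlay_positions` still provides the
dot positions (spaced one mean distance apart over the analyzed span,
half-open, so a 240-px span at 15 px spacing gives 16 dots).

**Orientation.** The image is rotated so the apical axis is vertical
(nearest-neighbor, canvas enlarged so nothing is clipped) and an even
(cosine-phase) Gabor kernel with wavelength fixed to the measured mean
stria distance (envelope sigma = 0.5 wavelength, aspect ratio 1) is swept
over [-45 deg, 45 deg] by bounded scalar optimization from 5 equispaced
starts. The objective integrates the squared response over the central 80%
of the apical extent — the middle portion of the valve face, away from the
curved apices whose boundary response would otherwise bias the shallow
objective by about a degree. The result is reported as |theta|, degrees
off the transapical axis.

**Obliquity correction.** The apical-axis line crosses striae inclined by
theta at spacing `p / cos(theta)`, so the pipeline rescales accepted
densities by `cos(theta_hat)` once the orientation is known (< 2% below 10
degrees). Verified recovery on synthetic images across the study's density
range (4.7-10.4 per 10 um), |theta| <= 20 deg, noise SD <= 15: density
within 5%, orientation within 1 deg (worst case ~0.3 deg).

## Consensus analytics

Per specimen, votes are counted over the five non-missing categories; the
majority label is the unique maximum, with ties recorded and mapped to
"ambiguous"; percent agreement is the top count over all non-empty votes.
Documented conventions (configurable where noted in the API):

* "Complete agreement" requires all non-empty votes to be the same single
  *species* label; unanimous "ambiguous" does not count as agreement.
* The k-dissenter cascade counts specimens whose non-empty votes deviate
  from a species majority label in at most k participants; tied or
  ambiguous-majority specimens can never satisfy it. Counts are therefore
  non-decreasing in k and k = 0 equals complete agreement.
* Pairwise similarity is the fraction of identical votes among specimens
  where both participants gave non-empty, non-ambiguous votes;
  out-of-group counts as an identification.
* Ternary coordinates renormalize over the three species votes only and
  embed them in an equilateral triangle with unit heights, so the distance
  from each tip's opposite edge equals that species' vote fraction.
* Length-window agreement tiles the observed length range in 10-um windows
  and reports, per window, the fraction of specimens with >= 90% agreement;
  empty windows carry n = 0 and a missing fraction.

## Group statistics and classification

Summaries (n, min, max, mean, SD) are produced at three labeling
stringencies: unequivocal (percent agreement 1.0 for a species), majority
(species majority label), and single-vote (any participant voted the
species; specimens may then enter several groups). Missing feature values
are handled by complete-case analysis per feature, so stria-orientation n
can be smaller than the group size. ANOVA is a one-way fixed-effects linear
model (dummy-coded groups) with coefficient p-values from the model summary;
it is verified against a hand sums-of-squares oracle to 1e-10 and its
type-I error calibration against simulation. ANCOVA adds valve length and a
group-by-length interaction and also reports per-group simple regression
lines. No multiple-testing correction is applied by default, matching the
original analysis design.

Classification uses majority-vote species labels (ambiguous/tied specimens
excluded) on three feature sets: 19 scalar morphometrics ("non-EFD" — the
enumerated variable list names 18; the heteropolarity index is included as
the 19th, which is the documented reading of the published variable count),
56 EFD coefficients, and their union (75). Algorithm settings mirror the R
packages the experiments were specified with: Gaussian naive Bayes; LDA;
QDA (reported not-applicable with a singular-covariance reason whenever a
class has no more cases than variables — the published experiments hit the
same wall on the combined set); SVM with RBF kernel, cost 1, kernel width
1/p, on standardized variables; random forest with 500 trees and sqrt(p)
candidate variables per split. Cross-validation redraws an unstratified
10-fold partition per replicate (stratification available by flag) and
reports the pooled test misclassification percentage with mean and range
over replicates; partitions that would starve a discriminant classifier of
a class are redrawn.

## Numerical choices and degenerate inputs

* All randomness flows through explicitly seeded `numpy` generators; no
  global state. Cohorts, images, vote tables, CV partitions, and forests are
  byte-identical under a fixed seed.
* Eccentricity sampling (512 positions), the adaptive-threshold window
  (41 px), the spectral-prominence threshold (3x median), the Gabor envelope
  factor (0.5) and multistart count (5) are all keyword-configurable with
  the defaults above.
* Zero between-group sum of squares returns F = 0 (not 0/0) so zero-noise
  fixtures behave as expected.
* Degenerate outlines raise typed errors in single-specimen calls and become
  missing rows in batch calls; texture estimation on featureless foregrounds
  returns an unaccepted estimate rather than a number.

## Known limitations

* The synthetic cohort's group separations are inherited from the published
  summary table, not from real outlines; classifier error rates on it are
  indicative of the machinery only.
* The convexity-index and ellipticity/triangularity formulas are documented
  reconstructions of names used in the source software, not verified
  re-implementations of it.
* The uniform EFD parameterization is not numerically interchangeable with
  constant-speed coefficients; use `parameterization="arc_length"` for
  comparisons with arc-length-based implementations.
* Stria density on strongly oblique patterns (> ~20 deg) depends on the
  obliquity correction and degrades with it.
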