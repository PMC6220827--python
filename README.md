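# valvemorph

Quantitative taxonomy for look-alike pennate diatoms: morphometric feature
extraction from valve outlines and masked light-microscope images,
multiexpert vote consensus analytics, group statistics, and species
classification — with a synthetic-data generator so the whole analysis runs
and is testable without microscope slides.

## The problem

Three Southern Ocean *Fragilariopsis* species — *F. ritscheri*,
*F. obliquecostata*, and *F. sublinearis* — are separated in the light
microscope almost entirely by gradual characters: valve size and aspect
ratio, heteropolarity (one rounded and one pointed apex), a central
expansion of the outline, and the density and obliquity of the striae. Even
experienced diatomists disagree on many specimens. This package implements
the analysis chain that turns those verbally communicated characters into
numbers, reconciles a panel of expert identifications into a majority-vote
gold standard, and asks how well statistical classifiers reproduce the
panel's consensus — for users doing diatom morphometrics, inter-annotator
studies, or classifier benchmarking on microscopy data.

## What it computes

* **Outline morphometrics** (`valvemorph.outline`): heteropolarity-aware
  alignment (principal axis to x, flip so the broader apex — positive OLS
  slope of |y| on x — sits at +x); elliptic Fourier descriptors
  (a_n, b_n, c_n, d_n) with harmonic-power calibration; length, width, area,
  perimeter, aspect ratio L/W; heteropolarity index
  |A₁ − A₂| / (A₁ + A₂) from an exact polygon split on the transapical
  axis; eccentricity of the broadest position (x_apex − argmax w(x)) / L;
  five convexity-defect indices against the convex hull; rectangularity,
  compactness, ellipticity, triangularity, roundness, form factor
  4πA/P².
* **Stria texture** (`valvemorph.texture`): stria density per 10 μm from the
  Fourier spectrum of virga positions along the apical axis (adaptive
  threshold → run centers → 5-px marks → binomial smoothing → DFT peak),
  with an objective spectral-prominence accept/reject; stria orientation
  (degrees off the transapical axis) by maximizing an even Gabor filter's
  integrated squared response over the valve face.
* **Consensus analytics** (`valvemorph.consensus`): per-specimen majority
  votes with tie handling, percent agreement, agreement cascades allowing
  k dissenters, experienced-vs-novice splits, pairwise annotator similarity,
  ternary vote coordinates, agreement by valve-length window.
* **Statistics & classification** (`valvemorph.stats`, `valvemorph.classify`):
  per-species summaries at three labeling stringencies; one-way ANOVA and
  length-ANCOVA per feature; naive Bayes / LDA / QDA / SVM / random-forest
  experiments on three feature sets (19 scalar morphometrics, 56 EFD
  coefficients, both) by resubstitution and replicated 10-fold
  cross-validation.
* **Synthetic cohorts** (`valvemorph.synthetic`): valve outlines with
  controllable length, width, heteropolarity and central expansion;
  striated masked images with known period and orientation; simulated
  expert panels with per-experience-group confusion. Ground truth rides
  along, so every estimator is checked by parameter recovery.

## Worked example

```python
from valvemorph.synthetic import SyntheticValveParams, StriaTextureParams, \
    generate_outline, generate_striated_image
from valvemorph.outline import heteropolarity_index, basic_measures
from valvemorph.texture import estimate_stria_features

valve = SyntheticValveParams(length=60, width=8, h=0.55, bulge=0.02)
outline, truth = generate_outline(valve, "demo")
print(f"HI = {heteropolarity_index(outline):.4f}  (ground truth {truth['heteropolarity_index']:.4f})")
print(f"aspect ratio = {basic_measures(outline)['aspect_ratio']:.2f}")

texture = StriaTextureParams(density=7.4, theta_deg=4.0, noise_sd=10.0)
image, _ = generate_striated_image(valve, texture, seed=1)
density, orientation = estimate_stria_features(image)
print(f"stria density = {density.density:.2f} per 10 um, orientation = {orientation.theta:.2f} deg")
```

prints

```
HI = 0.0394  (ground truth 0.0394)
aspect ratio = 7.35
stria density = 7.33 per 10 um, orientation = 3.99 deg
```

i.e. a strongly heteropolar valve (index 3.9%, the scale typical of
*F. ritscheri*), whose simulated striation (7.4 striae per 10 μm inclined 4°
to the transapical axis) is recovered to within about a percent and a
fraction of a degree.

The full analysis is laid out as numbered drivers:

```bash
python analysis/01_simulate.py --seed 0        # cohort: outlines, images, votes
python analysis/02_outline_features.py         # alignment, EFDs, shape indices
python analysis/03_texture_features.py         # stria density + orientation
python analysis/04_consensus.py                # majority votes, agreement, similarity
python analysis/05_group_stats.py              # Table-style summaries, ANOVA/ANCOVA
python analysis/06_classification.py --seed 0  # 3 feature sets x 5 algorithms
python analysis/07_parameter_recovery.py       # bias/RMSE vs generator truth
```

Each writes its tables under `results/` and prints a one-line summary of
what it found. The same stages are available as a console tool
(`valvemorph simulate|features|consensus|stats|classify|run|study`).

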