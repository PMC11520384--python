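# Methods

This document records the modeling choices, parameter defaults, and numerical
conventions of the `hsistress` package. The pipeline reimplements the analysis
of a greenhouse hyperspectral study of soybean and coleus under two-spotted
spider-mite stress; because that study's imagery is not publicly deposited,
the package pairs the analysis code with a synthetic scene generator that
emulates the study's design and lets every stage be validated end to end.

## Band axis and cube format

- Wavelength axis: 150 evenly spaced band centers from 380 to 1,015 nm
  (spacing 635/149 ≈ 4.2617 nm, the study's nominal "4.2 nm" resolution).
- Cubes are stored as ENVI: a text `.hdr` plus a raw little-endian float32
  binary. Writing uses BIP interleave; reading accepts BIP, BIL and BSQ.
- Scene metadata (species, treatment, day index, session, replicate, seed,
  white-panel region) is written as extra key-value entries in the `.hdr`,
  so one file pair fully describes an acquisition.
- Coordinates are 0-based, row-major; rectangles are half-open
  `(row0, row1, col0, col1)`.
- Wavelengths are serialized with `repr`, so a write→read roundtrip is
  bit-exact for both data and axis.

## Study design

Per species: 7 acquisition days (elapsed days 0, 7, 8, 9, 14, 15, 16) × 2
sessions (noon, midnight) × 3 treatment groups (control, low, high mite
density) × 8 replicate plants = 336 scene combinations. Day 0 precedes
infestation; all day-0 scenes carry the treatment label `baseline`, which is
the fourth classification class. Post-infestation days are grouped into
period 1 (days 7–9) and period 2 (days 14–16).

## Synthetic scene generator

A scene is a background, a white reference panel (reflectance 0.99), and an
elliptical plant whose pixel spectra follow a multiplicative effect chain:

```
pixel = endmember × diurnal^[midnight] × stress(treatment, session)
        × aging(elapsed days) × plant_factor × pixel noise
```

- **Endmembers** are parametric (sums of Gaussian bumps and sigmoid edges):
  a green-leaf soybean profile (green peak at 550 nm, red absorption dip near
  668 nm, sharp red edge at 720 nm, NIR plateau, 970 nm water dip) and an
  anthocyanin-rich coleus profile with elevated red reflectance.
- **Diurnal effect**: per-band multiplicative ratio applied at midnight,
  defined piecewise over wavelength windows (noon = 1). Soybean midnight
  reflectance drops a few percent in the visible and rises slightly in the
  NIR; coleus differs in sign pattern.
- **Stress effect**: per-band ratios for low and high infestation; control
  and baseline are 1. The low ratio is the high ratio raised to the power
  0.4 (an intermediate effect), and at midnight the log-effect is amplified
  by a factor of 1.5 (`midnight_gain`), which is what makes midnight
  classification easier — as reported in the original study.
- **Aging effect**: per-band maturation drift reaching `ratio_final` at day
  16, geometric in elapsed days (exactly 1 at day 0). This is a deliberate
  design addition: without it the baseline class is statistically identical
  to later controls, whereas the study classifies baseline at 0.97–1.00
  accuracy. Defaults: windows (380–500: 0.92, 500–600: 0.95, 600–700: 0.82,
  730–1,015: 1.12).
- **Growth**: the plant-mask area grows geometrically over the schedule
  (soybean ≈ 4-fold, coleus ≈ 3-fold; initial area 3% of the scene).
- **Noise model** (all Gaussian, all scaled by a master `scale`; `scale=0`
  is exactly deterministic): per-pixel per-band reflectance noise
  (sd 0.02), per-pixel brightness spread (sd 0.10), a per-plant biological
  factor (sd 0.02) held constant across that plant's acquisitions, a
  per-scene illumination jitter (sd 0.01), and white-panel pixel noise
  (sd 0.002).
- Scenes can be emitted as raw sensor counts under a halogen-like
  illumination gain (1,500–4,000 counts per unit reflectance, rising toward
  the NIR), which exercises the calibration stage downstream.
- Seeding: every scene's seed derives from the plan seed via
  `numpy.random.SeedSequence` over the design coordinates, so studies are
  bit-reproducible and individual scenes are independently reproducible.

What the generator does **not** emulate: push-broom scanning geometry and
keystone/smile artifacts, leaf-level spatial structure (veins, specularity),
mite population dynamics, water stress, or absolute radiometric units. It is
a statistical emulation sufficient to exercise the pipeline, not a physical
plant model — absolute accuracies from the original tables are therefore not
reproduction targets; qualitative trends are.

## Preprocessing

- **Calibration**: one-point empirical line method. Per band, gain =
  panel_reflectance / mean panel counts; applied to the whole cube. Scale
  invariant by construction; a zero-mean panel band raises an error naming
  the band. Calibrated reflectance is clamped at 0 below; values above 1 are
  allowed (specular/noise) and flagged above 1.5.
- **Green filtering**: NDVI-style, (NIR − red)/(NIR + red) ≥ `ndvi_min` with
  red = 660–680 nm and NIR = 780–800 nm window means, plus a NIR brightness
  floor (0.15). Soybean default `ndvi_min` 0.5; coleus 0.2 (reddish leaves
  depress red/NIR contrast). The panel region is always excluded.
- **Spatial binning**: k×k tiles anchored at the mask bounding-box origin;
  a tile yields one observation (the mean spectrum of its masked pixels) if
  at least ⌈k²/2⌉ of its pixels are masked. k = 1 is per-pixel identity;
  k = 5/7/9 give the study's 25/49/81-fold data reduction.

## Repeatability and band testing

- **Eq. 1**: per band, repeatability = 100 − (max − min) × 100 / mean over a
  set of acquisition profiles. ≤ 100 always, 100 iff zero range, unbounded
  below; zero-mean bands are NaN and flagged. Worked examples: reflectances
  {0.50, 0.55} → 90.476; {0.05, 0.55} → −66.67.
- **Profiles**: per acquisition (or pooled across replicates), the mean
  spectrum of a seeded random sample of up to 1,200 masked pixels, matching
  the study's "1,200 random pixels per combination".
- **Paired t-tests**: per band, two-sided `scipy.stats.ttest_rel` over
  matched acquisition pairs (e.g. midnight vs noon of the same 7 days →
  df = 6). No multiple-testing correction by default, mirroring the study's
  presentation; a Benjamini–Hochberg option exists but is off by default.
  Zero-variance bands are flagged undefined and never significant.

## Classification

- Balanced sampling: exactly `n` observations per class, seeded, without
  replacement; a short pool raises an error naming the class and deficit.
  Defaults per binning level: 1,200 (k=1), 1,200 (k=5), 600 (k=7), 375 (k=9).
- Classifier: `sklearn.svm.SVC(kernel="linear")` (default C, one-vs-one)
  under seeded `StratifiedKFold` cross-validation (k = 10). K-1 = mean
  held-out accuracy × 100; per-class accuracy = recall from the pooled
  held-out confusion matrix.
- Cohen's kappa is implemented by hand from the confusion matrix
  ((p_o − p_e)/(1 − p_e)); an explicit brute-force double loop and
  `sklearn.metrics.cohen_kappa_score` serve as independent test oracles.

## Experiment grid and summaries

- The grid: 2 species × 2 periods × 2 sessions × 4 binning levels = 32
  configurations. Each pools the period's scenes plus the day-0 baseline
  pool, balanced-samples, and scores by CV.
- Session summaries average the 8 per-session rows per column and compare
  sessions by one-way ANOVA (two groups, so F = t²), printing letters a/b.
- Rounding follows the printed tables: decimal half-up at 2 decimals (via
  `Decimal`, after pre-rounding to 8 decimals so binary float artifacts do
  not flip ties). This is required to reproduce e.g. the coleus midnight K-1
  mean 63.235 → 63.24.
- Known printed-value caveat: averaging the published per-row values
  reproduces every summary Kappa and K-1 exactly, but two per-class cells
  differ by one unit in the second decimal (the original summaries were
  computed from unrounded scores). Tests assert exact Kappa/K-1 equality and
  a one-ULP tolerance elsewhere.

## Problem sizes

Full-scale runs (120×120 scenes, 8 replicates, 336 scenes/species) are
supported but slow on one CPU; the test and acceptance suites use reduced
sizes chosen by this package (60×60 scenes, 2 replicates, 4 days, binning
levels 1 and 5, 120/20 observations per class) that preserve the qualitative
trends — low-class hardest, midnight ≥ noon kappa — while running in seconds
per seed.

## Limitations

- Synthetic-only validation: absolute agreement with the original tables is
  out of reach without the original imagery; published values are used as
  aggregation inputs and oracle targets instead.
- Linear SVM with default C only, as in the study; no hyperparameter search.
- The green filter is a simple NDVI threshold, not a learned segmentation.
- One-point ELM assumes a spectrally flat, unsaturated panel and spatially
  uniform illumination.
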