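# Methods

This note documents the models and numerical choices behind `chemurin`, the
assumptions they rest on, and what the synthetic-data tests do and do not
demonstrate.

## Spectral model and pre-processing

A Raman spectrum is treated as point samples of intensity on a strictly
increasing wavenumber grid (cm⁻¹); no bin semantics, no instrument response
model. Replicate scans of one urine sample are averaged pointwise before any
modelling, so each sample enters the statistics exactly once. The working
window is 400–1,800 cm⁻¹ (closed interval); acquisition outside it is
discarded. Grids are harmonized by linear interpolation only — spectra are
densely sampled relative to the ~8 cm⁻¹ optical resolution, so any
higher-order scheme would add assumptions without information — and
extrapolation is never performed: a target grid outside a spectrum's native
coverage is an error.

### ISREA baselining

The baseline is a cubic spline anchored at a small ordered set of
wavenumber *nodes* (2–8, first and last pinned to the window bounds).
The iteration is:

1. initialize each anchor at the spectrum's intensity at its node
   wavenumber (linear interpolation when a node falls between grid points);
2. fit a cubic interpolating spline through the anchors and evaluate it on
   the grid;
3. in every inter-node segment where the spline exceeds the signal by more
   than `tolerance × max|intensity|`, lower the two bounding anchors by that
   segment's worst overshoot (an interior anchor shared by two violating
   segments is lowered by the larger one);
4. repeat until no segment violates, or fail after `max_iterations` with
   the last iterate attached to the error.

Defaults: `tolerance = 1e-4` (relative), `max_iterations = 100`; both
overridable in `PreprocessConfig`. Corrected intensities may be negative —
clipping would destroy the pipeline's scale-invariance. Adding a constant
offset to a spectrum shifts the baseline by the same constant and leaves
the corrected signal unchanged.

Boundary conditions: the spline uses **not-a-knot** ends (the scipy
default), not natural ends. A natural spline forces zero second derivative
at the window edges and therefore cannot reproduce a generic cubic
background; not-a-knot reproduces polynomials up to cubic exactly, which is
the behaviour a baseline estimator should have and the property the test
suite asserts. With two nodes the "spline" degrades to a straight line.

Two consequences worth knowing: (i) the corrected signal is exactly zero at
the nodes only while the anchors remain on the spectrum; wherever the
initial spline genuinely overshoots (e.g. a background curvature the node
set cannot represent), the lowered anchors leave a small positive residual
at those nodes of the order of the overshoot. (ii) node *placement* is part
of the analysis design — the package ships the study's node presets
(`fig1`, `analysis1`, `analysis2`, `dkd`, `imn`, `mn`, `rn`) but performs no
automatic node optimization.

After baselining each spectrum is scaled to unit Euclidean norm, which
removes overall intensity (laser power, collection efficiency) as a factor;
consequently only *relative* band intensities are informative, and a class
effect confined to a single band with no reference band is attenuated by
normalization.

## PCA, MANOVA, DAPC

PCA (full SVD via scikit-learn, mean-centred) consolidates the grid into
orthonormal components; the retained count is the smallest k whose
cumulative explained-variance fraction reaches the retention target
(default 0.99, exposed as a parameter). Inside model fitting the count is
additionally capped at `n − g − 1` (n samples, g classes) so the
within-class scatter stays invertible on noise-dominated data; without the
cap a null cohort can retain nearly n − 1 components and make the
discriminant eigenproblem singular.

MANOVA is descriptive output: Wilks' Λ = det(W)/det(T) on the retained
scores, with the classical Bartlett chi-square sequence estimating the
number of significant separation dimensions. It never gates an analysis.

DAPC solves the canonical eigenproblem with the symmetrized whitening
`(W/(n−1))^(−1/2) (B/(n−1)) (W/(n−1))^(−1/2)` (numerically preferable to the
non-symmetric `W⁻¹B`), orders axes by decreasing eigenvalue, and keeps
**all** of them: with two classes only one axis carries between-class
separation (trailing eigenvalues ≈ 0 up to round-off), but retaining the
full rotation keeps the canonical geometry well-defined and reproducible.
Classification is nearest-centroid by Euclidean distance in canonical
space — under the whitening this equals a Mahalanobis rule with the pooled
within-class covariance — with ties broken to the earlier label in the
model's class order (order of first appearance in the training labels).
Every PC and canonical axis is sign-fixed so its largest-magnitude element
is positive, making loadings platform-reproducible. Models serialize to
versioned JSON with `repr`-exact floats, so a round trip is bit-exact.

## Validation and screening

Leave-one-out cross-validation refits *both* PCA and DAPC on each fold;
pre-processing is strictly per-sample, so preprocessed rows are reused
across folds without information leakage. Every class needs ≥ 2 samples or
the orphaned class is named in the error.

Metric panels report accuracy, sensitivity, specificity, PPV and NPV as
percentages rounded to one decimal, half away from zero (36.36 → 36.4).
Zero-denominator ratios are reported as NA, never coerced. The
random-chance bracket for a binary screen is `50% [100·n₊/n, 100·n₋/n]` —
the accuracies of the constant all-positive and all-negative classifiers;
the two bounds sum to exactly 100 before rounding.

Screen definitions are unions of manifest class labels for the positive and
negative sides plus an explicit exclusion list; samples in no referenced
class are excluded and counted, so evaluated + excluded always equals the
manifest size. The shipped presets mirror the study's analyses over the
census manifest, including the exclusion of the single dual-pathology
DKD+IMN sample wherever it can be neither cleanly positive nor negative
(it *is* counted positive in the diabetic-IMN screen). The census uses
disjoint atomic labels (DKD/NO 9, DKD/OV 2, DKD/IMN 1, DKD/OT 3, IMN/DM± 5+6,
MN 6, RN 3, OT 4, PATH 9, DM+ 161, DM− 65, HEALTHY 25, SURINE 22); with the
preset group rules these reproduce the reported evaluated-set sizes
22, 150, 181, 134, 18 and 20. The census rows cannot simultaneously satisfy
every printed subtotal of the source tables (which double-count overlap
samples); where forced to choose, the screen denominators won. There is no
score-threshold tuning: the screening boundary is the nearest-centroid
boundary, and the only sensitivity/specificity dial is the PCA retention
target.

## Synthetic cohorts

`simulate_cohort` draws, per sample: one lognormal concentration factor per
molecular band group (glucose, urea, protein, nucleic acids, ...; CV 10 %
by default — a metabolite's concentration scales all of its bands
together), Gaussian band profiles at the annotated band centres on a
400–1,800 cm⁻¹ grid at 2 cm⁻¹ spacing, and a smooth background (cubic drift
plus a broad fluorescence hump at 1,200 cm⁻¹, coefficients jittered 15 %
per sample). Replicates add i.i.d. homoscedastic Gaussian noise
(sd 0.5 detector units against band amplitudes of 5–30); ten replicates per
sample by default. The SURINE control class uses the same generator with
all variabilities quartered, making it the quietest class by construction.
Class effects are multiplicative on band-group amplitudes; `effect_size`
scales every multiplier's deviation from 1, with `effect_size = 1`
corresponding to the calibrated condition of ~2× glucose/urea shifts
between the DKD-like and IMN-like signatures against the 10 % within-class
CV, and `effect_size = 0` producing exchangeable classes. All randomness
flows from one seed through per-sample, per-replicate `SeedSequence`
substreams, so cohorts are bitwise reproducible and individual samples are
reproducible in isolation.

What the generator does **not** emulate: Lorentzian/Voigt line shapes,
heteroscedastic or correlated detector noise, cosmic-ray spikes, wavelength
miscalibration, day effects, or any physiological covariance between
metabolites beyond the per-group concentration draws. Passing tests
therefore demonstrate that the pipeline recovers effects of the assumed
form at the study's sample sizes — not that real urine cohorts separate.

## Problem sizes and tolerances in the test suite

Tests run the 22-sample two-class cohort at full study conditions
(10 replicates, 701 grid points). The rare-positive screen test
(11 positives / 139 negatives) thins to 2 replicates and an 8 cm⁻¹ grid,
and the permutation-null test uses 40 samples × 71 grid points with 30
label permutations — sizes chosen so the distributional assertions (mean
accuracy within 5 points of chance; sensitivity ≥ 80 %, specificity ≥ 95 %
under a strong effect) are stable while the whole suite stays fast.
Numerical tolerances follow the contracts: 1e-9 for I/O round trips and
centroid algebra, 1e-12 for normalization idempotence, the relative ISREA
tolerance (1e-4) for baseline convergence, and the one-decimal reporting
convention for all percentage comparisons.

## Known limitations

* ISREA's published update rule is not fully specified in the secondary
  literature; the anchor-lowering contract above is this package's fixed,
  tested interpretation.
* The nearest-centroid assignment rule and the per-fold PCA refit are
  design choices the original platform leaves unstated; both are recorded
  here as this package's contract.
* With two classes the informative canonical subspace is one-dimensional;
  the retained trailing axes are geometry, not signal.
* The chance bracket assumes a binary screen; the multiclass report uses
  exact-match accuracy and one-vs-rest panels, with no reject/"uncertain"
  option.
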