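# Methods

This note documents the models, numerical choices and limitations behind
`evraman`, in the order the pipeline runs them.

## Data model

A spectrum is a strictly increasing wavenumber axis (cm⁻¹) with one
intensity per point and metadata (sample id, class, donor, optional map
position). All multivariate work happens on a `SpectralDataset`: n spectra
linearly interpolated onto one common per-window grid, the two spectral
windows (fingerprint 500–1800 cm⁻¹ and CH-stretch 2600–3200 cm⁻¹ by
default, closed intervals) concatenated into a single feature vector. Both
windows are analysed jointly because the discriminating chemistry lives in
both: protein/nucleic-acid structure in the fingerprint, lipid CH stretches
in the high-wavenumber region. The default grid step is 1 cm⁻¹ — finer than
the effective sampling of a 1800 gr/mm spectrograph, so interpolation loses
nothing — and is configurable; every spectrum must cover each window within
one grid step at the edges. Long-format tables are written with 17
significant digits and read back with round-trip float parsing, so a
dataset survives a write/read cycle bit-for-bit.

## Baseline removal

Autofluorescence is modelled as a polynomial of order 6 per window
(`poly_order`, ≥ 0). The default estimator is the iterative *modified
polyfit* (modpoly): fit the polynomial by least squares, replace every
intensity lying above the fit by the fit, refit, and stop when the working
curve's relative change drops below `rel_tol` (1e-6) or after `max_iter`
(100) rounds. The iteration converges to a lower-envelope polynomial that
passes under the Raman bands; a single unmasked fit biases band heights
downward because the polynomial is pulled up through the peaks.
`BaselineConfig(iterative=False)` provides that single-pass fit for
comparison with software that uses it. Non-convergence within `max_iter` is
flagged on the result, not raised: the partially converged envelope is
still a usable baseline, and on noisy spectra the last iterations move it
by amounts far below the noise floor. Fits use a QR-factorised Vandermonde
basis on the axis rescaled to [−1, 1], shared across all spectra of a
dataset, which keeps the order-6 problem well conditioned and makes
whole-cohort correction a handful of matrix products. The corrected
spectrum is computed by subtraction, so corrected + baseline reproduces the
input exactly. Because the projection is linear and clipping commutes with
subtracting a polynomial, a constant (or any polynomial) offset added to
the input leaves the corrected spectrum unchanged, and an already-corrected
spectrum is a fixed point of the procedure — both are enforced in tests.

## Normalisation and alignment

Spectra are scaled to unit Euclidean norm (unit-vector normalisation);
all-zero spectra are an error. Post-acquisition calibration drift is then
compensated by a rigid wavenumber shift: a grid search over
[−`max_shift`, +`max_shift`] (default ±5 cm⁻¹) at 0.1 cm⁻¹ resolution
maximises the Pearson correlation with a reference, evaluated in a ±20 cm⁻¹
window around the 1003 cm⁻¹ phenylalanine ring-breathing band — a sharp
feature present in essentially all biological specimens. The narrow anchor
matters: with a wide correlation window, genuine between-class band
differences (not drift) can pull shifts of over 1 cm⁻¹ on data that have no
drift at all. When the anchor region is absent the full overlap is used.
The cohort reference is the per-channel median spectrum — robust and
parameter-free, since no instrument standard is available post hoc. Ties
resolve to the smaller |shift|; an optimum at the search boundary is
applied but flagged, since the true drift may exceed the window.

Pipeline order is crop → baseline → normalise → align (normalisation
precedes calibration). For file inputs whose spectra arrive on differing
native axes, resampling to the common grid happens before alignment,
because the median reference is only defined on a shared grid; for
generator data, which are born on the grid, the order is exactly as above.

## Map background filtering

Mapped acquisitions over an air-dried drop include substrate-only points.
Preprocessed map spectra are clustered agglomeratively (Ward linkage,
Euclidean metric — the chemometrics default for normalised spectra;
`average` and `complete` are available) and cut at two clusters. The
cluster with the higher mean integrated intensity over 2850–2950 cm⁻¹ is
labelled *vesicle*, since lipid-rich vesicle material dominates the CH
stretch; if the axis lacks that band the total integrated intensity is used
with a warning. Clustering is purely spectral — map coordinates are
metadata only. An all-identical map returns a degenerate single-cluster
partition rather than an arbitrary split.

## PCA–LDA classification

PCA is covariance-based: columns are mean-centred, never variance-scaled,
because after unit-vector normalisation all channels share one scale and
autoscaling would inflate noise-only channels. Components come from the
SVD of the centred matrix; each loading's sign is fixed so its
largest-magnitude element is positive; variance fractions are quoted
against the total variance so they sum to one over all components.

LDA maximises the Fisher criterion. With within/between scatter matrices W
and B, the discriminant axes are the leading generalised eigenvectors of
B v = λ (W + ridge·I) v (ridge 1e-8 guards near-singular W; passing
ridge 0 on singular W raises with advice). Prediction assigns the nearest
class mean in discriminant space, exact ties going to the lexicographically
smaller label. Wilks' Λ = det(W)/det(W+B) is computed via log-determinants;
its significance uses Bartlett's χ² approximation,
−(n−1−(k+g)/2)·ln Λ on k(g−1) degrees of freedom.

LOOCV defaults to 25 PCs — enough to capture the discriminating variance
while keeping far fewer variables than observations; fewer degrade
separation and more add only noise directions. Two protocols: **paper**
(default) fits PCA once on the full cohort and cross-validates only the
LDA, the common practice in spectroscopy software; **strict** refits PCA
inside every fold and projects the held-out spectrum onto the training
model, removing the small information leak of the shared decomposition. An
exact-equality test against a naive n-refit oracle pins the paper protocol.

Metrics are one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/n per class, macro values as unweighted means, all
reported in percent rounded half-up to one decimal (the convention of
clinical performance tables). A class without true instances yields an
undefined sensitivity; macro averages then cover the defined classes and a
warning is recorded. One-way ANOVA on single-PC scores uses the classical
F = MS_between/MS_within with (g−1, n−g) df; if the within-group variance
is exactly zero the result is F = +∞, p = 0 (flagged), except that a
completely constant input (zero between-group variance too) returns F = 0,
p = 1.

## CLS unmixing

A target spectrum (usually a PC loading) is decomposed over seven
unit-normalised membrane-lipid references by ordinary least squares.
Coefficients are unconstrained: PC loadings are signed difference spectra,
and a negative coefficient is the meaningful statement that a component
loads on the negative lobe. Unit-normalising references makes coefficient
magnitudes comparable across lipids. The goodness-of-fit is
`percent_error` = 100·‖residual‖₂/‖target‖₂, the standard relative-residual
figure for CLS. The Gram matrix's condition number is checked against 1e10;
a rank-deficient library raises naming the most collinear pair. An optional
intercept column absorbs constant offsets and is reported separately.

## Synthetic data generator

The generator emulates a three-cytotype EV cohort: BM-MSC (3 donors, 50
spectra), ASC (4 donors, 105), DF (3 donors, 43) — every donor contributes
at least 10 replicates, and the totals match a realistic unbalanced
clinical collection. Each spectrum is

    Σ_r w_r·reference_r + protein/NA band block + polynomial baseline + noise

with Lorentzian bands (the natural Raman line shape; Gaussian available).
The seven lipid references are band sums at literature positions (e.g.
cholesterol ester 537/702 cm⁻¹, the ceramide/C–N 1127 cm⁻¹ band, the
choline 718 cm⁻¹ band of SM and PCh, CH stretches 2850–3010 cm⁻¹), with
per-seed jitter of centers (sd 1 cm⁻¹) and heights (5%); the tables are
balanced so pairwise cosine similarities stay below 0.8, which keeps the
CLS problem well posed. The common band block carries phenylalanine 1003,
amide III ~1240, CH 1450/2940 and nucleic-acid 720–820/1090 cm⁻¹ features;
small class-specific bands (Trp 1337 for BM-MSC, 1127 for ASC, Pro 853/920
for DF) add secondary fingerprint differences.

Class lipid weights encode the contrast the analysis should recover: SM
weighted up for ASC vesicles, GM1 and PCh for BM-MSC and DF vesicles.
Defaults: additive noise sd 1% of the peak signal, donor effect 5%
(one multiplicative amplitude factor per component, shared by all of a
donor's spectra — inter-donor variability is visible but small), baseline a
random order-6 polynomial at up to ~50% of the peak signal. Maps place
vesicle spectra of one class and substrate-only points (baseline + noise)
on a grid with 20–30 µm steps. Everything is a deterministic function of
(config, seed).

What the generator does **not** emulate: detector shot statistics and
cosmic rays, wavelength-dependent instrument response, real lipid spectra
(the references are stylised band sums), within-map spatial correlation,
and drift (axes are born aligned). Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under the assumed
signal model, not instrument-level performance on real acquisitions.

One caveat the synthetic experiments make explicit: donors are nested
within class, so under spectrum-wise LOOCV the donor-level perturbation is
itself class-informative — with class contrasts set to zero but donor
variability left on, accuracy stays well above chance. Chance-level
behaviour is recovered when noise is the only variability. Real studies
face the same replicate-level leakage; donor-wise cross-validation would be
the stricter design, and spectrum-wise LOOCV figures should be read with
that in mind.

## Problem sizes

The test suite and the reproduction script use the full default cohort
(198×1902) where the claim concerns it, and reduced cohorts (3 classes ×
2 donors × ~8–16 spectra, 2 cm⁻¹ step) for oracle-equality and Monte-Carlo
properties, with 10–20 seeds per stochastic claim and 1000 simulations for
the ANOVA null calibration — sizes at which every documented property is
already stable.

## Known limitations

- The modpoly baseline can shave intensity from very broad bands (FWHM
  comparable to the window) since they resemble baseline curvature.
- The shift alignment assumes a rigid axis offset; it cannot correct
  nonlinear dispersion errors.
- `paper`-mode LOOCV shares the PCA across folds (see above); `strict`
  mode quantifies the difference.
- CLS assumes the reference set spans the chemistry of the target; missing
  constituents surface only as percent error, not as a warning.
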