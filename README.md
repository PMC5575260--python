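# evraman

Raman chemometrics for label-free fingerprinting of extracellular vesicles
(EVs).

Bulk Raman spectroscopy of air-dried EV suspensions yields a biochemical
fingerprint — lipid, protein and nucleic-acid bands in the 500–1800 cm⁻¹
fingerprint region and the lipid-dominated 2600–3200 cm⁻¹ CH-stretch
region — that can distinguish vesicles by their cell of origin (e.g.
bone-marrow mesenchymal stromal cells, adipose-derived stromal cells,
dermal fibroblasts) without antibodies or labels. This package implements
the full analysis chain such a study needs, for spectroscopists and
stem-cell/EV researchers:

- **Preprocessing** — iterative sixth-order polynomial (modpoly) baseline
  removal of autofluorescence, unit-vector (L2) normalisation, and rigid
  wavenumber-shift alignment anchored at the 1003 cm⁻¹ phenylalanine band.
- **Map background filtering** — two-class agglomerative hierarchical
  clustering (Ward/Euclidean) separates vesicle spectra from substrate
  points in a mapped drop; the cluster with the higher integrated
  2850–2950 cm⁻¹ CH-stretch intensity is the vesicle cluster.
- **PCA–LDA classification** — covariance PCA of the preprocessed spectra;
  Fisher linear discriminant analysis on the first *k* (default 25) PC
  scores; leave-one-out cross-validation; per-class and macro sensitivity,
  specificity and accuracy; one-way ANOVA on PC scores and the Wilks'
  Lambda test, Λ = det(W)/det(W+B), for multivariate group separation.
- **CLS lipid unmixing** — unconstrained classical least squares expresses
  a PC loading (a signed difference spectrum) as a linear combination of
  seven membrane-lipid reference spectra (Chol, Cer, SM, GM1, PCh, PE, PA),
  with a relative-residual percent error.
- **Synthetic data** — a deterministic generator producing class-structured
  cohorts (lipid mixtures + protein bands + polynomial baseline + donor
  effects + noise) and Raman maps with ground truth, for validating every
  stage end to end.

## Worked example

```python
import numpy as np
from evraman import (default_config, generate_dataset, loocv_classify,
                     confusion_metrics, fit_pca, wilks_test, cls_fit,
                     make_reference_library)
from evraman.pipeline import preprocess_dataset

# three-class synthetic cohort: 50 BM-MSC, 105 ASC, 43 DF spectra
d, truth = generate_dataset(default_config(seed=1))
dp, info = preprocess_dataset(d)          # baseline -> normalise -> align

pca = fit_pca(dp, 25)
cm = loocv_classify(dp, n_pcs=25)          # leave-one-out PCA-LDA
m = confusion_metrics(cm)
print("classes:", cm.classes)
print(cm.counts)
print("macro sensitivity/specificity/accuracy: %s / %s / %s"
      % (m.macro_sensitivity, m.macro_specificity, m.macro_accuracy))

w = wilks_test(pca.scores[:, :2], dp.labels)
print("Wilks lambda (PC1-PC2): %.3g, p = %.3g" % (w.lam, w.p))

lib = make_reference_library(d.axis, seed=1)
labels = np.asarray(dp.labels, object)
contrast = dp.matrix[labels == "ASC"].mean(axis=0) - dp.matrix.mean(axis=0)
fit = cls_fit(contrast, lib)
print("ASC contrast CLS:", {k: round(v, 3) for k, v in fit.as_dict().items()})
```

prints (seed 1):

```
classes: ['ASC', 'BM-MSC', 'DF']
[[105   0   0]
 [  0  50   0]
 [  0   0  43]]
macro sensitivity/specificity/accuracy: 100.0 / 100.0 / 100.0
Wilks lambda (PC1-PC2): 1.66e-05, p = 0
ASC contrast CLS: {'Chol': 0.007, 'Cer': 0.035, 'SM': 0.115, 'GM1': -0.076, 'PCh': -0.09, 'PE': -0.012, 'PA': 0.0}
```

The confusion matrix is diagonal — the default cohort is cleanly separable
at its default noise level — and the CLS fit of the ASC-vs-grand-mean
difference spectrum recovers the generator's built-in lipid contrast:
sphingomyelin (SM) loads positively on the ASC side while ganglioside GM1
and phosphatidylcholine (PCh) load negatively (i.e. toward BM-MSC/DF
vesicles). The near-zero Wilks' Λ with p ≪ 0.001 confirms separation of the
group means in PC1/PC2 space.

A command-line interface wraps the same pipeline:

```bash
evraman simulate --config cfg.yaml --out simdir/   # write a synthetic cohort
evraman run      --config cfg.yaml --out rundir/   # full analysis -> report.json
evraman metrics  --confusion counts.csv            # metrics from any count table
```

`evraman metrics` on the three-class count table
`[[46,2,2],[1,97,7],[1,7,35]]` (rows = true BM-MSC, ASC, DF) reports
sensitivities 92.0 / 92.4 / 81.4%, macro sensitivity 88.6% and BM-MSC
specificity 98.6% — the one-vs-rest definitions with half-up rounding to
one decimal.

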