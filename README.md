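# morphosig

Whole-skull 3D geometric morphometrics for testing whether an exaggerated
anatomical structure behaved as a **socio-sexual signal**.

A candidate display trait — the parietal-squamosal frill of ceratopsian
dinosaurs is the motivating case — is expected to leave four statistical
signatures in a sample of conspecific skulls:

1. **Modularity** — the trait forms a phenotypic module, internally
   integrated but only loosely covarying with the rest of the skull;
2. **Positive allometry** — it changes in relative size and in shape faster
   than any other region during growth;
3. **High variance** — it shows the highest size-independent morphological
   disparity;
4. **Sexual dimorphism** — pooled-sex samples may show bimodal shape scores
   (often absent under mutual selection).

`morphosig` implements the full landmark-based pipeline for all four tests
on 3D configurations of fixed landmarks and curve/surface semilandmarks,
plus a synthetic-data generator with exported ground truth so every stage
can be verified without fossil data.

## Methods at a glance

* **Superimposition.** Centroid size CS = √Σᵢ‖xᵢ − x̄‖²; generalized
  Procrustes analysis (translation, unit-CS scaling, proper rotations);
  a reflection-augmented GPA that registers the sagittal midline of
  bilaterally symmetric structures to a common plane; landmark-level
  retrodeformation by bilateral symmetrization of mildly sheared specimens
  (refused beyond 10° of sagittal obliquity).
* **Semilandmarks.** Thin-plate-spline bending energy (3D kernel) with
  closed-form sliding of curve/surface semilandmarks within their tangent
  spaces against the evolving consensus.
* **Allometry.** Multivariate regression of shape on ln CS; R² with a
  permutation test; the common allometric component (CAC) and residual
  shape components; per-module ln CS ~ ln CS slopes (1 = isometry) and
  per-module CAC-score slopes (0 = no shape change), compared pairwise by
  ANCOVA interaction F-tests; shape prediction at any size.
* **Modularity.** Landmark congruence matrix; maximum-likelihood comparison
  of module partitions with Fisher-z normal likelihoods, AICc and Akaike
  weights; the merge rule for high between-module correlations (within 0.1
  of the lowest within-module value); the covariance ratio CR with a
  landmark-permutation test (CR < 1 ⇒ modular).
* **Disparity.** Per-landmark and per-module Procrustes variance,
  normalized by landmark count, with covariate tests against growth rate
  and within-module correlation.
* **Dimorphism.** Hartigan's dip statistic (exact greatest-convex-minorant
  construction, validated against brute-force minimization over unimodal
  CDFs) with Monte-Carlo uniform-null p-values, scanned over the first
  eight residual shape components of allometry-corrected data, per module
  and whole-skull, with and without the smallest ('juvenile') specimens.

## Worked example

```python
from morphosig import (make_truth, simulate_dataset, gpa, ShapeAllometry,
                       covariance_ratio, module_size_allometry)

truth = make_truth(seed=0)                      # 5 modules x 12 landmarks
data, truth = simulate_dataset(truth, n_specimens=30, seed=1)

aligned = gpa(data.complete_subset())
fit = ShapeAllometry(aligned).fit(n_perm=999, seed=2)
print(fit.summary())
print(module_size_allometry(data)["slope"].round(3))
cr, p, _ = covariance_ratio(aligned, list(data.scheme.modules),
                            n_perm=999, seed=3)
print(f"covariance ratio CR = {cr:.3f}  (permutation p = {p:.4f})")
```

```
Shape ~ log(centroid size) regression
==============================================
specimens:            30
coordinates:          180 (60 landmarks x 3)
R-squared:            0.5106
permutation p:        0.0010  (999 perms, seed 2)
CAC slope |b|:        0.1127
residual components:  27

module
frill          1.378
snout          1.066
jugal          0.981
maxilla        0.997
postorbital    0.863
Name: slope, dtype: float64

covariance ratio CR = 0.725  (permutation p = 0.0010)
```

Half of the shape variance is size-related (the generator planted 0.5); the
frill-analog grows with strong positive allometry (slope 1.38 ≫ 1, the
planted exponent was 1.4) while the postorbital-analog is negatively
allometric; and the skull is significantly modular (CR < 1, permutation
p ≈ 0.001).

The same analysis runs end-to-end from the shell:

```sh
morphosig run-all --seed 7 --out results/ --n-perm 999 --n-mc 2000
morphosig simulate --seed 1 --out data/ --preset paper_like
```

`run-all` writes delimited tables for every stage plus `report.json` and a
four-prediction `summary.txt`.

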