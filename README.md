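# ranklomics

Intensity-invariant texture radiomics for predicting the IDH genotype of
glioblastomas from a single contrast-enhanced T1-weighted MRI slice.

Texture features computed directly on gray levels are fragile: the same tumor
scanned on two machines yields different co-occurrence statistics because the
absolute intensities shift. `ranklomics` addresses this with the **ranklet
transform**: each 4×4 image block is split into two equal pixel subsets X and
Y along a Haar-style pattern (vertical, horizontal or diagonal) and scored by
the normalized Wilcoxon rank-sum statistic

```
R = U / (C²/8) − 1,      U = Σ_{p∈Y} π(p) − (C/2)(C/2+1)/2,
```

where π(p) are mid-ranks over all C = 16 block pixels. U counts pixel pairs
(y ∈ Y, x ∈ X) with y > x (ties as ½), so R ∈ [−1, 1] and depends only on the
*ordering* of pixel values — any strictly increasing intensity map (brightness
offset, contrast scaling, gamma) that introduces no new ties leaves every
coefficient bit-identical.

On the transformed coefficient images (and on the raw image as a baseline)
the package computes the 14 classical gray-level co-occurrence (GLCM) features
at distance d = 1 averaged over θ ∈ {0°, 45°, 90°, 135°}, plus the 11
gray-level run-length (GLRLM) statistics, restricted to the tumor ROI. A
logistic-regression classifier with stepwise backward elimination under the
leave-one-out (LOO) error selects the feature subset; the result is reported
as a per-case mutation probability and an accuracy / sensitivity /
specificity / PPV / NPV panel. A synthetic-image module (Gaussian random
field textures, elliptical ROIs, seeded cross-scanner intensity jitter) makes
every stage testable without clinical data.

Intended users: radiomics researchers who need texture features robust to
cross-institution scanner variation, and anyone reproducing rank-based
texture pipelines on small labeled cohorts.

## Worked example

```sh
ranklomics synth cohort --n-neg 32 --n-pos 7 --seed 1234 --out cohort/
ranklomics extract cohort/ --out features.csv
ranklomics classify features.csv --out report.json
```

prints (abridged):

```
wrote 39 cases to cohort
wrote 39 cases x 100 features to features.csv
raw_glcm: accuracy 1.000 sensitivity 1.000 specificity 1.000 (14 features)
ranklet_vertical_glcm: accuracy 0.974 sensitivity 0.857 specificity 1.000 (12 features)
ranklet_horizontal_glcm: accuracy 0.974 sensitivity 1.000 specificity 0.969 (13 features)
ranklet_diagonal_glcm: accuracy 0.974 sensitivity 0.857 specificity 1.000 (13 features)
raw_glrlm: accuracy 1.000 sensitivity 1.000 specificity 1.000 (11 features)
ranklet_glrlm: accuracy 1.000 sensitivity 1.000 specificity 1.000 (32 features)
report written to report.json
```

The synthetic cohort has 32 "wild-type" cases (smooth, homogeneous texture)
and 7 "mutant" cases (shorter correlation length, higher heterogeneity), so
both the raw and ranklet panels recover the class signal under LOO; on real
multi-scanner data the raw panel degrades with intensity drift while the
ranklet panel does not, which is what the invariance report demonstrates:

```sh
ranklomics invariance --seed 3 --out inv.json
# median feature SD per panel: raw=0.08594, ranklet_vertical=0,
# ranklet_horizontal=0, ranklet_diagonal=0
```

Each feature is recomputed on the original image and on brightness-, contrast-
and gamma-perturbed versions; the SD across versions is zero for every
ranklet-panel feature and positive for the raw panel.

As a library:

```python
import ranklomics as rk

case = rk.generate_texture_image(rk.TextureParams(), seed=3)
coeffs = rk.ranklet_transform(case.image, case.mask, resolution=4)
row = rk.extract_case_features(case)           # 100 named features
```

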