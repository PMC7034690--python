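# Methods

## Problem setting

Glioblastomas are classified into wild-type and mutant IDH genotypes; the
mutant form tends to show more heterogeneous imaging intensities. The
package predicts this binary genotype from texture features of a manually
delineated tumor ROI on one representative axial slice. Because cohorts of
this kind are assembled across institutions and scanners, the central design
goal is intensity invariance: features must depend on the spatial
arrangement of gray levels, not their absolute values.

## Pipeline

1. **Normalization** (`io.normalize_intensity`). The whole slice is
   stretched linearly to 0–255 and rounded half-up. Whole-image (rather than
   ROI-only) statistics are used because normalization precedes contour
   delineation in the clinical workflow the package models. A constant image
   maps to all zeros with a logged warning instead of aborting a batch.

2. **Ranklet transform** (`ranklet`). The image is tiled into
   non-overlapping `resolution × resolution` blocks (default 4)
   anchored at the top-left of the ROI bounding box;
   trailing partial blocks are dropped and a coefficient is marked valid only
   when its whole source block lies inside the ROI, so tumor texture is never
   contaminated by background. Each block is split into subsets X and Y by a
   Haar-style pattern per orientation (vertical: left|right, horizontal:
   top|bottom, diagonal: quadrant checker; which half is Y is a frozen
   convention — flipping it only negates coefficients globally, and the GLCM
   of the quantized coefficients is unaffected up to bin reflection). The
   coefficient is the normalized rank-sum statistic `R = U/(C²/8) − 1` with
   mid-ranks for ties; ties therefore count ½ in the equivalent pair-count
   formulation, the standard Wilcoxon treatment, which also makes constant
   blocks map exactly to 0. A sliding-window variant is available through the
   `stride` parameter, but the default and all tests use stride = resolution.

   *Invariance guarantee.* Mid-ranks depend only on the ordering and tie
   structure of block pixels, so any strictly increasing map that introduces
   no new ties preserves every coefficient bit-for-bit. Rounding perturbed
   images back to integers can merge adjacent values (new ties), which is why
   the perturbation API exposes a pre-rounding float path; with 8-bit
   rounding the coefficients are near- but not exactly invariant.

3. **Quantization and texture features** (`texture`). Ranklet coefficients
   are binned into G = 8 equal-width bins over [−1, 1] (last bin closed so
   +1 lands in bin G−1); raw images use G = 32 equal-width bins over 0–255.
   Neither count has a single canonical value, so both are configurable;
   8 and 32 are common practice for coefficient-valued and 8-bit inputs
   respectively. The GLCM
   counts level pairs at distance d = 1 for θ ∈ {0°, 45°, 90°, 135°} with
   symmetric accumulation (standard Haralick practice; it makes θ and
   θ + 180° coincide) and both pair endpoints inside the mask — no padding
   or reflection. Fourteen features are computed per direction and averaged.
   Where two non-identical literature forms share a name, the assignment is:
   *homogeneity* uses the 1+|i−j| denominator, *inverse difference moment*
   the normalized squared form paired with *inverse difference normalized*;
   *information measure of correlation* is the first Haralick variant
   (HXY − HXY1)/max(HX, HY); *difference variance* is the variance of the
   |i−j| distribution. All entropies use the natural logarithm. Degenerate
   GLCMs (zero marginal SD) report correlation 0 with a warning. The GLRLM
   counts maximal equal-level runs per direction, truncated at mask
   boundaries, and yields the 11 classical statistics (SRE … LRHGE) with
   1-based gray-level weighting (1/g² is undefined at bin 0), averaged over
   the four directions.

   Per case this yields 4 GLCM panels (raw + three orientations, 14 each)
   and 4 GLRLM panels (11 each) under `<source>_<feature>` column names.

4. **Classification** (`classify`). Logistic regression (maximum likelihood,
   unpenalized) is the primary classifier; KNN (k = 5) and RBF-SVM (C = 1,
   Platt probabilities with a fixed random state) are provided for
   comparison — those hyperparameters are package defaults, reported in the
   config echo. Features are standardized inside each LOO fold using
   training-fold statistics only. A non-convergent logistic fit (complete
   separation is routine at N ≈ 39) falls back to a small ridge penalty
   (C = 100) and the fold is flagged. A probability ≥ 0.5 classifies as
   mutant; the tie goes to the positive class so the rule is deterministic.

   **Stepwise backward elimination** starts from one full panel and, per
   iteration, removes the feature whose removal gives the lowest LOO error,
   stopping when no removal strictly lowers it. Ties are broken toward the
   feature with the largest Wald p-value in a full-data logistic fit, then
   lexicographically. The selection criterion *is* the validation loop —
   deliberately, matching the classical small-cohort radiomics design this
   package models — which couples
   selection and validation and makes the LOO error an optimistic estimate
   of generalization; treat reported accuracies accordingly. For
   classification the GLRLM features are grouped into two panels (raw;
   ranklet with the three orientations pooled), alongside the four GLCM
   panels.

   Per-feature group differences use a Lilliefors-corrected
   Kolmogorov–Smirnov normality check per class (the correction standard
   statistical packages apply when the normal parameters are estimated from
   the sample; a naive KS with plug-in parameters would be anti-conservative
   as a gate); if both classes pass at α = 0.05 a two-sample Student t test
   is used, otherwise Mann–Whitney U, both two-sided. P-values are reported
   raw, with a Bonferroni-adjusted column alongside in the classification
   report.
   Panel performances are compared by a Pearson chi-squared test on the 2×2
   correct/incorrect table.

## Synthetic data model

`synthetic` generates Gaussian-random-field textures: white noise smoothed
at a correlation length (pixels), mixed with an unsmoothed component whose
weight is the heterogeneity parameter, standardized, mapped to
`base_mean + base_sd·z` and compressed affinely into 0–255 only when it
overflows (order-preserving — no clipping, since clipping would create ties
and break exact invariance). The ROI is a rotated ellipse with jittered
semi-axes ≈ (0.20 H, 0.25 W), covering 13–19 % of the frame. Defaults:
64×64 images, `base_mean` 128, `base_sd` 45; wild-type class correlation
length 6 px / heterogeneity 0.1, mutant class 2 px / 0.6 — one scalar axis
(local spatial correlation) separates the classes in the same direction as
the modeled biology (mutant less homogeneous). Cohorts derive one generator
per case from `SeedSequence([master_seed, case_index])`, so any case is
reproducible independent of generation order, and apply per-case contrast
(U(0.88, 0.97)) then brightness jitter (within the image's headroom, capped
at ±10) to mimic cross-scanner variation.

What the generator does *not* emulate: brain anatomy, MR physics (bias
fields, Rician noise), partial-volume effects at the tumor rim, 3D
structure, or observer variability in contouring. Passing tests therefore
demonstrate correctness of the transforms and honest behavior of the
statistics on textures whose discriminative axis is known — not clinical
performance on MRI.

The invariance report perturbs a case with brightness shifts fitted to the
image's headroom, contrast 0.85 and gamma {0.8, 1.25}, and recomputes raw
and ranklet GLCM panels per version **without re-normalizing**:
normalization commutes with affine maps, so re-stretching would trivially
undo brightness/contrast perturbations and mask exactly the effect the
report measures; perturbations here model drift that survives or follows
normalization. SDs across versions are computed after subtracting the first
version's values (numerically stabler; exactly zero when versions coincide
bit-for-bit).

## Problem sizes and numerical choices

The default study-scale experiments use a 32 + 7 cohort (the modeled class
imbalance) of 64×64 images, a balanced 20 + 20 cohort for single-feature
significance, 20 seeded images for invariance checks, 1,000 random blocks /
200 random images for oracle comparisons, and 200 null replicates for type-I
calibration — sizes chosen so the full suite runs in well under a minute on
one core while keeping binomial noise small relative to the asserted margins.
Round-half-up is used wherever values are quantized to integers. Feature
CSVs serialize floats at 17 significant digits so round-trips are exact.

## Known limitations

- LOO-coupled selection overstates accuracy (see above);
  `nested_loo_evaluate` (or `RunConfig(nested_validation=True)`) re-runs the
  whole selection inside an outer LOO for an honest estimate, at N times the
  cost.
- Single-slice 2D only; no 3D co-occurrence, no multi-resolution ranklet
  pyramid, no higher-order matrices (GLSZM/NGTDM).
- The GLCM feature name/formula pairing follows one consistent literature
  reading (documented above); other radiomics toolkits resolve the ambiguous
  names differently, so cross-toolkit feature values need not match.
- PPV/NPV are undefined (NaN, with a warning) when a class is never
  predicted; small cohorts hit this routinely.
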