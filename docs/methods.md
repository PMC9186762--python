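# Methods

This note records the models, conventions and numerical choices behind
`samp`, in the spirit of a statistical software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A **segmented field** is one field of view: a nuclear-stain intensity image,
a whole-cell-stain intensity image, and two integer label masks sharing one
label per nucleus/cell pair. Invariants enforced on construction: all four
arrays share a shape, intensities are nonnegative, and every nucleus pixel
set is contained in its same-labelled cell (violators are dropped with a
warning — they indicate segmentation errors, not measurable cells). Objects
whose cell mask touches the field border are excluded from measurement:
truncated morphology would bias every size feature, and no unbiased
correction exists at the single-object level.

A **feature table** is cells × 62 features plus six metadata identifiers
(model, condition, replicate, well, field, object). The 62 names are a fixed
registry; all readers validate against it byte-exactly, because silent
column drift is the dominant failure mode of spreadsheet-based profiling.

## Feature definitions and conventions

All geometry is in pixel units, 0-based (row, col) coordinates.

- **Perimeter** uses the 4-direction Crofton estimator
  (`skimage.measure.perimeter_crofton`). We compared candidate estimators
  (crack boundary, weighted 8-connected chain, Vossepoel–Smeulders weights,
  marching-squares contour length, Crofton) on rasterized disks, ellipses
  and rotated squares with known perimeters; Crofton was within ~2% on all
  smooth/rotated shapes, where crack counting errs by +27% and the weighted
  chain by +5% on disks. Its one known weak spot is the axis-aligned
  digitized rectangle (−8%), which no smooth-shape estimator handles well.
- **Form factor** is 4πA/P², clamped at 1: by the isoperimetric inequality
  values above 1 are discretization artifacts of very small objects.
- **Elongation** = minor/major axis, axes from the second central moments
  (4·√eigenvalue, the ellipse-equivalent convention). A one-pixel object has
  degenerate moments; both axes are then reported as the equivalent diameter
  with a warning.
- **Compactness** = area / convex-hull area (solidity). The hull, and the
  Feret (caliper) diameters behind **chord ratio** = maxFeret/minFeret, are
  computed on pixel corners (centres ± 0.5) so that a solid axis-aligned
  rectangle has compactness exactly 1 and one-pixel-wide objects keep a
  nonzero width. This deliberately makes compactness *not* the algebraic
  inverse of form factor — the two carry different information.
- **Displacement** is the distance between the geometric and the
  intensity-weighted centroid (per compartment stain).
- **Intensity moments** use the population (n) denominator, so a balanced
  two-valued region {0, 10} has SD exactly 5; skewness and excess kurtosis
  are the Fisher definitions and defined as 0 for zero-variance regions.
  **Energy** and **entropy** (bits) come from a 64-bin histogram on the
  per-object min–max range; a constant object has energy 1, entropy 0.
- **Light flux** is total intensity normalized to the field-median total
  intensity of the same compartment — a dimensionless per-field relative
  brightness. **Intensity spreading** is the mean intensity of the outer
  half of a cell's pixels (ranked by distance to the centroid) over the
  inner half: >1 means rim-concentrated stain. These two and chord ratio
  are in-house definitions chosen to be monotone in the obvious physical
  quantity; they are isolated behind the feature registry so alternative
  definitions can be swapped without touching the pipeline.
- **GLRLM texture** quantizes each object to 16 grey levels on its min–max
  range (constant → level 1), enumerates maximal equal-level runs in the 4
  principal directions restricted to mask pixels, and pools the run-length
  matrices. GLN = Σᵢrᵢ²/Nr, RLN = Σⱼcⱼ²/Nr, HGLRE = Σp(i,j)·i²/Nr,
  LGLRE = Σp(i,j)/i²/Nr (Galloway's statistics). Run totals conserve pixel
  count per direction, which the tests assert.
- **Spatial features** are computed per field on nuclear centroids, never
  across fields. Four graphs: sphere-of-influence (edge iff
  d ≤ r_a + r_b with r = nearest-neighbour distance), Euclidean MST,
  Gabriel (closed-disk predicate: boundary points block) and the relative
  neighbourhood graph ("lune", open predicate: boundary points do not
  block). These conventions give the chain MST ⊆ RNG ⊆ Gabriel and degree
  ≥ 1 everywhere, and make a regular grid behave like the continuous
  definitions (interior Gabriel degree 4). Predicates carry a 1e-9 relative
  slack so exactly symmetric configurations (equilateral triangles, grids)
  are decided as in continuous space despite floating-point rounding.
  Coincident centroids are separated by a deterministic 1e-6 px jitter with
  a fixed internal seed. Fields with fewer than two nuclei report the eight
  spatial features as missing.

## Normalisation

Aggregation is a three-level mean hierarchy: cells → well summary means
(technical replicates) → experiment means (one per replicate) → condition
means.

- **Z-score profile**: per feature,
  `Z = (condition mean_sen − condition mean_ctrl) / SD(control experiment
  means)`, SD with the n−1 denominator (three replicates is the design
  target; n−1 is the small-sample convention). Zero control SD yields a
  missing Z, not ±∞, and missing Z never counts as significant.
  Significance is strict: |Z| > 1.96; Z = 1.96 exactly is not significant.
  With only three experiment means the 1.96 cut-off is nominal rather than
  exact — the ratio follows a heavy-tailed t-like distribution, so the
  false-positive rate of the rule exceeds 5%; this is a property of the
  design, reported here as a caveat, and the package does not pretend
  otherwise.
- **Standard scores**: within each experimental replicate, each feature is
  centred/scaled by the mean and n−1 SD of the pooled two-condition cell
  population; replicate scores are concatenated, then summarised by
  feature-wise medians (medians resist the heavy outlier tails of
  single-cell data). Condition profiles therefore show both conditions,
  unlike Z-profiles where the control is the reference.
- **Masking**: datasets from the older rectangular-image microscope
  generation cannot measure eight cell-geometry features. The mask is
  configuration (default: Cells Area, Form Factor, Elongation, Compactness,
  Chord Ratio, Gyration Radius, Diameter, Perimeter); masked features are
  fixed at 0 in profiles, excluded from significance counts (denominator
  62 → 54) and from factor analysis.
- **Clustering** of profile rows: Ward's criterion on unsquared Euclidean
  distances (the ward.D2 convention), deterministic leaf order.

## Exploratory factor analysis

Input is the per-cell standard-score matrix (masked features excluded).
The pipeline:

1. **Scree/Kaiser**: eigenvalues of the Pearson correlation matrix; the
   initial factor count is #{λ > 1}, strict inequality.
2. **Extraction**: maximum-likelihood common-factor analysis. For fixed
   uniquenesses ψ the loadings follow from the top-k eigenpairs of
   ψ^{-1/2}Rψ^{-1/2} (Jöreskog's profile likelihood); ψ is optimized by
   L-BFGS-B with the analytic gradient, bounded below at 0.005 to contain
   Heywood cases (a bound hit raises a warning). The fit reproduces R's
   `stats::factanal` uniquenesses to ~1e-3 on test fixtures (an independent
   implementation used as the oracle).
3. **Rotation**: Oblimin with γ = 0 (quartimin), the common default of the
   oblique family, via the Bernaards–Jennrich gradient-projection
   algorithm, always started from the identity rotation (deterministic).
   Column signs are fixed so each factor's largest-|loading| entry is
   positive; columns are ordered by explained sum of squares. Membership
   uses the *pattern* loadings at |λ| ≥ 0.5.
4. **Designation**: each factor is labelled by the majority feature family
   of its members, ties broken by summed |loading|; empty membership →
   "Unclassified". The shipped family map assigns each of the 62 features
   to one of nine designations (sizes, shapes, intensities, spacing, and
   per-stain intensity-variance families covering CV/SD/skewness/kurtosis/
   histogram/GLRLM statistics).
5. **Adjustment**: over-factoring (any factor with < 2 members — a coherent
   family was split) decrements k; under-factoring (a factor holding ≥ 2
   features from each of ≥ 2 families) increments k; iterate within
   k ∈ [2, 12], at most 10 steps. The qualitative over/under judgement is
   operationalized by these two rules; both are configurable and a manual
   override is honoured. If the rules oscillate, the smaller k wins
   (parsimony). Over-factoring is checked first because a near-empty factor
   is the less ambiguous signal.
6. **Scores**: Thompson's regression method, W = R⁻¹(ΛΦ), applied to the
   standard scores; ill-conditioned R gets a 1e-8 ridge with a warning.
   Regression scores are shrunken, so their covariance approaches but does
   not reach Φ. Median factor scores per condition form the factor
   profiles; the strongest-loading member of each designated factor forms
   the reduced "representative" profile.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; they emulate structure, not photorealism.

**Phantom fields** place elliptical nuclei inside concentric, co-oriented
larger ellipses (cells) by dart throwing with a minimum centre distance
just above the maximum cell diameter (no overlaps), then add Gaussian pixel
noise. Defaults: 512² px fields; proliferating cells — 12 per field,
nuclear semi-axes 9×7 ± 0.8 px, nuclear stain 180 ± 12, cell stain
120 ± 10, noise SD 6; senescent cells — 5 per field, semi-axes doubled
(≈4× nuclear area), nuclear stain ×0.6 (dimmer DNA stain is a known
senescence correlate), sparser packing. Ground truth (centres, axes,
orientations, intensities) is returned with every field. What the phantom
does *not* emulate: textured chromatin, intensity gradients, touching
cells, segmentation errors; tests passing on phantoms therefore validate
the measurement code, not robustness to imperfect segmentation.

**Factor tables** draw X = FΛᵀ + ε with eight planted factors mapped onto
the feature families (primary loading 0.8, cross-loadings 0.1, uniqueness
0.3, factor correlation = identity); the 13 cell-intensity-variance
features carry no primary loading and act as near-noise columns, which is
what lets the over-factoring rule be exercised. The senescent condition
shifts factor means by (+2 nuclear size, +2 cell size, −1 cell intensity,
−1.5 nuclear intensity, +1.5 spacing, −0.8 nuclear shape, −1.2 cell shape,
+1 nuclear-intensity variance) — signs follow the enlarged/dim/sparse
senescent phenotype; magnitudes were chosen once as a potent, clearly
separable phenotype. Defaults: 1,700 cells per condition per replicate ×
3 replicates (≈5,100 per condition, ~10,200 cells total). A deterministic
per-feature affine transform (fixed internal seed) maps scores to
raw-looking scales, exercising the scale invariance of the normalisations.

**In-vivo tables** draw 27-feature cells for control and drug-treated
tumours (3 samples each, 400 cells per sample): p21-positive cells (10% /
45% of cells respectively) have gamma-distributed DAB optical densities
around 0.45 vs 0.08 for negatives, and size features shifted by +1.5 SD.

## In-vivo profiling

p21 DAB mean OD is graded 0/1+/2+/3+ at thresholds 0.2/0.4/0.6 with
*inclusive* boundaries (OD = 0.2 is 1+), matching the upstream detection
software's convention; positivity ⇔ ≥ 1+. The 0.05 counterstain detection
threshold belongs to the upstream nucleus-detection step and is carried as
metadata only. Treatment-level profiles use *mean* standard scores pooled
over both treatments (means, not medians, at this level). Stratified
Z-profiles compare p21-positive to p21-negative cells *within* each
treatment, with the SD taken across per-sample means (n−1, N = 3 samples);
the choice of the within-treatment p21-negative stratum as the reference
population is a documented configuration default — the alternative
(cross-treatment reference) is not exposed because it conflates treatment
and senescence effects.

## Problem sizes and determinism

Validation runs at deliberate desk scale: phantom fields of 400–640 px with
4–12 objects, oracle comparisons on ≥ 20 random instances per feature
family (12–30 points/pixels each), EFA recovery on the ~10,200-cell default
table, and embeddings on a few hundred cells with perplexity reduced
accordingly (the 100 default targets full-scale datasets; the code lowers
it with a warning when n ≤ 3·perplexity). Every stochastic step takes an
explicit seed; t-SNE/UMAP are run in their seeded single-threaded modes,
which is the only supported mode.

## Known limitations

- Headline per-model numbers from real microscopy (e.g. how many of 62
  features change in a given senescence model) depend on data that is not
  redistributable; the package validates structure and recovery on planted
  ground truth instead.
- Crofton perimeter underestimates axis-aligned rectangles by ~8%; if a
  dataset is dominated by rectangular objects the form factor will be
  correspondingly inflated.
- Chord ratio, light flux, intensity spreading and displacement are
  in-house operationalizations of proprietary feature names; their values
  are internally consistent but not numerically comparable to the original
  acquisition software.
- The over/under-factoring rules are a reasonable mechanization of an
  expert judgement; unusual loading structures (e.g. genuine singleton
  factors) will be folded away by the parsimony preference.
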