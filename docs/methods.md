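# Methods

## The radial positioning score

Lysosome positioning along the microtubule network is scored per cell on a
normalized radial coordinate running from the centrosome (the
microtubule-organizing center, marked by γ-tubulin) to the plasma membrane
(outer edge of the α-tubulin stain).  For a pixel p inside the cell mask,

    r(p) = Dc(p) / (Dc(p) + Db(p)),

with Dc the Euclidean distance to the centrosome pixel and Db the Euclidean
distance transform to the nearest background pixel.  r is 0 at the
centrosome, approaches 1 at boundary-adjacent pixels, and for strip or disk
geometries equals the fractional position along the centrosome→membrane
segment.  This definition was chosen over ray casting because it is well
defined for non-convex outlines, needs no angular discretization, and is a
single vectorized computation; a ray-based variant would disagree with it on
strongly concave cells, which is out of scope here.

The cell is partitioned into five equal-width shells of the coordinate
(region k covers r ∈ [0.2k, 0.2(k+1)), with region 4 closed at 1.0 so every
boundary pixel is labeled; the centrosome pixel has r = 0 and belongs to
region 0).  The per-cell readout is the fraction f_k of background-corrected
LAMP1 intensity in each shell, and the **peripheral score** f₃ + f₄ — the
share of lysosomal signal in the outer 40% of the axis.  Report views and
summary JSON suppress region 0 by convention (the perinuclear pool dominates
it) but no renormalization is applied: stored fractions always refer to
whole-cell intensity, and the full f₀..f₄ vector is kept in the CSV.

Background is corrected per cell as the median LAMP1 intensity outside the
cell mask dilated by 5 px (policy `median`; `none` disables it), with the
corrected intensity clamped at zero.  Without this, the camera offset —
which scales with region *area*, not lysosome content — would dominate the
outer-region fractions.  Cells whose corrected whole-cell intensity is not
positive are excluded and logged, not imputed, matching per-cell manual
analysis practice; likewise cells whose centrosome cannot be localized.

## Segmentation

* Cell mask: α-tubulin channel smoothed with a σ = 1 px Gaussian, Otsu
  threshold, largest connected component, light binary opening (radius 1)
  and hole filling.  Otsu on the smoothed channel is parameter-free and
  invariant to positive intensity rescaling; an absolute threshold can be
  supplied for real data.
* Nucleus: same procedure on the counterstain, intersected with the cell.
* Centrosome: peak of the σ = 2 px smoothed γ-tubulin signal inside the cell
  mask.  Tied peaks are resolved toward the nucleus centroid, then by
  smallest (row, col) — a pure determinism device.
* Puncta: negated Laplacian-of-Gaussian response at σ = 2 px (matching the
  simulated spot width), thresholded, connected components, area ≥ 3 px.
  The default threshold is robust: median + 5·1.4826·MAD of the response.
  Otsu is inappropriate here because spots occupy well under 1% of the
  pixels, so the response histogram is effectively unimodal and Otsu splits
  the noise mode (measured F1 ≈ 0.34 versus ≈ 1.0 for the MAD rule on
  default-noise scenes).  When the MAD is exactly zero — only possible on
  noise-free synthetic data — the rule falls back to Otsu, which is reliable
  precisely in that clean bimodal case.  Touching puncta that merge into one
  component are counted once; no watershed splitting by default.

Coordinates are (row, col), 0-based, pixel centers; masks are boolean over
the pixel grid.

## The synthetic scene generator

Scenes emulate single-cell, four-channel immunofluorescence images
(LAMP1 / α-tubulin / γ-tubulin / DAPI):

* Geometry: star-convex boundary r(θ) = R·(1 + irregularity·g(θ)), where g
  is a random Fourier series over harmonics 2–5 normalized to unit peak.
  Any irregularity < 1 yields a single closed region.  Default 512×512 px
  with R = 150 ± 8 px; the `SceneParams.small()` preset (128 px, R = 42 ± 3,
  40 puncta) is the desk-scale configuration used throughout the simulation
  studies for speed.  A circular nucleus (0.35 R) sits at the cell center
  and the centrosome just outside its edge (offset 0.10 R), reflecting the
  usual juxtanuclear MTOC position.
* Puncta: normalized radii are i.i.d. Beta(α, β) — a flexible two-parameter
  family on [0, 1] chosen as a *modeling device*, not an inference about real
  lysosome distributions; (2, 4) gives a perinuclear and (4, 2) a peripheral
  phenotype.  Each planted radius u is mapped onto the pixel grid by casting
  a ray from the centrosome at a random angle and taking the cytoplasmic
  pixel whose measured r is nearest u; the *angle* (never u) is resampled up
  to 200 times until |r − u| ≤ 0.02, so nucleus exclusion (rays crossing the
  nucleus cannot serve mid-range radii) does not bias the planted marginal.
  Puncta are excluded from the nucleus because lysosomes are cytoplasmic.
  Spots are rendered as integrated-amplitude Gaussians (σ = 2 px,
  500 photons).
* Camera model: Poisson(signal + background) shot noise plus Gaussian read
  noise (background 10 photons, read σ = 2) — the standard fluorescence CCD
  model.  `shot_noise=False` yields the noise-free expectation image used in
  recovery benchmarks.

What the generator does **not** emulate: optical PSF/aberrations beyond a
Gaussian spot, 3D structure, multi-cell crowding, spatially varying
background, amplitude heterogeneity, or out-of-focus light.  Passing
recovery tests therefore demonstrate correctness of the measurement chain on
idealized single-cell scenes, not segmentation robustness on real
micrographs.

Degradation scenes rank pixels by distance from the image center so planted
cell and halo areas are pixel-exact; fills are hard-edged because the
planted areas themselves are the quantity under test (pre-smoothing a mask
tens of pixels across shifts its area by several percent through curvature
bias, which is also why `measure_degradation` defaults to no smoothing).

## The statistics dispatcher

For two samples with ≥ 8 observations each: both groups are tested with the
D'Agostino–Pearson omnibus (p > 0.05 defines normal); if both pass, an
F-test of variances (threshold 0.05, conventional) selects Student's versus
Welch's t-test; otherwise the Mann–Whitney test is used.  Below 8 per group
the omnibus statistic is undefined, so the dispatcher takes the t branch
directly and records a warning.  All tests are two-sided; significance is
rendered ns/*/**/*** at 0.05/0.01/0.001.  No multiple-testing correction is
applied by default (per-comparison reporting); a Holm adjustment is
available.

Mann–Whitney uses midranks; the p-value is exact (full enumeration) when the
pooled size is ≤ 12 and tie-free, else the tie-corrected normal
approximation with continuity correction.  The Brunner–Munzel test is
implemented from midranks: p̂ = P(A<B) + ½P(A=B), studentized with a
Welch–Satterthwaite-type t approximation; it warns below 10 per group and
reports p̂ without a p-value under complete tied separation (zero rank
variance in both samples).  Its p̂ is validated against brute-force pairwise
enumeration and its p-value against an independent implementation.

## Cohorts and survival

Synthetic cohorts carry log-normal expression per gene, exponential event
times (baseline hazard 0.012/month ⇒ median ≈ 58 months, a plausible
breast-cancer scale; hazard multiplied by the planted ratio in the high-risk
group), independent exponential censoring, uniform lymph-node totals
(1–30), and binomial node positives with a group-dependent probability
(0.15 vs 0.40 by default).  The planted high-risk group is *defined* as the
set selected by the combined expression stratification, making downstream
recovery exact by construction and letting null cohorts (hazard ratio 1,
equal node probabilities) calibrate type-I error.

Stratification is rank-based: the single-gene high group is everyone at or
above the value of the ⌈f·n⌉-th largest expression (ties included, so the
group can exceed ⌈f·n⌉); the combined group re-ranks the high stratum by a
second gene until the smallest set covering the target share of the whole
cohort is reached.  The published 3%-of-total figure is treated as a target
size from which the within-stratum cut is derived, since only the outcome,
not the rule, is stated; tie handling is likewise unstated upstream, so the
deterministic ≥-threshold convention is adopted.  Kaplan–Meier estimation
and the logrank test are delegated to lifelines behind this module's
surface; both are verified against hand-computed product-limit and
hypergeometric O−E instances.

## Closed forms

* Degradation ratio: (cleaved − cell)/cell with cleaved measured as the
  union of cleaved signal and cell footprint.  The union reconciles the
  subtraction formula with the "extracellular area relative to total cell
  area" reading and guarantees a non-negative ratio.
* Tumor volume: V = 4/3π·L·W·(L+W)/2·1/8 (mm³), with axes canonicalized so
  L ≥ W; equal axes reduce to the sphere volume πd³/6.

## Problem sizes and tolerances

Simulation studies use the desk-scale scene preset: the parameter-recovery
study runs 200 replicate experiments of 20 cells per group for the planted
Beta(2, 4) vs Beta(4, 2) contrast and 200 identical-parameter null
replicates; segmentation benchmarks use 20 seeds at 256 px; dispatcher and
logrank null calibrations use 2000 and 1000 replicates.  Monte-Carlo
acceptance bands are set at ±3 binomial standard errors around the nominal
rate.  Exactness claims (rank statistics vs enumeration, planted areas,
partition coverage) are asserted to 1e-12/1e-9; geometry against the disk
oracle to 0.01 absolute, which bounds the pixel-discretization error at the
sizes used.

## Known limitations

* The radial coordinate compresses near strong concavities (Db measures the
  nearest boundary, not the boundary along the outward path).
* Merged puncta bias size/count statistics when spot density is high; the
  count benchmarks therefore use a minimum planted separation.
* The exact Mann–Whitney branch is limited to pooled n ≤ 12 and tie-free
  data; beyond that the asymptotic approximation is used.
* Survival analysis covers two-group logrank comparison only — no Cox
  models, no competing risks, no multi-gene signatures beyond the two-gene
  combined rule.
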