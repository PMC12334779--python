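# Methods

## Coordinate conventions and value domain

All volumes are reoriented at load time to a fixed anatomical array order:
axis 0 cranial→caudal, axis 1 ventral→dorsal, axis 2 left→right. A supine
acquisition is assumed, so axis 1 is the gravitational axis; reorientation
is header-based only (no in-plane tilt correction), and a volume without
usable orientation metadata is rejected rather than guessed. Voxel indexing
is 0-based; slice ranges are half-open.

Lung HU values are **clipped**, not excluded, to [−1000, +100] inside the
mask. Clipping keeps the mask voxel count as the denominator of every
percentage histogram, so profiles over sub-regions always sum to 100 %.
`clip_hu` is idempotent and leaves out-of-mask voxels untouched.

## Segmentation fallback

An externally supplied mask always wins; the built-in segmentation exists so
a scan can be processed without one and none of the science core depends on
it. Recipe: threshold below −300 HU → drop components touching the in-plane
image border (exterior air) → drop components smaller than 30 ml → close
with a 3 mm ellipsoidal structuring element so dense consolidations enclosed
by aerated lung are re-included. Optional seed points restrict the result to
seeded components (the "semiautomatic" interaction). Defaults are sized for
human lungs; test phantoms pass a smaller `min_component_volume`. Large
vessels and airways are not removed.

## Regional partition

Slice selection places 18 ideal positions as a linspace from the first to
the last lung-containing slice, rounds half-away-from-cranial, and resolves
any collision by shifting caudally (with extent ≥ 18 rounding alone cannot
collide; the resolver is a safety net). Endpoints are always included. The
18 slices split 6/6/6 into apical / mediastinal / diaphragmatic; any slice
count divisible by 3 is accepted for non-default configurations.

Gravitational thirds are computed, by default, from the lung mask's
anterior–posterior extent **on each slice** (configurable to one global
extent). Bands are equal thirds of the physical extent, half-open with the
ventral edge closed, so a voxel exactly on a boundary joins the more dorsal
band; a slice whose lung collapses to a single row is wholly ventral
(degenerate but total). The partition is exact: every in-mask voxel on a
selected slice belongs to exactly one of the nine ROIs, and empty ROIs are
recorded as warnings rather than silently dropped.

Native slice thickness is recorded but never enforced — selection works on
whatever grid the scan has.

## Profiles and compartments

Histograms use 220 bins of 5 HU over [−1000, +100]: bins [edge, edge+5)
with the final bin [95, 100] closed, an exact single cover of the clipped
domain. Hyperaerated is taken as [−1000, −800) and non-aerated as
[−100, +100]; the interior boundaries are bin-edge-ambiguous by ±1 bin in
principle, so they are implemented half-open on the dense side and
configurable via `compartment_percent`. Poorly- and normally-aerated
compartments (boundaries −500/−800) are optional extras. Empty ROIs yield
profiles flagged empty and NaN aeration summaries — never silent zeros.

## The focal index

The score is defined as the non-overlapping area between the ventral-apical
and dorsal-diaphragmatic HU distribution curves. The published verbal
definition normalises each curve's area to 100 *and* multiplies the
absolute-difference integral by 100, which taken literally would give a
0–20,000 scale; the stated range, however, is 0–200. We therefore treat the
curves as probability densities (unit area) and scale by 100:

FI = 100 · Σ_b |p_VA(b) − p_DD(b)| = 200 · TV(p_VA, p_DD),

which reproduces the stated endpoints exactly (0 for identical curves, 200
for disjoint supports) and equals the percent-per-bin curves summed without
the extra ×100. The discrete bin sum is the exact integral of the
piecewise-constant densities; 5-HU bins are used throughout, matching the
profile definition. Empty profiles and mismatched grids are refused.
`pairwise_focal_matrix` generalises the score to all 36 ROI pairs as a
diagnostic; only the VA–DD entry is "the" focal index.

## Quantitation

Standard quantitative-CT relations: gas fraction = max(0, −HU/1000), tissue
fraction its complement, tissue density (HU+1000)/1000 g/ml, so a voxel of
volume v ml contributes v·(−HU/1000) ml gas and v·(1+HU/1000) g weight.
Gas + tissue volume equals the masked volume identically. Whole-lung totals
linearly interpolate the per-slice quantities between analysed slices and
hold the outermost measured values constant to the lung extent ends — the
simplest scheme that is exact for constant and linear craniocaudal trends
and reproduces the direct sum when every slice is analysed.

## Cohort statistics

Correlations are Pearson by default with a Fisher-z 95 % CI and a t-test
p-value (n − 2 df); a Spearman option covers rank correlation, since the
literature this implements names both in one phrase. Cohen's kappa uses the
standard marginal expected agreement with the large-sample standard error
√(p_o(1−p_o)/n)/(1−p_e), truncated to [−1, 1]; other CI constructions for
kappa exist and can shift the bounds by a few hundredths at n ≈ 37. The
sensitivity regression is OLS with intercept on PEEP (cmH₂O), respiratory
rate (1/min) and Vt/PBW (ml/kg), reporting coefficients, p-values, R²,
adjusted R² and the overall F-test; rank-deficient designs raise an error
naming the offending columns. In the batch pipeline, a zero-variance focal
index aborts the battery, while a single constant covariate marks only its
own entry undefined.

## Phantom generator

A phantom is two ellipsoidal "lungs" (analytic geometry, no airways or
lobes) inside a +40 HU body box on a −1000 HU background, spanning exactly
18 axial slices so slice selection covers every lung slice. Each nominal
region draws i.i.d. HU values from a mixture of truncated normals on
[−1000, +100]. A single focality parameter φ blends an aerated law
(N(−850, 12) truncated to [−1000, −400]) into a consolidated law
(N(+30, 12) truncated to [−150, +100]) with weight φ·s, where the severity
s rises linearly from 0 at ventral-apical to 1 at dorsal-diaphragmatic.
Because the two default laws have disjoint supports, the analytic focal
index is exactly 200·φ, and it is nondecreasing in φ for any law pair.

Design choices worth stating:

* **Partition-consistent labelling.** Region labels are assigned with the
  pipeline's own partition operators on the true mask, so each measured ROI
  is an i.i.d. sample from its generating law and recovery error is pure
  binomial sampling noise. Slices outside the selection (none, for the
  default 18-slice lungs) would take the nearest selected slice's
  craniocaudal band; they never enter profiles.
* **Narrow default peaks.** The empirical focal index of a sampled phantom
  deviates from the analytic value by roughly
  100·√(2/n)·√(2/π)·Σ_b √p_b in the worst (identical-law) case. With 12-HU
  component SDs this bound is ≈ 1.2 at 10⁵ voxels per ROI and ≈ 3.9 at 10⁴,
  keeping sampling noise well below the index resolution being validated.
  Real ARDS profiles are broader (tens of HU per mode and often bimodal),
  so phantom recovery demonstrates correctness of the estimator, not the
  sampling error to expect on clinical scans.
* **Noise model.** Optional additive Gaussian scanner noise is applied
  after sampling and before clipping; the analytic ground truth convolves
  the law densities with the noise kernel on a 1-HU grid and folds the
  out-of-domain spill onto the edge bins, mirroring `clip_hu`.
* **Determinism.** One integer seed fully determines a phantom; identical
  configs are bit-identical.
* **Sizing.** `default_config(target_roi_voxels=n)` scales the in-plane
  semi-axes analytically so the smallest ROI (the apical/diaphragmatic
  outer-third corners of the ellipsoid) holds at least n voxels. Test and
  example phantoms use 1.5–10 k voxels per ROI; the recovery validation
  uses 100 k, where 20 phantoms run in well under a minute.

What the phantoms do **not** emulate: anatomical lobes, airways and
vessels, gravity-dependent atelectasis physics, beam hardening, partial
volume at the pleura, or respiratory-phase variation. Passing recovery
tests therefore validates the measurement chain (orientation, partition,
binning, scoring, quantitation), not clinical robustness to those factors.

## Numerical and degenerate-input policy

Histogram normalisation is exact to 1e−9; the focal index is capped at 200
against floating-point overshoot. Degenerate inputs fail loudly: empty
masks, insufficient craniocaudal extent, empty profiles, zero-variance
correlation inputs, degenerate kappa marginals, rank-deficient designs and
out-of-domain HU values all raise typed exceptions. Reports serialise with
sorted keys and fixed rounding, so identical inputs and configuration
reproduce a byte-identical report; every report embeds a configuration
digest and the package version.

## Known limitations

* The gravitational axis is taken from the header (supine assumption); no
  tilt or rotation correction is applied.
* The segmentation fallback is a generic threshold recipe, not a clinical
  tool; severe consolidation beyond the closing radius will be missed.
* Whether the gravitational thirds should follow the lung or the thoracic
  cavity, per-slice or globally, is under-determined in the source
  literature; both modes are implemented, per-slice lung extent is the
  default.
* Kappa's CI construction is one of several asymptotic variants.
* Cohort-level reference values from patient data cannot be reproduced
  without the original scans; validation rests on analytic endpoints,
  recomputable count statistics and phantom recovery.
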