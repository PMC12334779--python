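# focalindex

Quantitative CT analysis of lung-injury focality for mechanically ventilated
patients with ARDS. The package turns a thoracic CT volume and a lung mask
into regional Hounsfield-unit (HU) distribution profiles, aeration
compartments, lung weight and gas volume — and condenses the regional
heterogeneity into a single objective score, the **focal index**, intended to
replace the subjective visual dichotomy of "focal" versus "diffuse" injury
with a continuous measurement.

## The method

1. **Nine regions.** Eighteen axial slices are selected evenly over the
   lung's craniocaudal extent and split into apical, mediastinal and
   diaphragmatic thirds; within each slice the lung's ventral-to-dorsal
   extent is divided into three equal-length gravitational bands. The 3 × 3
   product gives nine three-dimensional regions of interest (ROIs).
2. **HU profiles.** Each ROI's voxel HU values (clipped to [−1000, +100];
   −1000 = gas, +100 = dense non-aerated tissue) are histogrammed into 220
   bins of 5 HU, normalised to percent of the ROI's voxels. Hyperaerated
   tissue is HU ∈ [−1000, −800), non-aerated tissue HU ∈ [−100, +100].
3. **Focal index.** With f_VA and f_DD the normalised HU distributions of
   the ventral-apical and dorsal-diaphragmatic regions — the two ends of the
   transpulmonary-pressure gradient — the score is the non-overlapping area
   between the curves,

   FI = 100 · Σ_b |p_VA(b) − p_DD(b)| = 200 · TV(p_VA, p_DD),

   where p are per-bin probability masses and TV is the total-variation
   distance. FI = 0 means identical regional aeration (diffuse injury);
   FI = 200 means completely separated distributions (maximal focality).
4. **Quantitation.** Per-voxel gas fraction −HU/1000 and tissue density
   (HU + 1000)/1000 g/ml give per-slice gas volume and lung weight, extended
   to the whole lung by linear interpolation between the analysed slices.
5. **Cohort statistics.** Pearson correlations (Fisher-z 95% CI) of the
   focal index with regional aeration, gas, weight and fluid balance;
   Cohen's kappa for two-rater agreement on the focal/diffuse call; and an
   OLS sensitivity regression of the index on ventilatory settings (PEEP,
   respiratory rate, tidal volume per predicted body weight).

A built-in phantom generator produces two-lung synthetic scans whose
regional HU laws are truncated-normal mixtures with a focality dial
φ ∈ [0, 1] and an analytically known focal index (200 · φ for the default
laws), so the full pipeline is testable without patient data.

## Worked example

```python
import focalindex as fx

config = fx.default_config(phi=0.8, seed=11, target_roi_voxels=10_000)
volume, mask, truth = fx.generate_phantom(config)
report = fx.run_scan_arrays(volume, mask)
print(f"analytic focal index : {truth.analytic_fi:7.2f}")
print(f"measured focal index : {report.focal_index.value:7.2f}")
print(f"overlap of curves    : {report.focal_index.overlap_percent:7.2f} %")
```

prints

```
analytic focal index :  160.00
measured focal index :  158.61
overlap of curves    :   20.69 %
```

With φ = 0.8 the dorsal-diaphragmatic law carries 80 % consolidated mass, so
the true non-overlap score is 160 of 200; the measured value differs only by
voxel-sampling noise, and ~21 % of the probability mass of the two curves
still overlaps. The scripts in `examples/` walk through each capability
(per-scan scoring, regional profiles and the pairwise focality matrix, gas
and weight quantitation, cohort statistics).

The same pipeline is available from the shell:

```bash
focalindex run --ct scan.nii.gz --mask lung.nii.gz --out report.json
focalindex cohort --manifest cohort.csv --out-dir results/
focalindex phantom --out-dir phantoms/ --phi 1.0 --seed 7
```

ROI label images use integer codes 1–9 in craniocaudal-major order
(1 = ventral-apical … 9 = dorsal-diaphragmatic).

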