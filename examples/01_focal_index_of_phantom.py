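"""Score the focality of a synthetic scan.

Generates a phantom whose ventral-apical region stays aerated while
consolidation grows toward the dorsal-diaphragmatic corner (phi = 0.8),
runs the full pipeline, and prints the focal index next to its analytic
ground truth.
"""

import focalindex as fx

config = fx.default_config(phi=0.8, seed=11, target_roi_voxels=10_000)
volume, mask, truth = fx.generate_phantom(config)
report = fx.run_scan_arrays(volume, mask)

va = report.aeration[fx.VENTRAL_APICAL]
dd = report.aeration[fx.DORSAL_DIAPHRAGMATIC]

print(f"analytic focal index : {truth.analytic_fi:7.2f}")
print(f"measured focal index : {report.focal_index.value:7.2f}")
print(f"overlap of curves    : {report.focal_index.overlap_percent:7.2f} %")
print(f"VA hyperaerated      : {va.hyper_percent:7.2f} %   VA non-aerated: {va.nonaer_percent:6.2f} %")
print(f"DD hyperaerated      : {dd.hyper_percent:7.2f} %   DD non-aerated: {dd.nonaer_percent:6.2f} %")

# The focal index is 200 x the total-variation distance between the two
# regional HU distributions: 0 = identical curves (diffuse), 200 = fully
# separated curves (focal). Here phi = 0.8 puts 80% consolidated mass in the
# dorsal-diaphragmatic law, so the analytic score is 160; the measured value
# differs only by sampling noise. The aeration lines show the same story:
# the ventral apex is hyperaerated, the dorsal base mostly non-aerated.
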