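"""Detect cell clusters on one synthetic slide and export annotations.

Runs the detection chain (downsample 3x, grayscale, fixed threshold 210,
connected components, area filter) on a generated case and writes the
resulting polygons as GeoJSON in full-resolution pixel coordinates.
"""

from pathlib import Path

from lbcquant import CohortSpec, DetectionParams, detect_clusters, generate_cohort
from lbcquant.io import write_annotations

case = generate_cohort(CohortSpec(n_normal=1, n_lesion=0, seed=7))[0]
params = DetectionParams(min_area_px=50, max_area_px=10**8)
annotations = detect_clusters(case, params)

print(f"case {case.case_id}: {len(annotations)} clusters at mpp={case.mpp:.3f}")
for ann in annotations:
    print(
        f"  {ann.cluster_id}: area {ann.area_px:8.0f} px "
        f"= {ann.area_um2:7.0f} um^2, {len(ann.polygon)} vertices"
    )

out = Path("scratch_annotations.geojson")
write_annotations(annotations, out)
print(f"\nwrote {out} (polygon areas are in full-resolution pixels; um^2\n"
      "uses the case's microns-per-pixel calibration squared)")
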