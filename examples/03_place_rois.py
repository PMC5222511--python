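"""Fit the optic-disc ellipse and place the five peripapillary ROIs.

The disc margin comes from manually clicked points (here: points sampled
from a known ellipse); the five ~2x2-degree ROIs (superior, superotemporal,
temporal, inferotemporal, inferior) are centred one degree plus half a box
side outside the fitted margin along radial directions.
"""

import numpy as np

from octavg import ScaleModel, fit_ellipse, icd_sampling_box, place_rois

scale = ScaleModel()
# clicked margin points of a slightly elliptical disc at (152, 120)
angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
points = np.column_stack([152 + 24 * np.sin(angles), 120 + 28 * np.cos(angles)])

disc = fit_ellipse(points)
print(f"disc centre (row, col): ({disc.center_px[0]:.1f}, {disc.center_px[1]:.1f})")
print(f"semi-axes: {disc.semi_axes_px[0]:.1f} x {disc.semi_axes_px[1]:.1f} px, "
      f"fit RMS {disc.rms_residual_px:.2e} px")

for roi in place_rois(disc, scale, laterality="OD", image_shape=(304, 304)):
    status = f"EXCLUDED ({roi.exclusion_reason})" if roi.excluded else "ok"
    print(f"  {roi.label:>2}: box {roi.box}, vessels at "
          f"{roi.vessel_orientation_deg:.0f} deg, {status}")
    if not roi.excluded:
        box = icd_sampling_box(roi, scale)
        # the 3 x 30 px sampling box lies perpendicular to the vessels
        print(f"      ICD box: {box.width_px}x{box.length_px} px, "
              f"profile axis at {box.long_axis_deg:.0f} deg")
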