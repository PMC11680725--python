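"""Measure edge sharpness with the sigmoid rise-distance metric.

Builds a curved-edge phantom with known steepness, samples perpendicular
intensity profiles along the curve, fits the sigmoid edge model and reports
the 10-90% rise distance in millimetres, before and after blurring.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from selfgate import synth
from selfgate.sharpness import image_sharpness

FOV_MM, BASE_RES = 220.0, 220  # 1 mm pixels
pts = [[10.0, 32.0], [25.0, 29.0], [40.0, 35.0], [54.0, 32.0]]
img = synth.make_edge_phantom(
    a0_px=0.0, a1=100.0, a2=10.0, s=0.5, image_size=64, curve_control_points=pts
)

expected = FOV_MM / BASE_RES * 2 * np.log10(9) / 0.5
med, rds, _ = image_sharpness(img, pts, FOV_MM, BASE_RES, n_lines=12, half_length_px=8)
print(f"generating steepness    : s = 0.5 per px -> closed-form RD {expected:.3f} mm")
print(f"measured median RD      : {med:.3f} mm over {len(rds)} lines")

blurred = gaussian_filter(img, 1.5)
med_b, _, _ = image_sharpness(blurred, pts, FOV_MM, BASE_RES, n_lines=12, half_length_px=8)
print(f"after 1.5 px blur       : {med_b:.3f} mm")
print(
    "\nA shorter rise distance means a sharper blood-myocardium interface;\n"
    "blurring widens the fitted sigmoid and the metric grows accordingly."
)
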