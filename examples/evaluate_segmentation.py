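"""Segmentation agreement metrics on synthetic mask pairs.

DSC measures voxel overlap; ASD measures the mean physical (mm)
distance between mask surfaces under the anisotropic voxel spacing, and
is the more sensitive of the two to boundary errors.
"""

import numpy as np
from scipy import ndimage

from npcstage.metrics import asd, dsc, score_cohort

rng = np.random.default_rng(0)
spacing = (6.0, 0.5, 0.5)

truth = np.zeros((8, 40, 40), np.uint8)
truth[2:6, 10:30, 10:30] = 1

inplane = np.zeros((3, 3, 3), bool)
inplane[1] = ndimage.generate_binary_structure(2, 1)
cases = []
pred = truth.copy()
for i in range(4):
    cases.append((f"erosion_{i}", pred.copy(), truth, spacing))
    print(f"erosion {i}: DSC {dsc(pred, truth):.3f}, "
          f"ASD {asd(pred, truth, spacing):.3f} mm")
    pred = ndimage.binary_erosion(pred, structure=inplane).astype(np.uint8)

report = score_cohort(cases, n_boot=2000, seed=0)
d, a = report["dsc"], report["asd_mm"]
print(f"\ncohort: median DSC {d['median']:.3f} (IQR {d['iqr']:.3f}, "
      f"95% CI {d['ci'][0]:.3f}-{d['ci'][1]:.3f})")
print(f"        median ASD {a['median']:.3f} mm (IQR {a['iqr']:.3f})")
# Interpretation: each in-plane erosion peels one 0.5 mm rim off the
# prediction, so DSC falls and ASD grows by roughly half the rim width
# per step -- the two metrics move oppositely on nested contours.
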