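"""Run one phantom through the preprocessing chain used for training.

The chain resamples to a target voxel spacing (third-order spline
in-plane, nearest neighbour across slices; masks nearest-neighbour
everywhere), z-score normalises the intensities and crops to a fixed
grid centred on the tumor.
"""

from npcstage.phantoms import PhantomConfig, generate_cohort
from npcstage.preprocess import preprocess_case, stratified_kfold

cases = generate_cohort(PhantomConfig(), n=8, seed=3)
case = cases[0]

img, msk = preprocess_case(case.image, case.mask, case.spacing,
                           target_spacing=(6.0, 1.0, 1.0), target_shape=(12, 24, 24))
print(f"raw:       shape {case.image.shape}, spacing {case.spacing} mm, "
      f"tumor {int(case.mask.sum())} voxels")
print(f"processed: shape {img.shape}, spacing (6.0, 1.0, 1.0) mm, "
      f"tumor {int(msk.sum())} voxels")
print(f"intensities: mean {img.mean():+.4f}, sd {img.std():.4f}  (z-scored)")

labels = {c.case_id: c.stage for c in cases}
split = stratified_kfold(labels, k=2, seed=0)
print("fold assignment:", dict(sorted(split.folds.items())))
# Interpretation: in-plane resolution halves (0.5 -> 1 mm) so the tumor
# voxel count drops ~4x; slices are untouched; each fold carries a
# near-equal share of every stage.
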