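"""Generate a small synthetic phantom cohort and inspect its structure.

Each case is an anisotropic 3D volume (16 x 64 x 64 voxels at
6 x 0.5 x 0.5 mm) holding a bright connected tumor grown inside nested
anatomical shells; the T-stage label (1-4) records the deepest shell
band the tumor invades, so stage is statistically tied to tumor bulk.
"""

from collections import Counter

import numpy as np

from npcstage.phantoms import PhantomConfig, generate_cohort

config = PhantomConfig()
cases = generate_cohort(config, n=40, seed=7, out_dir="scratch_phantoms")

print("stage counts:", dict(sorted(Counter(c.stage for c in cases).items())))
for stage in (1, 2, 3, 4):
    vols = [int(c.mask.sum()) for c in cases if c.stage == stage]
    if vols:
        print(f"  T{stage}: {len(vols):2d} cases, tumor volume "
              f"{min(vols)}-{max(vols)} voxels (mean {np.mean(vols):.0f})")

case = cases[0]
print(f"\nfirst case: id={case.case_id} stage=T{case.stage} "
      f"volume={int(case.mask.sum())} voxels, image range "
      f"[{case.image.min():.2f}, {case.image.max():.2f}]")
print("NIfTI image/mask pairs and manifest.csv written to scratch_phantoms/")
# Interpretation: counts follow the configured 8/44/27/21% stage mixture,
# and mean tumor volume rises with stage -- the signal the staging
# network must learn.
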