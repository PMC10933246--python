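"""Simulate a test-retest DMI study and look at its ground truth.

Builds the default six-subject, two-session study on a 10x10x10 grid:
a parametric brain atlas with external reference phantoms, per-exam
concentration truth with subject/session variance components, and raw CSI
free induction decays (700 points, 5 kHz).
"""

import numpy as np

from dmikit import make_study

study = make_study(seed=1)

print("atlas regions and voxel counts:")
for name, n in study.atlas.voxel_counts().items():
    print(f"  {name:13s} {n:4d}")

truth = study.truth.frame
glx = truth[(truth.metabolite == "glx") & (truth.timepoint_min == 120.0)]
print(f"\nGlx at 120 min across subjects/sessions/regions: "
      f"{glx.conc_mm.mean():.2f} +/- {glx.conc_mm.std():.2f} mM")
print("(population curve peaks near 3.2 mM; the spread reflects the "
      "configured 18% between- and 9% within-subject CoVs plus regional variation)")

grid = study.exam_grid(subject=0, session=0, timepoint_min=120.0)
print(f"\nraw CSI grid: shape {grid.data.shape}, noise sd {study.noise_sd:.2f} "
      f"(calibrated for whole-brain water SNR ~14 at 120 min)")
voxel = tuple(np.argwhere(study.atlas.region_mask('thalamus'))[0])
print(f"thalamus voxel FID starts at |{abs(grid.data[voxel][0]):.1f}| signal units")
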