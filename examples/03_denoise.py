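"""MP-PCA denoising: how much of the noise does rank truncation remove?

Sliding 3x3x3 patches are unfolded into Casorati matrices (27 voxels x 700
spectral points); the retained rank per patch is chosen by comparing the
eigenvalue tail to the Marchenko-Pastur law for pure noise.  The noise-free
synthesis of the same exam provides the ground truth.
"""

import numpy as np

from dmikit import denoise_grid, make_study

study = make_study(seed=3)
noisy = study.exam_grid(0, 0, 120.0)
clean = study.exam_grid(0, 0, 120.0, noise=False)

denoised, info = denoise_grid(noisy, return_info=True)

rmse = lambda g: np.sqrt(np.mean(np.abs(g.data - clean.data) ** 2))
before, after = rmse(noisy), rmse(denoised)
ranks = info["rank_map"][info["rank_map"] >= 0]
print(f"FID RMSE to ground truth: {before:.3f} -> {after:.3f} "
      f"({100 * (1 - after / before):.0f}% reduction)")
print(f"selected ranks: median {int(np.median(ranks))}, max {ranks.max()} — "
      "background patches are pure noise (rank ~0); patches inside the brain "
      "keep the few components spanned by the four resonances")
sigma2 = np.nanmedian(info["noise_variance_map"])
print(f"estimated complex noise variance {sigma2:.1f} "
      f"(true: {2 * study.noise_sd**2:.1f})")
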