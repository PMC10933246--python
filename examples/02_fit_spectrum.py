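"""Fit one voxel's spectrum and read the quality metrics.

Reconstructs a brain voxel's spectrum (FFT, zero-filled twice, no line
broadening) and fits the four deuterium resonances in the time domain with
prior knowledge: bounded frequencies around the literature shifts, bounded
Lorentzian linewidths, shared zero-order phase.
"""

import numpy as np

from dmikit import fit_voxel, make_study, reconstruct_spectrum, spectrum_metrics

study = make_study(seed=1)
grid = study.exam_grid(0, 0, 120.0)
voxel = tuple(np.argwhere(study.atlas.region_mask("thalamus"))[0])
fid = grid.data[voxel]

spec = reconstruct_spectrum(fid, grid.acq)
snr, fwhm = spectrum_metrics(spec, peak_window_hz=(-15, 15))
print(f"water spectral SNR {snr:.1f}, linewidth {fwhm:.1f} Hz "
      f"(QC keeps voxels with SNR > 5 and linewidth <= 30 Hz)")

fit = fit_voxel(fid, study.priors, grid.acq)
print(f"converged: {fit.converged}\n")
print(f"{'resonance':9s} {'amp':>7s} {'freq Hz':>8s} {'FWHM Hz':>8s} {'CRLB %':>7s}")
for name in fit.names:
    r = fit[name]
    print(f"{name:9s} {r['amplitude']:7.2f} {r['frequency_hz']:8.1f} "
          f"{r['fwhm_hz']:8.1f} {r['crlb_percent']:7.1f}")
print("\nCRLB% is the minimum relative amplitude uncertainty at this noise "
      "level; water is tightest, the overlapping Glx/lactate pair loosest.")
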