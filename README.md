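# dmikit

Deuterium metabolic imaging (DMI) measures the uptake of orally administered
²H-labelled glucose and its conversion to glutamate+glutamine (Glx), lactate
and water, through the ²H resonance on a clinical MR system. Whether DMI can
serve as a treatment-response biomarker hinges on its **test–retest
repeatability**: how large a change in a metabolite map is real rather than
measurement noise.

`dmikit` is a Python library for studying exactly that question end to end on
synthetic data. It simulates complete scan–rescan DMI studies — a label
atlas, ground-truth concentration dynamics with explicit subject/session
variance components, and raw chemical-shift-imaging FIDs (10×10×10 × 700
points at 5 kHz) — and analyses them with the full processing chain:

* FFT reconstruction (zero-filled, no apodization) and spectrum metrics;
* Marchenko–Pastur PCA denoising with automatic rank selection;
* prior-knowledge time-domain fitting of the four ²H resonances
  (bounded least squares on damped complex exponentials), Cramér–Rao lower
  bounds, and the water SNR > 5 / linewidth ≤ 30 Hz voxel QC;
* saturation correction, Richardson–Lucy partial-volume correction,
  bias-field correction, and three quantification modes (baseline
  natural-abundance water, external phantoms, internal cerebellum);
* the repeatability statistics:

      between-subject CoV = SD / mean
      within-subject CoV  = SD(Exam₂ − Exam₁) / √2 / mean
      repeatability coefficient = 1.96 · √2 · within-subject CoV

It is aimed at people designing or evaluating DMI protocols who want a tested
reference implementation of the analysis chain and a sandbox in which every
stage can be validated against known ground truth.

## Worked example

```python
from dmikit import make_study, fit_voxel, reconstruct_spectrum, spectrum_metrics
import numpy as np

study = make_study(seed=1)                      # 6 subjects x 2 sessions x 4 timepoints
grid = study.exam_grid(0, 0, 120.0)             # one raw CSI exam at 120 min
voxel = tuple(np.argwhere(study.atlas.region_mask("thalamus"))[0])

spec = reconstruct_spectrum(grid.data[voxel], grid.acq)
snr, fwhm = spectrum_metrics(spec, peak_window_hz=(-15, 15))
fit = fit_voxel(grid.data[voxel], study.priors, grid.acq)
print(f"water SNR {snr:.1f}, linewidth {fwhm:.1f} Hz")
for name in fit.names:
    r = fit[name]
    print(f"{name:8s} amp {r['amplitude']:6.2f}  CRLB {r['crlb_percent']:.1f}%")
```

prints (seed 1):

```
water SNR 14.6, linewidth 9.2 Hz
water    amp   6.06  CRLB 7.1%
glucose  amp   2.21  CRLB 14.9%
glx      amp   1.62  CRLB 26.8%
lactate  amp   0.49  CRLB 120.1%
```

The voxel passes QC (SNR > 5, linewidth ≤ 30 Hz); the CRLB column is the
minimum relative amplitude uncertainty at this noise level and reproduces the
characteristic hierarchy water ≪ glucose < Glx < lactate. The `examples/`
scripts walk through each capability: study simulation, spectral fitting,
denoising, quantification, and the repeatability tables. A thin CLI
(`dmikit simulate|process|stats|all`) runs the same pipeline from a YAML
config and writes NIfTI maps, tidy CSV tables, and a JSON run manifest.

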