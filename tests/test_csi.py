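"""CSI synthesis: signal model, linearity, SNR calibration."""

import numpy as np
import pytest

from dmikit import (
    AcquisitionParams,
    StudyDesign,
    VarianceParams,
    default_priors,
    make_study,
    synthesize_csi,
)
from dmikit.pipeline import water_snr_spectral
from dmikit.simulate.csi import b1_field, calibrate_noise_sd
from dmikit.spectral import reconstruct_spectrum


def _water_only(atlas, conc):
    regions = atlas.composites["whole_brain"]
    return {"water": {r: conc for r in regions}}


def test_noiseless_fid_starts_at_summed_amplitude(acq6, atlas6, priors):
    vp = VarianceParams()
    grid = synthesize_csi(_water_only(atlas6, 10.0), atlas6, acq6, vp, priors, noise_sd=0.0)
    voxel = np.argwhere(atlas6.region_mask("thalamus"))[0]
    fid = grid.data[tuple(voxel)]
    sat = 0.4587  # water steady-state factor at 70 deg / 155.8 ms / 320 ms
    assert fid[0].real == pytest.approx(10.0 * sat, rel=1e-3)
    assert fid[0].imag == pytest.approx(0.0, abs=1e-9)


def test_spectrum_linear_in_concentration(acq6, atlas6, priors):
    vp = VarianceParams()
    conc1 = {"glucose": {r: 2.0 for r in atlas6.composites["whole_brain"]}}
    conc2 = {"glucose": {r: 4.0 for r in atlas6.composites["whole_brain"]}}
    g1 = synthesize_csi(conc1, atlas6, acq6, vp, priors, noise_sd=0.0)
    g2 = synthesize_csi(conc2, atlas6, acq6, vp, priors, noise_sd=0.0)
    voxel = tuple(np.argwhere(atlas6.brain_mask)[0])
    s1 = reconstruct_spectrum(g1.data[voxel], acq6)
    s2 = reconstruct_spectrum(g2.data[voxel], acq6)
    glucose_hz = priors[1].center_frequency_hz
    band = np.abs(s1.frequency_hz - glucose_hz) < 10
    assert s2.magnitude[band].max() == pytest.approx(2 * s1.magnitude[band].max(), rel=1e-9)


def test_phantom_voxels_contain_only_water(acq6, atlas6, priors):
    vp = VarianceParams()
    conc = {m: {r: 3.0 for r in atlas6.composites["whole_brain"]}
            for m in ("water", "glucose", "glx", "lactate")}
    grid = synthesize_csi(conc, atlas6, acq6, vp, priors, noise_sd=0.0)
    ph = tuple(np.argwhere(atlas6.region_mask("phantom_low"))[0])
    br = tuple(np.argwhere(atlas6.region_mask("thalamus"))[0])
    spec_ph = reconstruct_spectrum(grid.data[ph], acq6)
    spec_br = reconstruct_spectrum(grid.data[br], acq6)
    glx_band = np.abs(spec_ph.frequency_hz - priors[2].center_frequency_hz) < 8
    water_band = np.abs(spec_ph.frequency_hz) < 8
    assert spec_ph.magnitude[water_band].max() > 5  # water present
    # the phantom's Glx band holds only the water wing, far below a brain
    # voxel's actual Glx peak
    assert spec_ph.magnitude[glx_band].max() < 0.35 * spec_br.magnitude[glx_band].max()


def test_unknown_metabolite_rejected(acq6, atlas6, priors):
    with pytest.raises(ValueError, match="unknown metabolites"):
        synthesize_csi({"citrate": {"frontal": 1.0}}, atlas6, acq6,
                       VarianceParams(), priors, noise_sd=0.0)


def test_b1_field_shape():
    b1 = b1_field((10, 10, 10), 0.07)
    center = b1[5, 5, 5]
    corner = b1[0, 0, 0]
    assert center < corner <= 1.07
    assert center == pytest.approx(1.0, abs=0.01)


def test_calibrated_noise_hits_target_water_snr():
    """Whole-brain water SNR at 120 min lands within 20% of the calibration
    target (median over 50 simulated exams)."""
    acq = AcquisitionParams(matrix=(6, 6, 6))
    design = StudyDesign(timepoints_min=(0.0, 120.0), seed=9)
    vp = VarianceParams()
    snrs = []
    for seed in range(50):
        study = make_study(design=design, acq=acq, vp=vp, seed=seed)
        grid = study.exam_grid(0, 0, 120.0)
        snr = water_snr_spectral(grid)
        snrs.append(np.mean(snr[study.atlas.brain_mask]))
    assert np.median(snrs) == pytest.approx(vp.target_water_snr, rel=0.20)


def test_study_is_bit_reproducible(acq6):
    design = StudyDesign(timepoints_min=(0.0, 120.0), seed=21)
    s1 = make_study(design=design, acq=acq6, seed=21)
    s2 = make_study(design=design, acq=acq6, seed=21)
    assert s1.truth.frame.equals(s2.truth.frame)
    assert np.array_equal(s1.b1_beta, s2.b1_beta)
    g1 = s1.exam_grid(2, 1, 120.0)
    g2 = s2.exam_grid(2, 1, 120.0)
    assert np.array_equal(g1.data, g2.data)
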