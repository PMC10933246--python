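"""Map corrections, quantification modes, regional aggregation."""

import math

import numpy as np
import pytest

from dmikit import (
    CorrectionConfig,
    MetaboliteMap,
    bias_field_correct,
    csi_psf,
    fourier_interpolate,
    partial_volume_correct,
    quantify,
    regional_means,
    saturation_correct,
    saturation_factor,
)
from dmikit.maps import PhantomCalibrationWarning, estimate_bias_field


# -- saturation --------------------------------------------------------------


def test_fully_relaxed_90_degree_pulse_needs_no_correction():
    assert saturation_factor(90.0, 10.0, 0.3) == pytest.approx(1.0, abs=1e-4)


def test_steady_state_factor_matches_hand_evaluation():
    # s = sin(70) (1 - E1) / (1 - cos(70) E1), E1 = exp(-0.1558/0.320)
    e1 = math.exp(-0.1558 / 0.320)
    expected = math.sin(math.radians(70)) * (1 - e1) / (1 - math.cos(math.radians(70)) * e1)
    assert saturation_factor(70.0, 0.1558, 0.320) == pytest.approx(expected, rel=1e-12)
    cfg = CorrectionConfig()
    assert saturation_correct(1.0, "water", cfg) == pytest.approx(1 / expected, rel=1e-12)


def test_short_t1_limit_is_sin_alpha():
    assert saturation_factor(70.0, 0.1558, 1e-6) == pytest.approx(
        math.sin(math.radians(70)), rel=1e-6
    )


# -- Richardson-Lucy ---------------------------------------------------------


def _delta_psf():
    psf = np.zeros((3, 3, 3))
    psf[1, 1, 1] = 1.0
    return psf


def test_rl_identity_kernel_is_identity(rng):
    vals = rng.random((8, 8, 8))
    m = MetaboliteMap("water", vals)
    out = partial_volume_correct(m, _delta_psf(), n_iter=10)
    assert np.allclose(out.values, vals)


def test_rl_conserves_flux(rng):
    m = MetaboliteMap("water", rng.random((8, 8, 8)))
    out = partial_volume_correct(m, csi_psf(), n_iter=15)
    assert out.values.sum() == pytest.approx(m.values.sum(), rel=1e-6)
    assert out.values.min() >= 0


def test_rl_restores_blurred_point_source():
    from scipy import ndimage

    truth = np.zeros((9, 9, 9))
    truth[4, 4, 4] = 100.0
    psf = csi_psf(shape="gauss", sigma_vox=0.8)
    blurred = ndimage.convolve(truth, psf, mode="wrap")
    assert blurred.max() <= 0.5 * truth.max()
    restored = partial_volume_correct(MetaboliteMap("glx", blurred), psf, n_iter=20)
    assert restored.values.max() >= 0.8 * truth.max()


def test_rl_zero_sum_psf_rejected():
    with pytest.raises(ValueError, match="positive sum"):
        partial_volume_correct(MetaboliteMap("water", np.ones((4, 4, 4))),
                               np.zeros((3, 3, 3)))


# -- bias field --------------------------------------------------------------


def test_flat_map_unchanged_by_bias_correction():
    m = MetaboliteMap("water", np.full((8, 8, 8), 7.0))
    out = bias_field_correct(m)
    assert np.allclose(out.values, 7.0, atol=1e-8)


def test_linear_gradient_bias_removed(atlas10):
    rngv = np.random.default_rng(0)
    truth = 10.0 * (1 + 0.02 * rngv.standard_normal(atlas10.shape))
    x = np.linspace(-0.5, 0.5, atlas10.shape[0])[:, None, None]
    bias = 1 + 0.2 * np.broadcast_to(x, atlas10.shape)
    mask = atlas10.brain_mask
    m = MetaboliteMap("water", truth * bias, mask=mask)
    out = bias_field_correct(m, order=2)
    ratio_before = (truth * bias / truth)[mask]
    ratio_after = (out.values / truth)[mask]
    cov = lambda r: r.std() / r.mean()
    assert cov(ratio_after) < 0.5 * cov(ratio_before)
    assert out.values[mask].mean() == pytest.approx(m.values[mask].mean(), rel=1e-9)


def test_bias_field_needs_enough_voxels():
    mask = np.zeros((6, 6, 6), dtype=bool)
    mask[0, 0, :3] = True
    with pytest.raises(ValueError, match="too small"):
        estimate_bias_field(np.ones((6, 6, 6)), mask, order=2)


# -- Fourier interpolation ---------------------------------------------------


def test_fourier_interpolation_identity_and_constant():
    vals = np.random.default_rng(3).random((6, 6, 6))
    assert np.allclose(fourier_interpolate(vals, (6, 6, 6)), vals)
    const = np.full((6, 6, 6), 3.3)
    up = fourier_interpolate(const, (12, 12, 12))
    assert np.allclose(up, 3.3, atol=1e-10)


def test_fourier_interpolation_exact_for_sinusoid():
    n, m = 10, 25
    x = np.arange(n) / n
    vals = 2 + np.sin(2 * np.pi * 2 * x)  # k = 2 < Nyquist
    vol = np.broadcast_to(vals[:, None, None], (n, 6, 6)).copy()
    up = fourier_interpolate(vol, (m, 6, 6))
    xm = np.arange(m) / m
    expected = 2 + np.sin(2 * np.pi * 2 * xm)
    assert np.max(np.abs(up[:, 0, 0] - expected)) < 1e-6
    assert up.mean() == pytest.approx(vol.mean(), rel=1e-12)


def test_fourier_downsampling_rejected():
    with pytest.raises(ValueError, match="smaller"):
        fourier_interpolate(np.ones((8, 8, 8)), (4, 8, 8))


# -- quantification ----------------------------------------------------------


@pytest.fixture
def exam_maps(atlas6):
    rngv = np.random.default_rng(5)
    maps = {}
    for name, level in [("water", 16.0), ("glucose", 3.0), ("glx", 2.5), ("lactate", 1.5)]:
        vals = np.zeros(atlas6.shape)
        mask = atlas6.brain_mask | atlas6.phantom_mask
        vals[mask] = level * (1 + 0.05 * rngv.standard_normal(mask.sum()))
        vals[atlas6.region_mask("phantom_low")] = 6.4
        vals[atlas6.region_mask("phantom_high")] = 19.15
        if name != "water":
            vals[atlas6.phantom_mask] = 0.0
        maps[name] = MetaboliteMap(name, vals, "au", mask)
    return maps


def test_cerebellum_mode_self_normalizes(exam_maps, atlas6):
    out = quantify(exam_maps, "cerebellum", atlas6, CorrectionConfig())
    cereb = atlas6.region_mask("cerebellum")
    for qm in out.values():
        if qm.mask.any():
            assert qm.values[cereb & qm.mask].mean() == pytest.approx(1.0, rel=1e-12)
            assert qm.units == "ratio"


def test_phantom_mode_recovers_anchor_concentrations(exam_maps, atlas6):
    out = quantify(exam_maps, "phantom", atlas6, CorrectionConfig())
    lo = atlas6.region_mask("phantom_low")
    hi = atlas6.region_mask("phantom_high")
    assert out["water"].values[lo].mean() == pytest.approx(6.4, rel=1e-9)
    assert out["water"].values[hi].mean() == pytest.approx(19.15, rel=1e-9)
    assert out["water"].units == "mM"


def test_phantom_intercept_warning(exam_maps, atlas6):
    bad = {k: MetaboliteMap(k, v.values.copy(), "au", v.mask.copy())
           for k, v in exam_maps.items()}
    lo = atlas6.region_mask("phantom_low")
    bad["water"].values[lo] = 1.0  # breaks the through-origin line
    with pytest.warns(PhantomCalibrationWarning):
        quantify(bad, "phantom", atlas6, CorrectionConfig())


def test_baseline_mode_round_trip(atlas6):
    """Noiseless generative round trip: baseline quantification recovers the
    simulated concentrations within 5%."""
    cfg = CorrectionConfig()
    brain = atlas6.brain_mask
    base_water = np.zeros(atlas6.shape)
    base_water[brain] = cfg.natural_abundance_hdo_mm
    truth = {"water": 16.0, "glucose": 3.0, "glx": 2.5, "lactate": 1.5}
    maps = {
        name: MetaboliteMap(name, np.where(brain, c, 0.0), "au", brain)
        for name, c in truth.items()
    }
    out = quantify(maps, "baseline", atlas6, cfg,
                   baseline_water=MetaboliteMap("water", base_water, "au", brain))
    for name, c in truth.items():
        got = out[name].values[brain & out[name].mask].mean()
        assert got == pytest.approx(c, rel=0.05)
        assert out[name].units == "mM"


def test_baseline_mode_requires_reference(exam_maps, atlas6):
    with pytest.raises(ValueError, match="baseline"):
        quantify(exam_maps, "baseline", atlas6, CorrectionConfig())


def test_double_quantification_rejected(exam_maps, atlas6):
    once = quantify(exam_maps, "cerebellum", atlas6, CorrectionConfig())
    with pytest.raises(ValueError, match="already quantified"):
        quantify(once, "cerebellum", atlas6, CorrectionConfig())


# -- regional means ----------------------------------------------------------


def test_regional_means_constant_map(atlas6):
    m = MetaboliteMap("water", np.full(atlas6.shape, 4.2))
    table = regional_means(m, atlas6)
    assert np.allclose(table["mean"], 4.2)


def test_regional_mean_respects_qc_mask(atlas6):
    vals = np.zeros(atlas6.shape)
    region = atlas6.region_mask("frontal")
    idx = np.argwhere(region)
    vals[region] = 1.0
    vals[tuple(idx[0])] = 7.0
    mask = region.copy()
    mask[tuple(idx[1])] = False  # one frontal voxel QC-excluded
    m = MetaboliteMap("glucose", vals, "au", mask)
    table = regional_means(m, atlas6).set_index("region")
    kept = [tuple(i) for i in idx if mask[tuple(i)]]
    brute = np.mean([vals[i] for i in kept])
    assert table.loc["frontal", "mean"] == pytest.approx(brute, rel=1e-12)
    assert table.loc["frontal", "n_voxels"] == len(kept)


def test_fully_excluded_region_reported_missing(atlas6):
    m = MetaboliteMap("glx", np.ones(atlas6.shape),
                      mask=~atlas6.region_mask("thalamus"))
    table = regional_means(m, atlas6).set_index("region")
    assert np.isnan(table.loc["thalamus", "mean"])
    assert table.loc["thalamus", "n_voxels"] == 0
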