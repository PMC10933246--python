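"""FID model, FFT reconstruction, and spectrum metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmikit import AcquisitionParams, fid_model, reconstruct_spectrum, spectrum_metrics
from dmikit.spectral import default_noise_window, fwhm_hz


def test_model_at_origin_is_amplitude_sum(acq):
    t = acq.time_axis()
    fid = fid_model([1.0, 2.5, 0.5], [0.0, -20.0, -50.0], [30.0, 30.0, 40.0],
                    [0.0, 0.0, 0.0], t)
    assert fid[0] == pytest.approx(4.0)


@given(a=st.floats(0.1, 50), d=st.floats(0.0, 100))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_single_component_modulus_decays_exponentially(a, d):
    t = np.linspace(0, 0.1, 64)
    fid = fid_model([a], [-37.0], [d], [1.1], t)
    assert np.allclose(np.abs(fid), a * np.exp(-d * t), rtol=1e-12)


def test_mismatched_parameter_lengths_raise(acq):
    with pytest.raises(ValueError, match="equal length"):
        fid_model([1.0, 2.0], [0.0], [1.0], [0.0], acq.time_axis())


def test_lorentzian_peak_height_and_fwhm(acq):
    """FFT of one noiseless damped exponential matches the closed-form
    Lorentzian: peak ~ a/(1 - exp(-d dt)) and FWHM ~ d/pi Hz."""
    a, d = 3.0, 40.0
    fid = fid_model([a], [0.0], [d], [0.0], acq.time_axis())
    spec = reconstruct_spectrum(fid, acq, zero_fill_doublings=3)
    peak = spec.magnitude.max()
    expected_peak = a / (1 - np.exp(-d * acq.dwell_s))
    assert peak == pytest.approx(expected_peak, rel=0.01)
    snr_mask = np.abs(spec.frequency_hz) < 50
    width = fwhm_hz(spec.frequency_hz, spec.magnitude, snr_mask)
    assert width == pytest.approx(d / np.pi, rel=0.05)


@pytest.mark.parametrize(
    "mode,doublings,expected", [("doublings", 2, 2800), ("doublings", 0, 700),
                                ("append", 2, 2100)]
)
def test_zero_fill_lengths(acq, mode, doublings, expected):
    fid = np.ones(700, dtype=complex)
    spec = reconstruct_spectrum(fid, acq, doublings, mode)
    assert spec.values.size == expected


def test_delta_fid_gives_flat_magnitude(acq):
    fid = np.zeros(700, dtype=complex)
    fid[0] = 1.0
    spec = reconstruct_spectrum(fid, acq, zero_fill_doublings=0)
    assert np.allclose(spec.magnitude, 1.0)


def test_parseval_under_unnormalized_forward_fft(acq, rng):
    fid = rng.standard_normal(700) + 1j * rng.standard_normal(700)
    spec = reconstruct_spectrum(fid, acq, zero_fill_doublings=0)
    assert np.sum(np.abs(fid) ** 2) == pytest.approx(
        np.sum(np.abs(spec.values) ** 2) / 700, rel=1e-12
    )


def test_fft_round_trip_recovers_fid(acq, rng):
    fid = rng.standard_normal(700) + 1j * rng.standard_normal(700)
    spec = reconstruct_spectrum(fid, acq, zero_fill_doublings=0)
    back = np.fft.ifft(np.fft.ifftshift(spec.values))
    assert np.max(np.abs(back - fid)) / np.max(np.abs(fid)) < 1e-10


def test_zero_filling_preserves_peak_integral(acq):
    fid = fid_model([2.0], [-30.0], [50.0], [0.3], acq.time_axis())
    s0 = reconstruct_spectrum(fid, acq, 0)
    s2 = reconstruct_spectrum(fid, acq, 2)
    # sum over the original bandwidth equals N x fid[0]-ish invariant:
    # zero filling interpolates, the integral (sum / points-per-Hz) is fixed
    assert np.sum(s0.values) == pytest.approx(np.sum(s2.values) / 4, rel=1e-9)


def test_snr_scales_with_amplitude_and_fwhm_does_not(acq, rng):
    t = acq.time_axis()
    noise = 0.1 * (rng.standard_normal(700) + 1j * rng.standard_normal(700))
    base = fid_model([1.0], [0.0], [30.0], [0.0], t)
    s1 = reconstruct_spectrum(base + noise, acq)
    s2 = reconstruct_spectrum(2 * base + noise, acq)
    snr1, w1 = spectrum_metrics(s1, (-20, 20))
    snr2, w2 = spectrum_metrics(s2, (-20, 20))
    assert snr2 == pytest.approx(2 * snr1, rel=0.05)
    assert w2 == pytest.approx(w1, rel=0.05)


def test_zero_variance_noise_window_is_an_error(acq):
    fid = fid_model([1.0], [0.0], [30.0], [0.0], acq.time_axis())
    spec = reconstruct_spectrum(fid, acq)
    spec.values[default_noise_window(spec.frequency_hz)] = 0.0
    with pytest.raises(ValueError, match="zero variance"):
        spectrum_metrics(spec, (-20, 20))


def test_pure_noise_snr_sits_below_qc_threshold(acq, rng):
    """Max-of-noise SNR in a metabolite-sized window stays well under the
    QC gate of 5 for pure-noise voxels."""
    snrs = []
    for _ in range(50):
        fid = rng.standard_normal(700) + 1j * rng.standard_normal(700)
        spec = reconstruct_spectrum(fid, acq)
        snr, _ = spectrum_metrics(spec, (-20, 20))
        snrs.append(snr)
    assert np.median(snrs) < 5.0
    assert np.mean(np.array(snrs) < 5.0) > 0.9
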