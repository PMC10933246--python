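"""Prior-knowledge fitting: recovery, CRLB behavior, QC rules."""

import numpy as np
import pytest

from dmikit import QCRule, crlb_percent, default_priors, fit_voxel, qc_mask
from dmikit.spectral import fid_model


def _priors_params(priors):
    f = np.array([p.center_frequency_hz for p in priors])
    d = np.array([p.damping_init for p in priors])
    return f, d


def test_self_consistency_at_prior_initials(acq, priors):
    """A noiseless FID generated exactly from the priors' starting values is
    recovered to 1e-6 relative."""
    f, d = _priors_params(priors)
    a = np.array([5.0, 2.0, 1.5, 1.0])
    fid = fid_model(a, f, d, np.zeros(4), acq.time_axis())
    fit = fit_voxel(fid, priors, acq)
    assert fit.converged
    assert np.max(np.abs(fit.amplitudes / a - 1)) < 1e-6
    assert np.max(np.abs(fit.frequencies_hz - f)) < 1e-6


def test_four_peak_refit_off_initial_values(acq, priors, rng):
    """Noiseless 4-resonance FIDs with parameters away from the starting
    values (global frequency shift, perturbed dampings and phase) refit to
    1e-4 relative amplitudes."""
    f0, d0 = _priors_params(priors)
    for _ in range(5):
        a = rng.uniform(0.5, 8.0, 4)
        f = f0 + rng.uniform(-3, 3)
        d = d0 + rng.uniform(-15, 30)  # common shim broadening
        fid = fid_model(a, f, d, np.full(4, rng.uniform(-0.5, 0.5)), acq.time_axis())
        fit = fit_voxel(fid, priors, acq)
        assert np.max(np.abs(fit.amplitudes / a - 1)) < 1e-4


def test_individual_frequency_mode_recovers_detuned_peaks(acq, priors, rng):
    """With shift_mode='individual', resonances perturbed independently
    within their bounds are still recovered."""
    f0, d0 = _priors_params(priors)
    a = np.array([5.0, 2.5, 2.0, 1.0])
    f = f0 + rng.uniform(-3, 3, 4)
    fid = fid_model(a, f, d0, np.zeros(4), acq.time_axis())
    fit = fit_voxel(fid, priors, acq, shift_mode="individual")
    assert np.max(np.abs(fit.amplitudes / a - 1)) < 1e-4
    assert np.max(np.abs(fit.frequencies_hz - f)) < 1e-3


def test_fit_invariant_to_global_scale(acq, priors, rng):
    f0, d0 = _priors_params(priors)
    fid = fid_model([4.0, 2.0, 1.0, 0.8], f0, d0, np.zeros(4), acq.time_axis())
    fid = fid + 0.2 * (rng.standard_normal(fid.size) + 1j * rng.standard_normal(fid.size))
    r1 = fit_voxel(fid, priors, acq)
    r2 = fit_voxel(1e4 * fid, priors, acq)
    assert np.allclose(r2.amplitudes, 1e4 * r1.amplitudes, rtol=1e-6)
    assert np.allclose(r2.frequencies_hz, r1.frequencies_hz, atol=1e-8)
    assert np.allclose(r2.crlb_percent, r1.crlb_percent, rtol=1e-6)


def test_residual_not_worse_than_initial(acq, priors, rng):
    f0, d0 = _priors_params(priors)
    fid = fid_model([4.0, 2.0, 1.0, 0.8], f0 + 2, d0 * 1.2, np.zeros(4), acq.time_axis())
    fid = fid + 0.5 * (rng.standard_normal(fid.size) + 1j * rng.standard_normal(fid.size))
    fit = fit_voxel(fid, priors, acq)
    # initial model: linear-projection amplitudes on the prior basis; the
    # returned residual can never exceed the residual of a zero model
    assert fit.residual_norm <= np.linalg.norm(fid)


def test_zero_fid_flagged_not_raised(acq, priors):
    fit = fit_voxel(np.zeros(acq.n_spectral, dtype=complex), priors, acq)
    assert not fit.converged


def test_crlb_scales_linearly_with_noise(acq, priors):
    f0, d0 = _priors_params(priors)
    a = np.array([5.0, 2.0, 1.5, 1.0])
    fid = fid_model(a, f0, d0, np.zeros(4), acq.time_axis())
    fit = fit_voxel(fid, priors, acq)
    c1 = crlb_percent(fit, 1.0, acq)
    c2 = crlb_percent(fit, 2.0, acq)
    assert np.allclose(c2, 2 * c1, rtol=1e-9)


def test_crlb_overlap_penalty(acq):
    """Overlapping resonances carry a larger amplitude CRLB than the same
    pair far apart, and the bound approaches the isolated-peak value as the
    separation grows."""
    from dmikit import ResonancePrior

    def two_peaks(sep_hz):
        return [
            ResonancePrior(name="a", center_frequency_hz=0.0, frequency_bound_hz=6,
                           damping_init=47.0, damping_bounds=(3.0, 160.0)),
            ResonancePrior(name="b", center_frequency_hz=-sep_hz, frequency_bound_hz=6,
                           damping_init=47.0, damping_bounds=(3.0, 160.0)),
        ]

    results = {}
    for sep in (15.0, 300.0, 1200.0):
        priors = two_peaks(sep)
        fid = fid_model([2.0, 2.0], [0.0, -sep], [47.0, 47.0], [0.0, 0.0],
                        default_acq_time(acq))
        fit = fit_voxel(fid, priors, acq)
        results[sep] = crlb_percent(fit, 1.0, acq)[0]
    assert results[15.0] > results[300.0]
    assert results[300.0] == pytest.approx(results[1200.0], rel=0.05)


def default_acq_time(acq):
    return acq.time_axis()


def test_crlb_ordering_matches_snr_hierarchy(acq, priors):
    """At 120-min amplitudes and study noise, CRLB% orders water < glucose <
    Glx, lactate."""
    f0, d0 = _priors_params(priors)
    a = np.array([7.39, 2.55, 2.25, 0.74])
    fid = fid_model(a, f0, d0, np.zeros(4), acq.time_axis())
    fit = fit_voxel(fid, priors, acq)
    c = crlb_percent(fit, 3.15, acq)
    water, glucose, glx, lactate = c
    assert water < glucose < glx
    assert glucose < lactate


def test_qc_thresholds_are_strict():
    snr = np.array([4.9, 5.1, 5.1, 5.1, 0.0])
    fwhm = np.array([20.0, 29.0, 31.0, 30.0, 20.0])
    mask, n_excluded = qc_mask(snr, fwhm, QCRule())
    assert mask.tolist() == [False, True, False, True, False]
    assert n_excluded == 3


def test_vacuous_qc_rule_keeps_everything():
    snr = np.array([0.01, 100.0])
    fwhm = np.array([500.0, 1.0])
    mask, n_excluded = qc_mask(snr, fwhm, QCRule(water_snr_min=1e-9,
                                                 water_linewidth_max_hz=1e9))
    assert mask.all() and n_excluded == 0
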