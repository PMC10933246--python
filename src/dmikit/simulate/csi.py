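"""Raw CSI synthesis: concentrations -> voxel FIDs.

Each voxel's FID is a sum of four damped complex exponentials at the
prior-knowledge frequencies, with amplitude proportional to

    concentration (mM) x steady-state saturation factor x B1 factor,

plus i.i.d. complex Gaussian noise.  Phantom voxels contain only the water
resonance at their nominal concentrations.  The transmit-receive B1 profile is
modelled as a smooth radial polynomial, 1 + beta * rho^2 with rho the
normalized distance to the grid center (rho = 1 at the corners), so |beta| is
the peak-to-center deviation; beta is drawn per session within the configured
+/- range.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from ..acquisition import (
    DEFAULT_T1_S,
    METABOLITES,
    AcquisitionParams,
    ResonancePrior,
    saturation_factor,
)
from ..containers import SpectralGrid
from .atlas import LabelAtlas, PHANTOM_REGIONS
from .truth import VarianceParams, population_curve


def b1_field(shape: tuple[int, int, int], beta: float) -> np.ndarray:
    """Radial-quadratic B1 amplitude map: 1 at the center, 1 + beta at corners."""
    axes = [((np.arange(n) + 0.5) / n - 0.5) / 0.5 for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    rho2 = (xx**2 + yy**2 + zz**2) / 3.0  # 1.0 at the corners
    return 1.0 + beta * rho2


def amplitude_maps(
    concentrations: dict[str, dict[str, float]],
    atlas: LabelAtlas,
    vp: VarianceParams,
    acq: AcquisitionParams,
    b1: np.ndarray | None = None,
    t1_s: dict[str, float] | None = None,
    phantom_scales: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Stack of per-metabolite signal-amplitude volumes, shape (4, nx, ny, nz).

    ``concentrations`` maps metabolite -> region -> mM (brain regions only;
    phantom voxels always carry their nominal water concentrations).  One
    signal unit corresponds to 1 mM at full relaxation and uniform B1.
    """
    t1_s = t1_s or DEFAULT_T1_S
    if b1 is None:
        b1 = np.ones(atlas.shape)
    maps = np.zeros((len(METABOLITES),) + atlas.shape)
    psf = _spatial_response_kernel() if vp.spatial_response else None
    for im, metab in enumerate(METABOLITES):
        sat = saturation_factor(acq.flip_deg, acq.tr_s, t1_s[metab])
        conc = np.zeros(atlas.shape)
        for region, mm in concentrations.get(metab, {}).items():
            conc[atlas.region_mask(region)] = mm
        amp = conc * sat * b1
        if psf is not None:
            # Cartesian CSI convolves the object with the periodic Dirichlet
            # voxel response; wrap-mode convolution is exact on the FOV torus
            amp = ndimage.convolve(amp, psf, mode="wrap")
        if metab == "water":
            phantom_amp = np.zeros(atlas.shape)
            for region, mm, fill in zip(
                PHANTOM_REGIONS, vp.phantom_concentrations_mm, phantom_scales
            ):
                phantom_amp[atlas.region_mask(region)] = mm * fill
            amp = amp + phantom_amp * sat * b1
        maps[im] = amp
    return maps


def _spatial_response_kernel() -> np.ndarray:
    from ..maps import csi_psf

    return csi_psf()


def synthesize_csi(
    concentrations: dict[str, dict[str, float]],
    atlas: LabelAtlas,
    acq: AcquisitionParams,
    vp: VarianceParams,
    priors: list[ResonancePrior],
    seed: int | np.random.SeedSequence | None = None,
    b1: np.ndarray | None = None,
    noise_sd: float | None = None,
    phantom_scales: tuple[float, float] = (1.0, 1.0),
) -> SpectralGrid:
    """Synthesize one exam's raw CSI grid from a truth table slice.

    ``noise_sd`` (sd of the real and imaginary noise components per FID point)
    overrides ``vp.noise_sd``; pass 0 for a noise-free grid.  All phases are
    zero.
    """
    missing = set(concentrations) - set(METABOLITES)
    if missing:
        raise ValueError(f"unknown metabolites in truth: {sorted(missing)}")
    amps = amplitude_maps(concentrations, atlas, vp, acq, b1=b1, phantom_scales=phantom_scales)
    t = acq.time_axis()
    freqs = {p.name: p.center_frequency_hz for p in priors}
    data = np.zeros(atlas.shape + (acq.n_spectral,), dtype=np.complex128)
    for im, metab in enumerate(METABOLITES):
        d = math.pi * vp.linewidths_fwhm_hz[metab]
        basis = np.exp((2j * np.pi * freqs[metab] - d) * t)
        data += amps[im][..., None] * basis
    if noise_sd is None:
        noise_sd = vp.noise_sd if vp.noise_sd is not None else calibrate_noise_sd(acq, vp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return SpectralGrid(data, acq, meta={"noise_sd": noise_sd})


def calibrate_noise_sd(
    acq: AcquisitionParams,
    vp: VarianceParams,
    at_time_min: float = 120.0,
    zero_fill_doublings: int = 2,
) -> float:
    """Noise level that puts the spectral water SNR at ``vp.target_water_snr``.

    The reference voxel carries the population whole-brain water concentration
    at ``at_time_min`` with unit B1.  Spectral SNR is peak magnitude over the
    sd of the real part of the noise floor; for an unnormalized forward FFT of
    N points with per-component time-domain sd sigma, that floor sd is
    sigma * sqrt(N), so sigma = peak / (target_snr * sqrt(N)).
    """
    water_mm = float(population_curve(vp, "water", np.array([at_time_min]))[0])
    sat = saturation_factor(acq.flip_deg, acq.tr_s, DEFAULT_T1_S["water"])
    d = math.pi * vp.linewidths_fwhm_hz["water"]
    t = acq.time_axis()
    fid = water_mm * sat * np.exp(-d * t)
    n_fft = acq.n_spectral * 2**zero_fill_doublings
    peak = float(np.abs(np.fft.fft(fid, n=n_fft)).max())
    return peak / (vp.target_water_snr * math.sqrt(acq.n_spectral))
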