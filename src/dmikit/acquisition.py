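"""Acquisition parameters and prior knowledge for the four deuterium resonances.

A 3-T deuterium (2H) chemical-shift-imaging exam yields one free induction
decay (FID) per voxel of a coarse spatial grid.  Four resonances are resolvable
at this field strength: deuterated water (HDO), glucose, combined
glutamate + glutamine (Glx), and lactate.  Their chemical shifts are expressed
in ppm relative to the 2H Larmor frequency; the acquisition carrier is placed
on water, so frequency offsets are reported in Hz relative to water.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

METABOLITES = ("water", "glucose", "glx", "lactate")

#: chemical shifts in ppm (water-referenced spectra put water at 4.8 ppm)
DEFAULT_PPM = {"water": 4.8, "glucose": 3.8, "glx": 2.4, "lactate": 1.3}

#: typical in-vivo linewidths (FWHM, Hz) used to initialise fits and simulate
DEFAULT_FWHM_HZ = {"water": 10.0, "glucose": 10.0, "glx": 15.0, "lactate": 25.0}

#: deuterium T1 relaxation times in seconds (literature-informed; used for the
#: partial-saturation correction, overridable in CorrectionConfig)
DEFAULT_T1_S = {"water": 0.320, "glucose": 0.064, "glx": 0.146, "lactate": 0.297}


class AcquisitionParams(BaseModel):
    """Constants of the chemical-shift-imaging acquisition.

    Defaults match a clinical 3-T deuterium protocol: a 10x10x10 matrix over a
    24 cm isotropic field of view, 700 spectral points at 5000 Hz bandwidth,
    70 degree excitation every 155.8 ms, and a 2H Larmor frequency of
    19.6 MHz (so 1 ppm is 19.6 Hz).
    """

    matrix: tuple[int, int, int] = (10, 10, 10)
    fov_mm: tuple[float, float, float] = (240.0, 240.0, 240.0)
    n_spectral: int = Field(700, ge=2)
    bandwidth_hz: float = Field(5000.0, gt=0)
    flip_deg: float = Field(70.0, gt=0, le=180)
    tr_s: float = Field(0.1558, gt=0)
    larmor_mhz: float = Field(19.6, gt=0)
    water_ppm: float = 4.8

    model_config = {"frozen": True}

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    @property
    def hz_per_ppm(self) -> float:
        return self.larmor_mhz  # MHz * 1e6 * 1e-6

    def time_axis(self) -> np.ndarray:
        """Sampling times of the FID in seconds (first point at t = 0)."""
        return np.arange(self.n_spectral) * self.dwell_s

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))


class ResonancePrior(BaseModel):
    """Prior knowledge constraining one resonance during time-domain fitting.

    Frequencies are offsets in Hz relative to the water resonance (the
    carrier).  Dampings are exponential decay rates in 1/s; the corresponding
    Lorentzian FWHM is damping / pi.
    """

    name: str
    center_frequency_hz: float
    frequency_bound_hz: float = Field(gt=0)
    damping_init: float = Field(gt=0)
    damping_bounds: tuple[float, float]
    amplitude_lower: float = 0.0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _bounds_contain_init(self) -> "ResonancePrior":
        lo, hi = self.damping_bounds
        if not (0 < lo <= self.damping_init <= hi):
            raise ValueError(
                f"damping_init {self.damping_init} outside bounds {self.damping_bounds}"
            )
        if self.amplitude_lower != 0.0:
            raise ValueError("amplitude lower bound must be 0")
        return self

    @property
    def fwhm_init_hz(self) -> float:
        return self.damping_init / math.pi


def default_priors(
    acq: AcquisitionParams | None = None,
    ppm: dict[str, float] | None = None,
    fwhm_hz: dict[str, float] | None = None,
    frequency_bound_ppm: float = 0.3,
    fwhm_bounds_hz: tuple[float, float] = (1.0, 50.0),
) -> list[ResonancePrior]:
    """Prior table for the four 2H resonances.

    Frequency search windows default to +/- 0.3 ppm around the literature
    shifts; linewidths are bounded to 1-50 Hz FWHM.  The glucose multiplet is
    modelled as a single Lorentzian, which is adequate at 3 T where its
    components are unresolved.
    """
    acq = acq or AcquisitionParams()
    ppm = ppm or DEFAULT_PPM
    fwhm_hz = fwhm_hz or DEFAULT_FWHM_HZ
    priors = []
    for name in METABOLITES:
        offset = (ppm[name] - ppm["water"]) * acq.hz_per_ppm
        priors.append(
            ResonancePrior(
                name=name,
                center_frequency_hz=offset,
                frequency_bound_hz=frequency_bound_ppm * acq.hz_per_ppm,
                damping_init=math.pi * fwhm_hz[name],
                damping_bounds=(math.pi * fwhm_bounds_hz[0], math.pi * fwhm_bounds_hz[1]),
            )
        )
    return priors


def saturation_factor(flip_deg: float, tr_s: float, t1_s: float) -> float:
    """Steady-state signal attenuation from repeated excitation at TR < 5 T1.

    s = sin(a) (1 - E1) / (1 - cos(a) E1),  E1 = exp(-TR/T1).
    The measured amplitude is s times the fully relaxed amplitude.
    """
    a = math.radians(flip_deg)
    e1 = math.exp(-tr_s / t1_s)
    s = math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1)
    if s == 0.0:
        raise ValueError("saturation factor is zero (flip angle 0?)")
    return s
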