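"""Ground-truth metabolite dynamics with subject/session variance components.

Concentration model per metabolite and region:

    C(t) = [NA if water] + curve(t) * u_subject * u_session * m_region * u_region

where ``curve(t) = c1 t + c2 t^2`` is the population enrichment curve (zero at
baseline), the ``u`` terms are mean-one log-normal random effects, and
``m_region`` is a fixed regional multiplier.  Natural-abundance deuterated
water (NA) is a physiological constant and carries no random effects, so the
water concentration at the baseline timepoint is exactly NA for every exam.

Log-normal effects with coefficient of variation ``cov`` use
``sigma_log = sqrt(ln(1 + cov^2))`` and mean 1, guaranteeing positivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from ..acquisition import METABOLITES
from .atlas import BRAIN_REGIONS, LabelAtlas

#: population enrichment curves, mM: (c1 [mM/min], c2 [mM/min^2]).
#: Glucose and lactate plateau near 100 min; water and Glx keep rising
#: almost linearly through 120 min.
DEFAULT_CURVES = {
    "water": (0.050, 0.0),
    "glucose": (0.060, -3.0e-4),
    "glx": (0.032, -4.5e-5),
    "lactate": (0.031, -1.55e-4),
}

#: fixed regional multipliers: water is spatially even, metabolites vary
#: moderately across the brain (strongest spread for lactate and Glx).
DEFAULT_REGION_MULTIPLIERS = {
    "water": {r: 1.0 for r in BRAIN_REGIONS},
    "glucose": {
        "frontal": 1.10, "parietal": 1.05, "temporal": 0.95, "occipital": 1.00,
        "cerebellum": 1.15, "thalamus": 1.00, "caudate": 0.90, "putamen": 0.90,
        "brain_stem": 0.85,
    },
    "glx": {
        "frontal": 1.15, "parietal": 1.10, "temporal": 0.90, "occipital": 1.05,
        "cerebellum": 1.20, "thalamus": 0.95, "caudate": 0.85, "putamen": 0.80,
        "brain_stem": 0.75,
    },
    "lactate": {
        "frontal": 1.20, "parietal": 1.10, "temporal": 0.90, "occipital": 1.00,
        "cerebellum": 0.80, "thalamus": 0.90, "caudate": 0.75, "putamen": 0.70,
        "brain_stem": 0.85,
    },
}


class StudyDesign(BaseModel):
    """Test-retest study layout: subjects x sessions x timepoints."""

    n_subjects: int = Field(6, ge=1)
    n_sessions: int = Field(2, ge=1)
    timepoints_min: tuple[float, ...] = (0.0, 30.0, 75.0, 120.0)
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("timepoints_min")
    @classmethod
    def _sorted_with_baseline(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if list(v) != sorted(v):
            raise ValueError("timepoints must be sorted ascending")
        if v[0] != 0.0:
            raise ValueError("timepoints must include a baseline at 0 min")
        return v


class VarianceParams(BaseModel):
    """Variance structure and signal/noise levels of the synthetic study."""

    curves: dict[str, tuple[float, float]] = DEFAULT_CURVES
    between_subject_cov: float = Field(0.18, ge=0)
    within_subject_cov: float = Field(0.09, ge=0)
    region_effect_cov: float = Field(0.05, ge=0)
    region_multipliers: dict[str, dict[str, float]] = DEFAULT_REGION_MULTIPLIERS
    natural_abundance_hdo_mm: float = Field(10.12, gt=0)
    phantom_concentrations_mm: tuple[float, float] = (6.4, 19.15)
    #: session-to-session variability of the effective phantom signal
    #: (log-normal CoV).  The reference phantoms are small relative to a CSI
    #: voxel, so repositioning between sessions changes the sampled volume
    #: fraction — the dominant reason external-phantom calibration is less
    #: stable than internal references.  The default is calibrated so the
    #: phantom-normalized within-subject CoV lands near the observed ~16%.
    phantom_fill_cov: float = Field(0.16, ge=0)
    #: optionally convolve brain amplitude maps with the truncated CSI voxel
    #: response before synthesis.  Off by default: the object is defined on
    #: the acquisition grid itself, for which Fourier sampling is exact, and
    #: the truncated non-negative kernel overstates the blur of sub-voxel
    #: structure it is meant to emulate.
    spatial_response: bool = False
    #: complex-noise sd per FID point; None = calibrate to target_water_snr
    noise_sd: float | None = Field(None, ge=0)
    target_water_snr: float = 14.0
    b1_amplitude_range: float = Field(0.07, ge=0)
    linewidths_fwhm_hz: dict[str, float] = {
        "water": 10.0, "glucose": 10.0, "glx": 15.0, "lactate": 25.0,
    }

    @field_validator("region_multipliers")
    @classmethod
    def _positive_multipliers(cls, v):
        for metab, table in v.items():
            if any(f <= 0 for f in table.values()):
                raise ValueError(f"regional multipliers must be > 0 ({metab})")
        return v


def population_curve(vp: VarianceParams, metabolite: str, t_min: np.ndarray) -> np.ndarray:
    """Population-mean concentration (mM) at ``t_min`` minutes post ingestion."""
    c1, c2 = vp.curves[metabolite]
    t = np.asarray(t_min, dtype=float)
    enrich = np.clip(c1 * t + c2 * t * t, 0.0, None)
    if metabolite == "water":
        return vp.natural_abundance_hdo_mm + enrich
    return enrich


def _lognormal_effects(rng: np.random.Generator, cov: float, shape) -> np.ndarray:
    """Mean-one log-normal draws with the requested coefficient of variation."""
    if cov == 0:
        return np.ones(shape)
    sig = np.sqrt(np.log1p(cov**2))
    return rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=shape)


@dataclass
class TruthTable:
    """Tidy ground-truth concentrations per subject/session/timepoint/region."""

    frame: pd.DataFrame  # columns: subject, session, timepoint_min, region, metabolite, conc_mm

    def exam(self, subject: int, session: int, timepoint_min: float) -> pd.DataFrame:
        f = self.frame
        sel = (
            (f["subject"] == subject)
            & (f["session"] == session)
            & (f["timepoint_min"] == timepoint_min)
        )
        return f.loc[sel]

    def exam_concentrations(
        self, subject: int, session: int, timepoint_min: float
    ) -> dict[str, dict[str, float]]:
        """{metabolite: {region: mM}} for one exam."""
        out: dict[str, dict[str, float]] = {}
        for row in self.exam(subject, session, timepoint_min).itertuples():
            out.setdefault(row.metabolite, {})[row.region] = row.conc_mm
        return out


def sample_truth(
    design: StudyDesign,
    atlas: LabelAtlas,
    vp: VarianceParams,
    seed: int | np.random.SeedSequence | None = None,
) -> TruthTable:
    """Draw a ground-truth concentration table for a whole study.

    Random-effect order: the per-subject effect scales a subject's entire
    enrichment trajectory, the per-session effect scales one exam day, fixed
    regional multipliers are applied last together with a small per-exam
    regional jitter.  Reproducible from the seed (defaults to ``design.seed``).
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    regions = list(BRAIN_REGIONS)
    n_s, n_e, n_t = design.n_subjects, design.n_sessions, len(design.timepoints_min)
    n_r, n_m = len(regions), len(METABOLITES)

    u_subj = _lognormal_effects(rng, vp.between_subject_cov, (n_s, n_m))
    u_sess = _lognormal_effects(rng, vp.within_subject_cov, (n_s, n_e, n_m))
    u_reg = _lognormal_effects(rng, vp.region_effect_cov, (n_s, n_e, n_t, n_r, n_m))

    t = np.asarray(design.timepoints_min)
    rows = []
    for im, metab in enumerate(METABOLITES):
        c1, c2 = vp.curves[metab]
        enrich = np.clip(c1 * t + c2 * t * t, 0.0, None)  # (n_t,)
        mult = np.array([vp.region_multipliers[metab].get(r, 1.0) for r in regions])
        conc = (
            enrich[None, None, :, None]
            * u_subj[:, None, None, None, im]
            * u_sess[:, :, None, None, im]
            * mult[None, None, None, :]
            * u_reg[:, :, :, :, im]
        )
        if metab == "water":
            conc = conc + vp.natural_abundance_hdo_mm
        rows.append(conc)

    conc = np.stack(rows, axis=-1)  # (n_s, n_e, n_t, n_r, n_m)
    idx = pd.MultiIndex.from_product(
        [range(n_s), range(n_e), design.timepoints_min, regions, METABOLITES],
        names=["subject", "session", "timepoint_min", "region", "metabolite"],
    )
    frame = pd.DataFrame({"conc_mm": conc.ravel()}, index=idx).reset_index()
    return TruthTable(frame)
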