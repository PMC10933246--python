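"""Whole-study assembly: design + atlas + truth + lazily generated raw grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..acquisition import AcquisitionParams, ResonancePrior, default_priors
from ..containers import SpectralGrid
from .atlas import LabelAtlas, make_atlas
from .csi import b1_field, calibrate_noise_sd, synthesize_csi
from .truth import StudyDesign, TruthTable, VarianceParams, sample_truth


@dataclass
class SyntheticStudy:
    """A complete synthetic DMI study.

    Raw CSI grids are generated on demand from per-exam child seeds, so a
    study object stays small regardless of grid size and any exam can be
    re-synthesized bit-identically (including a noise-free version for
    ground-truth comparisons).
    """

    design: StudyDesign
    atlas: LabelAtlas
    acq: AcquisitionParams
    vp: VarianceParams
    priors: list[ResonancePrior]
    truth: TruthTable
    b1_beta: np.ndarray  # (n_subjects, n_sessions)
    phantom_fill: np.ndarray  # (n_subjects, n_sessions, 2)
    noise_sd: float
    _exam_seeds: dict = field(default_factory=dict, repr=False)

    def exams(self):
        """Iterate (subject, session, timepoint_min) over the whole design."""
        for subject in range(self.design.n_subjects):
            for session in range(self.design.n_sessions):
                for tp in self.design.timepoints_min:
                    yield subject, session, tp

    def exam_grid(
        self, subject: int, session: int, timepoint_min: float, noise: bool = True
    ) -> SpectralGrid:
        """Synthesize one exam's raw grid; ``noise=False`` gives the ground truth."""
        key = (subject, session, timepoint_min)
        conc = self.truth.exam_concentrations(subject, session, timepoint_min)
        b1 = b1_field(self.atlas.shape, float(self.b1_beta[subject, session]))
        grid = synthesize_csi(
            conc,
            self.atlas,
            self.acq,
            self.vp,
            self.priors,
            seed=self._exam_seeds[key],
            b1=b1,
            noise_sd=self.noise_sd if noise else 0.0,
            phantom_scales=tuple(self.phantom_fill[subject, session]),
        )
        grid.meta.update(subject=subject, session=session, timepoint_min=timepoint_min)
        return grid


def make_study(
    design: StudyDesign | None = None,
    acq: AcquisitionParams | None = None,
    vp: VarianceParams | None = None,
    atlas: LabelAtlas | None = None,
    priors: list[ResonancePrior] | None = None,
    seed: int | None = None,
) -> SyntheticStudy:
    """Create a reproducible synthetic study under the default conditions.

    Identical (design, vp, seed) yield bit-identical studies: all randomness
    (truth effects, per-session B1 deviation, per-exam noise) derives from one
    seed sequence.
    """
    design = design or StudyDesign()
    acq = acq or AcquisitionParams()
    vp = vp or VarianceParams()
    priors = priors or default_priors(acq)
    if atlas is None:
        atlas = make_atlas(acq.matrix)
    if seed is None:
        seed = design.seed

    root = np.random.SeedSequence(seed)
    ss_truth, ss_b1, ss_fill, ss_noise = root.spawn(4)
    truth = sample_truth(design, atlas, vp, seed=ss_truth)

    rng_b1 = np.random.default_rng(ss_b1)
    beta = rng_b1.uniform(
        -vp.b1_amplitude_range, vp.b1_amplitude_range, size=(design.n_subjects, design.n_sessions)
    )
    rng_fill = np.random.default_rng(ss_fill)
    if vp.phantom_fill_cov > 0:
        sig = np.sqrt(np.log1p(vp.phantom_fill_cov**2))
        fill = rng_fill.lognormal(-0.5 * sig**2, sig, size=(design.n_subjects, design.n_sessions, 2))
    else:
        fill = np.ones((design.n_subjects, design.n_sessions, 2))

    noise_sd = vp.noise_sd if vp.noise_sd is not None else calibrate_noise_sd(acq, vp)
    exam_keys = [
        (s, e, tp)
        for s in range(design.n_subjects)
        for e in range(design.n_sessions)
        for tp in design.timepoints_min
    ]
    exam_seeds = dict(zip(exam_keys, ss_noise.spawn(len(exam_keys))))

    return SyntheticStudy(
        design=design,
        atlas=atlas,
        acq=acq,
        vp=vp,
        priors=priors,
        truth=truth,
        b1_beta=beta,
        phantom_fill=fill,
        noise_sd=noise_sd,
        _exam_seeds=exam_seeds,
    )
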