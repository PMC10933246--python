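"""Test-retest repeatability of a full synthetic study.

Runs the extended pipeline over all subjects/sessions and computes the
within-subject CoV (session-to-session), the repeatability coefficient
(the smallest change unlikely to be noise), and the between-subject CoV,
per metabolite, for the whole brain at 120 min.
"""

from dmikit import AcquisitionParams, PipelineConfig, StudyDesign, make_study
from dmikit.pipeline import run_study_analysis
from dmikit.stats import bland_altman

design = StudyDesign(timepoints_min=(0.0, 120.0))
acq = AcquisitionParams(matrix=(6, 6, 6))
cfg = PipelineConfig(design=design, acquisition=acq)
study = make_study(design=design, acq=acq, seed=4)

res = run_study_analysis(study, cfg, "extended", normalizations=("baseline",))
table = res["repeatability"]["baseline"]
wb = table[(table.region == "whole_brain") & (table.timepoint == 120.0)]
print(wb.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
print("\nconfigured truth: 9% within-subject, 18% between-subject CoV; "
      "glucose (the best-SNR enriched resonance) tracks them, Glx/lactate "
      "carry extra fit noise at this SNR.")

reg = res["regional"]
glu = reg[(reg.region == "whole_brain") & (reg.timepoint_min == 120.0)
          & (reg.metabolite == "glucose")]
wide = glu.pivot_table(index="subject", columns="session", values="value")
bias, lo, hi = bland_altman(wide[0].to_numpy(), wide[1].to_numpy())
print(f"\nBland-Altman (glucose, mM): bias {bias:+.2f}, "
      f"limits of agreement [{lo:+.2f}, {hi:+.2f}]")
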