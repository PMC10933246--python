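# Methods

`dmikit` simulates and analyses test–retest deuterium metabolic imaging (DMI)
studies of the brain at 3 T. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic data do and do not
emulate.

## Signal model and acquisition

A chemical-shift-imaging (CSI) exam is a 10×10×10 grid of complex free
induction decays (FIDs), 700 points at 5000 Hz bandwidth, excited at 70° every
155.8 ms. Four ²H resonances are modelled, each a damped complex exponential:

    s(t) = e^{iφ₀} Σ_k a_k · e^{(2πi f_k − d_k) t}

with a single zero-order phase φ₀ shared by all resonances and relative phases
fixed at zero (first-order phase is not modelled). Frequencies are offsets in
Hz from the water carrier; chemical shifts default to water 4.8, glucose 3.8,
Glx 2.4, lactate 1.3 ppm at a ²H Larmor frequency of 19.6 MHz (1 ppm ≈ 19.6 Hz).
All are configuration, not constants. The glucose multiplet is a single
Lorentzian — its components are unresolved at 3 T.

Voxel amplitudes are `concentration (mM) × saturation factor × B1 factor`,
with the steady-state saturation factor s = sin α (1−E₁)/(1−cos α E₁),
E₁ = exp(−TR/T₁). Default ²H T₁ values: water 320 ms, glucose 64 ms,
Glx 146 ms, lactate 297 ms (literature-informed, configurable). Label-loss
factors default to 1.0 (hooks exist). Default linewidths (FWHM): water and
glucose 10 Hz, Glx 15 Hz, lactate 25 Hz.

## The synthetic-study generator

The generator defines the study conditions; everything downstream is tested
against it.

* **Atlas** — a parametric, deliberately unrealistic geometry in native space:
  an ellipsoidal brain carved into four lobes, spherical cerebellum, brain
  stem, thalamus, caudate and putamen, plus two external phantom spheres
  (6.4 and 19.15 mM deuterated water, water resonance only). Every required
  region is guaranteed at least one voxel down to a 6³ grid; there is no
  registration stage because simulation and analysis share one space.
* **Dynamics** — population concentration curves are quadratic in time and
  zero at baseline: glucose (peak ≈ 3.0 mM) and lactate (≈ 1.55 mM) plateau
  near 100 min, Glx rises near-linearly to ≈ 3.2 mM at 120 min, and water
  rises linearly on top of the natural-abundance HDO level. The HDO baseline
  defaults to 10.12 mM and is configuration (the literature convention for
  baseline quantification); it carries no biological variance.
* **Variance components** — mean-one log-normal random effects
  (σ_log = √ln(1+CoV²)) applied multiplicatively to the enrichment curves:
  per subject (between-subject CoV, default 0.18), per session (within-subject
  CoV, default 0.09), and a per-exam, per-region jitter (default CoV 0.05).
  The regional jitter makes regional CoVs exceed whole-brain CoVs, as observed
  in vivo, and gives internal normalization a realistic noise floor. Fixed
  regional multipliers make metabolite maps vary moderately across regions
  while water stays flat.
* **B1** — a radial-quadratic transmit-receive profile, 1 + β ρ², with β drawn
  per session uniformly in ±7% (peak-to-center at the grid corners). Transmit
  and receive are not separated.
* **Phantom sampling fraction** — the external phantoms are small relative to
  a CSI voxel, so session-to-session repositioning changes the sampled volume
  fraction. This is modelled as a per-session, per-phantom log-normal factor
  (default CoV 0.16, calibrated so the phantom-normalized within-subject CoV
  lands near the observed ~16%). This mechanism — not B1 alone — is what makes
  external-phantom calibration the least stable quantification route.
* **Noise** — i.i.d. complex Gaussian per FID point. The default sd is
  calibrated analytically so the whole-brain spectral water SNR at 120 min is
  ≈ 14, the reported level; per-voxel metabolite SNRs and CRLB hierarchies
  then fall out in the observed order (water ≫ glucose > Glx > lactate).

Determinism: one master seed feeds a `SeedSequence` tree (truth, B1, phantom
fill, per-exam noise); identical configuration and seed reproduce every FID
bit for bit. Raw grids are synthesized lazily per exam, so studies stay small
in memory and a noise-free twin of any exam is available as ground truth.

What the generator does **not** emulate: spiral k-space readout and gridding
(voxels are synthesized directly, so there is no true spatial blurring), B₀
inhomogeneity and frequency drift, lineshape distortions, motion, lipid
contamination, and anatomical realism. Passing tests therefore demonstrate
correctness of the analysis chain and its statistical behavior under the
modelled variance structure — not performance on scanner data.

## Reconstruction and spectrum metrics

Spectra are unapodized FFTs ("no line broadening"), zero-filled twice —
read as two successive doublings, 700 → 2800 points; a config flag selects the
alternative append-twice reading (700 → 2100). Forward FFT unnormalized,
inverse 1/N. Spectral SNR is the peak magnitude over the sd of the real part
in the outer 10% spectral edges (metabolite-free by construction). Linewidths
are measured on the magnitude spectrum with linear interpolation at the
half-maximum crossings and converted by 1/√3 to the Lorentzian-equivalent
absorption width — the convention in which linewidths are quoted and in which
the fitted d/π and the 30-Hz QC gate are expressed.

## Denoising

MP-PCA with sliding 3×3×3 patches, stride 1, uniform averaging of overlaps.
Each patch unfolds to a complex Casorati matrix (27 voxels × 700 points; no
real/imaginary stacking). Rank selection compares, for each candidate signal
rank p, two noise-variance estimates from the discarded eigenvalues of
X Xᴴ/M: their mean, and their spread mapped through the Marchenko–Pastur bulk
width 4σ²√γ; the smallest p whose tail is MP-consistent is kept. The SVD is
computed through the 27×27 Gram matrix. Denoising runs per exam (a config
could concatenate timepoints, not done by default). The external phantom
voxels are excluded: an isolated weak phantom violates the local low-rank
assumption and can be nulled outright.

## Fitting, CRLB, QC

Bounded nonlinear least squares on the stacked real/imaginary time-domain
residuals, with the constraint set canonical prior-knowledge fitting uses for
overlapping resonances:

* one zero-order phase shared by all resonances (relative phases 0, no
  first-order phase);
* one **global frequency shift** (default): chemical shifts are physical
  constants and a B0 offset moves every ²H line together;
  ``shift_mode="individual"`` frees each frequency within ±0.3 ppm;
* one **common line broadening** over the priors' fixed per-resonance
  linewidth offsets (default): shim broadening is common-mode;
  ``damping_mode="free"`` frees each damping within 1–50 Hz FWHM;
* amplitudes ≥ 0, initialized by linear projection onto the prior basis.

Seven free parameters per voxel under the defaults (13 fully unconstrained).
The solver is a Levenberg–Marquardt iteration vectorized across voxels, with
analytic Jacobians, Jacobian reuse across rejected damping retries, and box
projection; deterministic (no restarts). Convergence: relative cost decrease
< 1e−6 or scaled step < 1e−8, cap 50 iterations; non-convergence is flagged,
never raised. Noiseless refits recover parameters to machine precision.

CRLB: σ²(JᵀJ)⁻¹ of the constrained model at the fitted parameters, reported
as 100·sd(a)/a, with σ estimated from the last 10% of the FID unless
supplied. Monte-Carlo at time-domain water SNR 10 shows the amplitude
estimator is CRLB-efficient (SD/CRLB ≈ 1.0, bias < 0.6%). The constraints
matter: they roughly halve the glucose and Glx amplitude bounds relative to
the fully free model (glucose ~12–15% per voxel at study SNR) and bring the
CRLB hierarchy to the magnitudes seen in vivo (water ≪ glucose < Glx ≪
lactate).

QC follows the pre-processing water gate: voxels are fitted only where the
**raw** (pre-denoising) spectral water SNR exceeds 5, and discarded when the
fitted water linewidth exceeds 30 Hz. The SNR gate defaults to the spectral
reading: with noise calibrated to spectral water SNR ≈ 14, the time-domain
ratio sits near 2.4 and a time-domain >5 gate would empty the brain; the
time-domain variant remains config-selectable. Phantom voxels are always
fitted and bypass the brain gate (they are calibration references).

## Corrections and quantification

Pipeline order (extended variant): denoise → fit+QC → saturation correction →
Richardson–Lucy partial-volume correction → bias-field correction. The RL
kernel defaults to a separable |Dirichlet|-integrated CSI response truncated
at ±2 voxels (Gaussian surrogate available), convolved periodically so the
multiplicative updates conserve total intensity exactly; the default of 5
iterations was chosen by end-to-end noise benchmarking on synthetic studies
(more iterations sharpen but amplify map noise). RL treats the brain only —
the phantoms are isolated points, not a partial-volume problem. The bias field is a single order-2 polynomial in
log-intensities estimated from the water map over QC-retained brain voxels
(the multiplicative B1/coil field is common to all resonances) and divided
out of every map, mean-preserving. Estimating the field per metabolite map is
available but ill-conditioned at low SNR (log of near-zero amplitudes).

Quantification modes: **baseline** (voxel-wise ratio to the session's
baseline water reference × 10.12 mM; the reference defaults to an order-2
log-polynomial fit of the baseline water map inside the brain, since the
pre-ingestion HDO level is constant physiology under a smooth B1/coil
profile and the raw voxel values only add reference noise — a config
restores raw-voxel division), **phantom** (two-point line through the
phantom signals at 6.4/19.15 mM; a through-origin check warns when the
intercept exceeds 10% of the low-phantom signal), **cerebellum** (division by
the exam's cerebellum mean of the same metabolite — a scalar, so dividing
maps and dividing regional means coincide; unitless). Quantifying twice is
rejected via the units tag. Regional means are arithmetic means over
QC-retained voxels on the acquisition grid (Fourier interpolation to a finer
grid exists for display, not analysis); empty regions propagate as missing,
never zero.

## Repeatability statistics

Between-subject CoV = 100·SD/mean (sample SD, n−1), sessions averaged per
subject first. Within-subject CoV = 100·[SD(Exam₂−Exam₁)/√2]/grand mean — the
formula's missing denominator is resolved as the grand mean of all
observations in the cell, making it the relative measure the analysis
requires (a per-pair-mean variant is available). Repeatability coefficient =
1.96·√2·wsCoV, so RC/wsCoV ≡ 2.7719 on every emitted row. Bland–Altman bias
and 1.96·SD limits, and an OLS quadratic dynamics fit, complete the module.
All statistics are invariant under common positive rescaling.

## Problem sizes and experiment design

The replicate-study experiments run at a reduced 6×6×6 grid (full 700-point
spectra, exams at 0 and 120 min), chosen so hundreds of complete
simulate-process-analyse cycles run on a desktop. At this scale the brain
holds ~44 voxels, so whole-brain means carry per-exam fit noise of roughly
1% (water), 2–3% (glucose), 4–5% (Glx) and ~15% (lactate) — the CRLB limit
of the constrained model, which the fit attains. Consequently:

* variance-component recovery is assessed on **glucose**, the best-SNR
  enriched resonance (Glx tracks it closely; the lactate whole-brain CoV is
  dominated by fit noise at this scale and honestly over-reads the
  configured values);
* the cerebellum-vs-phantom ordering is assessed on the **glucose
  between-subject CoV**, where both reference modes measure well and the
  n = 6 estimator noise does not blur the ordering (water, diluted by its
  invariant natural-abundance baseline, orders correctly in only ~85% of
  replicates at n = 6).

## Known limitations

Single-Lorentzian lineshapes only (no Voigt, no baseline splines); no
first-order phase; crisp atlas labels (no probabilistic weighting); the
matrix MP-PCA approximates the tensor variant through patch construction;
linear mixed-effects modelling of time/region effects is out of scope —
regional tables report group means only.
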