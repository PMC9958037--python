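# Methods

## Problem setting

Gated phase-contrast (QFlow) MRI of the lower-extremity veins yields, per
vessel setpoint, a stack of 2D through-plane velocity maps over one cardiac
cycle. Four setpoints are analyzed per limb: external iliac (EIV), femoral
(FV), popliteal (PV) and great saphenous (GSV) veins. Superficial venous
reflux — retrograde flow through an incompetent valve — manifests in the
GSV as a substantial backward volume per beat. The package quantifies each
scan into eight hemodynamic parameters, tests which of them separate reflux
from control limbs, and trains an RBF-network classifier on six of them.

## QFlow quantification

The net ROI flux per phase is the sum of in-ROI pixel velocities times the
pixel area (cm/s · cm² = mL/s). Volumes are time integrals over one beat,
taken with the trapezoid rule on the phase grid with the last interval
closing the cycle back to the R–R interval. Forward/backward volumes split
the **net flux by sign at each phase** (default), matching a single signed
flow curve per vessel; a per-pixel split (each pixel's signed velocity
counted separately) is available via `quantify(..., split="pixel")` as a
sensitivity option — the two conventions agree on all net quantities and
differ in FFV/BFV only when antegrade and retrograde flow coexist within
one frame.

Derived parameters: RF = 100·BFV/FFV, reported as *undefined* (`None`) when
FFV = 0 — never silently 0, so degenerate scans cannot corrupt downstream
statistics. SD is SV divided by the ROI area: the net distance a blood
column travels through the lumen per beat, which makes the printed
identities MF = SV·HR/60, MV = SD·HR/60 and MV·area = MF mutually
consistent. Because the same integrator and bins produce FFV and BFV,
SV = FFV − BFV and ASV = FFV + BFV hold exactly, not just to tolerance.

## Synthetic cohort generator

The generator emulates the *measured signal* of a QFlow exam, not MRI
physics: no k-space simulation, no velocity-encoding aliasing, no trigger
jitter, no eddy-current or background-phase offsets. What passing tests
show is therefore that the quantification, statistics and classifier are
correct given clean velocity maps; robustness to scanner artifacts is out
of scope.

**Waveforms.** Venous flow is modeled per beat in closed form. Without
reflux: flux(t) = m·(1 + a·sin(2πt/T)), a mildly pulsatile antegrade
baseline (pulsatility a ∈ [0,1]; antegrade volume exactly m·T). With reflux
fraction f > 0: one antegrade raised-cosine (Hann) lobe of area m·T and one
retrograde Hann lobe of area f·m·T (onset 0.10 T, duration 0.35 T by
default). Hann lobes are C¹ at their boundaries; with the default 30-phase
grid the trapezoid integration error stays below ~0.3% even for arbitrary
lobe/grid alignment (plain half-sine lobes, being only C⁰, would cost ~1%).
Ground truth SV/FFV/BFV/ASV come from the lobe areas, not quadrature, so
truth is exact by construction.

**Rendering.** Inside a circular lumen the velocity profile is parabolic
(Poiseuille); only the area-integrated flux matters downstream, so the
profile choice is inert. The profile is rescaled each phase so the in-lumen
pixel flux sums exactly to the waveform flux, then zero-mean Gaussian noise
(default SD 0.5 cm/s, a plausible phase-contrast noise floor) is added to
every pixel. Grid 64×64 at 0.17 cm/pixel (matching a 1.7 mm in-plane
acquisition voxel); lumen radii 0.50/0.45/0.40/0.35 cm for EIV/FV/PV/GSV.
A lumen under 2 pixel spacings is rejected as unresolvable.

**Cohort.** 26 reflux-patient limbs and 15 healthy-control limbs, one limb
per subject. Heart rate ~ Normal(70, 8) truncated to [40, 120] bpm. Mean
flux per setpoint (mL/s): EIV N(5.0, 1.0), FV N(3.0, 0.7), PV N(1.5, 0.4),
GSV N(0.6, 0.15), shared between groups except the patients' GSV, which is
drawn from N(1.4, 0.3) with reflux fraction ~ U(0.6, 0.95). No reference
flow magnitudes are available for this setting, so these values were chosen
once as physiologically plausible for a dilated refluxing GSV and fixed;
they produce the qualitative target pattern — GSV SV/FFV/ASV/MF separate the groups strongly, EIV/FV/PV do not.
`CohortConfig.effect_scale` interpolates the patients' GSV model toward the
control model; `effect_scale=0` gives an exact null generator used for
type-I-error calibration. All randomness flows from one seed through a
spawned seed tree (one stream for physiology, one per subject for noise),
so identical (config, seed) reproduce the cohort bit for bit.

## Features and standardization

Per limb: [SV_GSV, FFV_GSV, ASV_GSV, MF_GSV, SD_GSV/SD_PV, MF_GSV/MF_PV],
label 1 = reflux limb. Subjects with a missing GSV/PV row or a zero PV
denominator are excluded with a logged reason. The feature set mixes mL,
mL/s and unitless ratios inside one Euclidean distance, so standardization
(per-component zero mean, unit population SD, learned on the training
table) is on by default; disabling it (`standardize=False`) mimics training
on raw units. The second ratio defaults to MF but can be switched to MV
(`ratio="mv"`): both conventions are in circulation for this feature set,
and both are supported rather than hard-coding one.

## RBF network

* **Centers**: Lloyd's k-means (k = 16 default) initialized from a seeded
  sample of k distinct training points; empty clusters are re-seeded to the
  point farthest from its assigned center; stop on stable assignments or
  100 iterations.
* **Width**: one shared scalar σ = √(mean‖x − x̄‖²/p) — the standard
  deviation of the input vectors read as an overall scalar (≈ 1 on
  standardized features). Per-dimension or per-center readings of that
  phrase are equally defensible; per-center widths (mean member distance)
  are available via `per_center_sigma=True` for sensitivity analysis.
* **Output**: y(x) = Σ_j w_j φ_j(x), no bias term, single output unit.
* **Weights**: normalized LMS, w ← w + η/(ε + ‖φ‖²)·(d − wᵀφ)·φ with
  ε = 10⁻⁶, η = 0.5, 200 epochs, zero initialization, seeded per-epoch
  shuffling. The per-epoch step follows the harmonic schedule
  η_ep = η/(1 + ep/25): a fixed step leaves a gradient-noise misadjustment
  floor of order η/(2 − η) above the attainable squared error, whereas the
  decaying step converges to the NLMS fixed point, bringing the final MSE
  within a few percent of the least-squares optimum on typical systems.
  (`step_decay_tau=None` restores the fixed step.) Note the NLMS fixed
  point itself minimizes the input-energy-weighted squared error, so a
  small residual gap to the unweighted optimum is intrinsic when row
  energies vary.
* **Threshold**: swept over {0, 0.01, …, 1} maximizing F-measure on the
  training scores (ties → smallest threshold; decisions use strict >), or
  fixed (the pipeline default is 0.5). F is taken as 0 at thresholds that
  produce no true positive.

## Evaluation and statistics

Sensitivity, precision, accuracy and F-measure are exact ratios × 100;
any zero denominator yields an explicit *undefined* flag. The arithmetic
is exact and internally consistent: on 41 subjects, TPR = 100% together
with ACC = 90.24% forces the matrix tp = 26, fn = 0, tn = 11, fp = 4 and
hence PPV = 86.67% — quadruples pairing those values with PPV = 92.31%
cannot arise from integer counts, and this package only ever reports the
metrics of the actual matrix.

Group comparisons use the classic pooled-variance Student's t
(df = n_a + n_b − 2), two-tailed, with Welch's correction behind a flag;
p values are raw (no multiplicity correction, 24 comparisons), and the
output table carries a note saying so. Two constant samples with equal
means return t = 0, p = 1; with unequal means the test is rejected as
degenerate rather than reporting an infinite statistic.

The pipeline evaluates on the training set by default — all limbs train
the network, the small-cohort regime this design targets — and labels the
report accordingly; `holdout_fraction > 0` switches to a stratified
hold-out split for an honest generalization estimate, clearly labelled
`evaluation_on: holdout`.

## Problem sizes and numerical choices

Default experiments use the full 41-subject cohort (164 cines of 30×64×64
voxels, < 1 s per cohort end to end). The calibration study runs 500 null
cohorts at ground-truth level (no rendering), since pixel noise plays no
role in parameter-level t tests. Monte-Carlo direction checks use 200
seeds. Tolerances: noise-free quantification vs. closed-form truth 0.5%
relative; conservation identities 10⁻⁹; NLMS vs. normal equations 5%;
threshold selection exact against an exhaustive sweep.

## Known limitations

* No MRI physics: phase wrapping, VENC choice, partial-volume edge pixels,
  background-phase errors and trigger jitter are not emulated, so
  real-scanner robustness is untested.
* One limb per subject; the three-limb-group design (patients' morbid and
  normal limbs plus controls) collapses to a two-group comparison here.
* Training-set evaluation overstates generalization by construction; use
  the hold-out mode for anything beyond reproducing the training-stage
  protocol.
* Synthetic effect sizes are calibrated to a qualitative significance
  pattern, not to measured flow magnitudes, so absolute parameter values
  should not be read as normative physiology.
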