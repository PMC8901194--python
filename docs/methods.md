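# Methods

`nirscr` implements a complete analysis chain for block-design fNIRS
motor-task studies, together with a generative model of such a study so
every stage can be exercised and validated without recorded data.  This
note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic validation does and does not
establish.

## Data model

A recording is a raw optical intensity array `[n_samples x n_channels x
n_wavelengths]` in volts plus a montage and an event list.  The default
montage models an 8-optode wearable device placed symmetrically over the
two motor cortices: each optode contributes a 7.5 mm short-separation (SS)
channel, and adjacent optodes pair into 16 long-separation (LS, 30 mm)
channels.  The two LS channels of an adjacent optode pair probe the same
patch of cortex and define one of 8 regions of interest (ROIs); ROI 1 is
the left M1 (contralateral to right-hand movement), ROI 5 the right M1.
Channel role is a pure function of separation with a 10 mm boundary.  LED
wavelengths are 774, 817, 865 and 892 nm; the sampling rate is 8.98 Hz.
Time is seconds from recording start; sample 0 is t = 0; windows are
half-open `[start, end)`.

On disk, recordings are SNIRF (HDF5) files or, for inspection, CSV bundles
(one intensity matrix per wavelength plus a JSON sidecar).  Source and
detector positions cannot simultaneously realize every nominal separation
exactly, so the SNIRF writer also stores the montage verbatim in a metadata
tag; the reader prefers it and falls back to position-derived separations.
Round trips are lossless.

## Preprocessing

1. **Optical density.**  `od = -log10(I / I_ref)` with the reference the
   mean intensity over the leading 120 s rest (configurable).
2. **Motion correction** (spline scheme).  Artifacts are detected where the
   1 s moving standard deviation exceeds `median + 3 x 1.4826*MAD` of its own
   distribution — a robust rule that stays silent on stationary physiology.
   Within a flagged segment, a smoothing-spline trend (the artifact) is
   subtracted and replaced by a straight bridge between the adjacent clean
   levels, which removes spikes and baseline steps while keeping the series
   continuous at both segment ends; clean samples are untouched.  The
   smoothing parameter p = 0.99 is mapped to the spline penalty with a
   sampling-interval normalization (`lam = (1-p)/p * (1/fs)^3 * 1e-2`)
   chosen so that second-scale transients are tracked; the 10x-sd step test
   in the suite pins this behavior.
3. **Modified Beer–Lambert law.**  Per sample and channel the 4x2 system
   `od(lambda) = eps(lambda,.) * dC * dpf(lambda) * d` is solved by least
   squares (overdetermined: 4 wavelengths, 2 chromophores), giving
   oxy/deoxyhemoglobin changes in uM.  Differential pathlength factors
   default to (6.2, 6.2, 5.9, 5.5).  The extinction-coefficient table is
   pinned in `preprocess.EXTINCTION_CM_PER_M` (values consistent with the
   standard compiled hemoglobin spectra) and user-overridable; the simulator
   uses the identical forward map, so simulation -> inversion round trips
   are exact by construction (validated to < 1e-8 uM).
4. **Band-pass.**  Zero-phase (forward–backward) Hamming-windowed-sinc FIR,
   order 1000, 0.015–0.35 Hz: removes drift below and cardiac pulsation
   above the task band.  Whether the original offline chain was zero-phase
   is an open choice; zero-phase avoids latency bias in the GLM.  Task
   regressors are passed through the same filter so the canonical
   coefficient keeps amplitude units (without this the estimates shrink by
   the filter's in-band loss).

The *unfiltered* hemoglobin series is retained because the quality metrics
need the cardiac band.

## Signal quality and physiology metrics

Band powers are Welch estimates (Hann, 60 s segments, 50 % overlap,
rectangular band integration).

* **Raw signal strength**: per-channel mean intensity and
  `20 log10(mean/sd)` over the leading rest, averaged across wavelengths.
  Subject-level screening passes when the long-channel mean intensity is
  >= 0.06 V; on the modeled detector (white noise 6e-4 V) this corresponds
  to a 40 dB SNR.  Both thresholds are independent configuration values.
* **Short-channel quality**: cardiac content, `10 log10` of 0.6–2 Hz power
  over 2–4 Hz background power on unfiltered O2Hb, pass at >= 12 dB.  The
  background band is a documented choice.
* **Mayer-wave amplitude**: per LS channel, O2Hb band power 0.07–0.14 Hz
  normalized by the 0.6–2 Hz pulse power; the subject value is the median
  over LS channels.  The ratio is scale-free, so it isolates the relative
  strength of ~0.1 Hz systemic oscillations.

## Activation GLM with non-negative short-channel regression

The design contains, per condition, the boxcar convolved with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, 32 s support,
peak-normalized), plus temporal (1 s onset shift) and dispersion
(peak-dispersion perturbation) derivative regressors orthogonalized against
the canonical column, a constant, and — for SCR — the band-passed,
mean-centered O2Hb (resp. HHb) series of every short channel passing the
12 dB check.  Task regressors are normalized so an isolated trial peaks at
1; the canonical coefficient is then the per-trial peak response in uM.

Nuisance weights are constrained to `w >= 0`: scalp physiology can only add
to a long channel, and the constraint stops the regression from inflating
the task estimate with inverted scalp signals.  The mixed problem

    min || y - F b - N w ||^2,  w >= 0,  b free

is solved exactly by block elimination: project the free columns `F` out,
solve the reduced problem with active-set NNLS, back-substitute `b`.  A
500-problem exhaustive sign-support enumeration pins the solver to the
global optimum within 1e-8.

The activation statistic is `t = beta_canonical / se(beta_canonical)` with
the standard error from the design restricted to the free columns plus the
*active* nuisance set, and `dof = n - n_free - n_active` (standard
active-set practice; validated by the null calibration below).  The
derivatives absorb onset/shape misfit but do not enter the contrast.
O2Hb long channels are regressed on O2Hb short channels and HHb on HHb; no
cross-chromophore regression.  Zero-residual fits are capped at t = 1e6
with a warning.  ROI values are the arithmetic mean of the ROI's two
channels.

**Baseline-derived thresholds.**  Significance thresholds come from the
null: the full randomized 30-trial protocol is repeatedly placed at random
admissible shifts within task-free rest data and refitted, and the
threshold is the 95th percentile of the absolute null t-values (absolute
values, a documented choice).  Null designs use unfiltered task regressors;
the calibration test shows a fresh null sample exceeds the derived
threshold 5 % +- 1.5 % of the time for both NR and SCR designs.  The
shipped defaults, `DEFAULT_T_THRESHOLDS = {"SCR": 30, "NR": 22}`, are the
conventional values for the study this package models; thresholds derived
from synthetic rest depend on the generator's noise spectrum and need not
match them.

**Responder labeling.**  Per run the maximal t over channels is taken, the
four runs are averaged, and the subject is "strong" iff the mean strictly
exceeds the threshold (exactly 30 is weak).

## Test-retest statistics

For each chromophore x hand x processing tag, the t-values at the
contralateral M1 ROI (right hand -> ROI 1, left -> ROI 5) are averaged over
the two runs of each session and compared across the two sessions:

* Pearson r with Fisher-z 95 % CI and two-sided p;
* ICC(2,1) and ICC(2,k): two-way random effects, absolute agreement, from
  the ANOVA mean squares; confidence intervals follow the McGraw–Wong
  F-based formulas, with the averaged-measure bounds obtained by
  Spearman–Brown transformation of the single-measure bounds.  The
  implementation is validated against pingouin and against a textbook 6x4
  reliability table to 1e-6.  Interpretation bins: poor < 0.40 <= fair
  < 0.60 <= good < 0.75 <= excellent;
* MAE%: `100 * mean|t_s2 - t_s1| / range` with the range over the *pooled*
  two-session values (per-session vs pooled is ambiguous in common usage;
  pooled is the documented choice).

## Pseudo-online classifier

The causal chain never looks ahead: a forward-only Chebyshev-II order-2
high-pass at 0.005 Hz (20 dB stop band, a documented default) and
Butterworth order-4 low-pass at 0.35 Hz; then sample-wise adaptive SCR via
normalized LMS with projection onto `w >= 0` (step 0.005).  Per 16 s trial
window and long channel the features are amplitude (window mean minus the
value at onset — "amplitude" could also mean peak; this is the documented
choice), slope (least-squares line), and the mean of the CBSI-combined
trace `x = (dO2Hb - sigma*dHHb)/2`, `sigma = sd(dO2Hb)/sd(dHHb)` within the
window.  A linear SVM with L1 penalty is trained on run 1 (features
standardized with training statistics; C chosen from 10 log-spaced values
in [1e-3, 1e2] by stratified 5-fold CV) and evaluated on run 2; decisions
fall at trial end.  The 70 % line is the conventional display threshold for
1 % significance on 30 binary trials; the exact binomial computation
(73.3 % for n = 30) is provided alongside.

## The synthetic study generator

The generator emulates a 15-subject, 2-session, 2-run test-retest study
with known ground truth.  Each run contains:

* **Cortical responses** per ROI: lateralized double-gamma responses
  (contralateral M1 weight 1.0, premotor neighbours ~0.4, ipsilateral M1
  0.2; left-hand responses 0.8x the right-hand scale), O2Hb positive, HHb
  at -0.4x the O2Hb amplitude.  Session and run effects are small
  multiplicative lognormal factors (sd 0.12 and 0.05).
* **One superficial signal per hemisphere**: a Mayer oscillation
  (0.095–0.11 Hz sinusoid with slowly wandering amplitude, 0.26 uM x the
  subject's `mw_amplitude`), cardiac pulsation (1–1.3 Hz, 0.7 uM), a linear
  drift (0.2 uM/min) and band-limited 1/f background (0.23 uM, < 0.5 Hz).
  Short channels carry only this signal; long channels add a ~0.4
  superficial share.  Partial spatial correlation among short channels —
  the premise of multichannel SCR — comes from channel-specific gains.
* **Private cortical background** per long channel: 1/f-shaped noise in
  0.03–1.2 Hz (0.03 uM), representing spontaneous hemodynamics that no
  regression can remove.
* **Forward optics**: the same MBLL map as the inversion, scaled to the
  subject's raw intensity (short channels receive 30x the light of 30 mm
  channels, as their much shorter photon path implies), plus white detector
  noise of 6e-4 V, anchoring the 0.06 V <-> 40 dB correspondence.

Coupling quantities — per-channel superficial gains and light coupling —
are optode-placement properties and are drawn once per subject, so they are
identical across that subject's sessions and runs.

Nine subjects are strong responders (amplitude N(0.40, 0.05) uM, intensity
lognormal around 0.22 V).  The strong-responder amplitude was set so that
the 15-subject *group mean* contralateral response lands at ~0.26 uM O2Hb,
the scale typical of published group averages for hand grasping — a group
mean necessarily understates its strong members.  Six subjects are weak:
five have raw intensities of 0.02–0.045 V (below the 0.06 V screen; the
detector noise then dominates their hemoglobin estimates) with ~0.09 uM
responses, and one has good optics but a near-absent response (0.04 uM)
with 2.5x Mayer amplitude.  With these conditions the simulated study
reproduces the qualitative structure such a study reports: strong-responder
SCR t-values above the t >= 30 threshold and clearly above their NR values,
weak responders in the 13–25 range, a canonical strong responder classified
at ~95 % and short-channel-only input at chance.

**What the generator does not model**, and hence what passing tests cannot
show: real optode-coupling drift within a run, trial-to-trial response
variability, task-evoked systemic (scalp) responses, subject motion beyond
parametric spikes/steps, spatially continuous sensitivity profiles (ROI
responses are piecewise-constant across channels), or autocorrelated
detector noise.  Simulated strong-responder t magnitudes (~100–300) run
higher than typical published strong-responder values (~30–70): per-trial
decodability around 95 % combined with ~12,600-sample runs and the
generator's noise spectrum yields a larger t scale than real recordings,
where unmodeled within-band structure inflates residuals.  Conclusions
about t *ratios* (SCR vs NR, strong vs weak) transfer; absolute t scales
are study-specific.  For the same reason the simulated between-subject
spread dominates the session-to-session variance, so test-retest ICCs
saturate near 0.93 for *both* processing variants: in this generator the
benefit of short-channel regression shows in the t-values and in amplitude
recovery (RMSE down ~70 %), not in the ICC, whereas studies with a
narrower subject range can see the ICC itself rise after regression.

## Problem sizes used in validation

The test suite simulates the full 15 x 2 x 2 study once for the
SCR-efficacy, spatial-specificity and screening checks; null calibration
uses 1000 threshold draws plus 1000 fresh draws per design; classifier
checks average four independent session pairs; determinism is asserted by
running a 3-subject study end-to-end twice.  The acceptance script runs the
complete study (all three classifier inputs) and derives thresholds from
500 draws.  These sizes are the package's validation choices; all scale up
via `SimConfig`.

## Known limitations

* The GLM assumes white residuals when converting to t; fNIRS residuals
  are autocorrelated, which is why thresholds are calibrated empirically
  from the baseline null rather than from a t-distribution.
* ICC confidence intervals assume balanced complete data and normal errors.
* The adaptive filter's non-negative projection makes its zero-gradient
  weights a reflected random walk with a small positive bias proportional
  to sqrt(step); with the default step this bias is negligible relative to
  superficial gains.
* The linear mixed-effects analysis with multiple-comparison contrasts
  sometimes reported alongside these statistics is out of scope; standard
  REML tooling applies directly to the tidy activation tables.
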