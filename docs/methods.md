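# Methods

`cardiomap` analyzes optical-mapping movies of paced 3D human cardiac
microtissues: voltage-dye fluorescence stacks are segmented into
per-tissue action-potential (AP) traces, eight pro-arrhythmia metrics are
measured per beat, and study-level statistics (replicate-variability
decomposition, dose-response maps, a triangulation-slope indicator of
hERG block) are computed on top. Because raw recordings of this kind are
rarely shared, the package ships a first-class synthetic module that
generates ground-truthed inputs with the same statistical and
physiological structure; every claim the test suite makes is a claim
about the pipeline's behavior on that generator, and the end of this
note spells out what that does and does not show about real data.

## Synthetic action potentials and the metric oracle

A single AP is modeled as the product of two logistic sigmoids — an
upstroke with time constant `tau_up` (default 2 ms) and a phase-3
repolarization centered at `t_repol` (default 400 ms) with time constant
`tau_repol` (default 15 ms) — multiplied by an exponential plateau decay
(`plateau_decay`, default 5e-4 /ms). This family was chosen because the
level-crossing durations (APD30/50/80), the curvature-defined APD_MxR,
and triangulation can be steered independently. An optional early
afterdepolarization (EAD) is a Gaussian bump (amplitude a fraction of
the AP amplitude, width 40–80 ms) added during the plateau, gated by the
phase-3 sigmoid so it vanishes once the cell has repolarized.

Truth values come from a brute-force oracle that is deliberately
independent of the measurement code: the analytic waveform is sampled on
a ≥10 kHz grid, durations are read off by direct definition scan with
linear interpolation at level crossings, and the two arg-max quantities
(upstroke time, maximum curvature) are refined by bounded scalar
optimization of fixed-step finite differences of the *analytic* waveform,
which makes the oracle insensitive to the bracketing grid (10 kHz vs
100 kHz agree within 0.03 ms over 50 random draws).

Random fixture draws place EADs conservatively: on a declining plateau
(decay ≥ 5e-4 /ms), at least 1.5 bump-widths after the AP crest, and
ending 3.5 repolarization time constants before the phase-3 midpoint. A
bump merged into the AP crest or superposed on the steepest phase-3
descent does not produce a distinct secondary depolarization (no
derivative sign reversal) and is not what the detector — or an
electrophysiologist — would call an EAD.

## Movie rendering

Scenes emulate the acquisition geometry of a macroscope EMCCD recording:
64×64 pixels at 18.7 µm/px (a 1.2×1.2 mm field), 979 frames/s, circular
tissues of radius ~7.4 px (~170 pixels). Per-pixel signal is
`baseline ± baseline·waveform(t)` with the sign set by the dye polarity
(default `inverted`: fluorescence dips on depolarization, as for
di-4-ANEPPS under common filter sets) plus i.i.d. Gaussian read noise.
Overlapping tissues are rejected — microtissues in a mold are spatially
distinct. Not modeled: photon (Poisson) statistics, EMCCD gain noise,
photobleaching, motion, and 3D light scattering.

## Segmentation

Active pixels are found spectrally: each pixel trace is linearly
detrended and Fourier transformed, and scored by the fraction of non-DC
power inside ±1-bin bands around the pacing fundamental and its first
three harmonics (APs are strongly non-sinusoidal, so the harmonics carry
most of the beat power). Scores lie in [0,1]; a paced pixel scores near
1 while white noise scores near the band fraction of the spectrum. The
score map is thresholded (Otsu by default; a fixed threshold is
available for reproducibility), 8-connected components are labelled,
components of ≤60 pixels are discarded (strictly greater than 60
retained), and single-pixel holes are filled. Components touching the
field border are retained. The per-tissue trace is the plain average of
raw pixel intensities over the ROI, negated for inverted polarity, and
normalized to ΔF/F using the diastolic fluorescence F0 (mean over the
lowest quartile of the sign-corrected trace — robust to the pacing duty
cycle at 0.5 Hz, where diastole occupies most of the cycle).

ROI labels are assigned in row-major centroid order. A single noise
pixel can perturb a centroid enough to swap the order of two tissues at
the same image row, so evaluation code matches ROIs to ground truth by
maximal overlap, never by label index.

## Per-beat metrics

One beat window per stimulus, spanning pulse onset to the next pulse
(spontaneous, non-stimulus-locked activity is ignored). A beat is
**captured** when a deflection of at least 50% of the median candidate
amplitude reaches its maximum dF/dt within 300 ms of the pulse; both
numbers are configurable, as no standard definition exists. The
diastolic baseline is the median of the last 10% of the preceding
window. **Excitability** is exactly 100·captured/delivered.

For captured beats, with derivatives taken on a zero-phase
Savitzky–Golay-smoothed trace (5 ms window for the first derivative):

- **stim delay** — pulse onset to the time of maximum dF/dt (t_act);
- **rise time** — 10–90% amplitude crossing interval on the upstroke,
  linearly interpolated (the standard convention; 10–90% was chosen
  where the field also uses 20–80%);
- **APD30/50/80** — t_act to the first fall to (1 − x/100) of the beat
  amplitude above baseline, linearly interpolated. Levels are referenced
  to per-beat amplitude, never absolute voltage: dye signals are
  uncalibrated;
- **APD_MxR** — t_act to the maximum of the second derivative (11 ms
  smoothing window) searched from the APD50 crossing to shortly after
  the 95%-repolarization crossing (+20 ms margin; window end if that
  level is never reached, e.g. under a sustained EAD). Bounding the
  search is essential on noisy traces: after repolarization completes
  the true curvature is ~0 and an unbounded arg-max locks onto diastolic
  noise. A parabolic fit around the discrete arg-max gives sub-sample
  timing;
- **triangulation** — APD_MxR − APD50, exactly;
- **EAD flag** — between the end of the upstroke (first derivative zero
  after max dF/dt; not the global max, which a large EAD can itself be)
  and 90% repolarization, the smoothed derivative must reverse from
  negative to positive and the rebound must rise ≥5% of the beat
  amplitude above the local minimum — measured against the extrapolated
  falling base so a bump riding a declining plateau is not under-read,
  with the rebound bounded at the next local maximum — and persist
  ≥20 ms. EAD detection uses a wider 21 ms smoothing window than the
  duration metrics: EADs evolve over tens of milliseconds, and the wider
  window suppresses noise wiggles that mimic small re-depolarizations.
  With these defaults the detector is fully sensitive to noiseless bumps
  of ≥10% amplitude and false-alarms on ≤5% of clean beats at 2% noise.

EAD beats keep their APD values and feed the per-tissue summaries (EADs
are a major contributor to APD prolongation and must not be censored);
a tissue with no captured beats has all metric summaries unavailable.

Measured against the brute-force oracle over 50 random waveforms
spanning APD 100–600 ms at 979 Hz, APD30/50/80 agree within one sample
period (~1.02 ms) and APD_MxR within two.

## Ionic model

For direction claims that need mechanism rather than geometry, the
package integrates the Bueno-Orovio–Cherry–Fenton minimal ventricular
model (epicardial parameter set; forward Euler, 0.05 ms step, numba-JIT
compiled and vectorized over cell populations). Three conductance
multipliers act as block surrogates: `g_kr_scale` on the high-voltage
slow-outward current (plateau/phase-3 repolarization; reduction emulates
hERG/I_Kr block), `g_to_scale` on the low-voltage outward current
(terminal repolarization; I_to-class block), `g_cal_scale` on the slow
inward current (plateau; I_CaL). Cells are paced to steady state
(period-1 at 2000 ms cycle length: consecutive APD80 differ by <0.5 ms
after 8 beats) and the last beat is measured by the same metric code as
experimental traces. Only directions and slope orderings are claimed —
never quantitative agreement with any particular myocyte model, whose
parameterization is not being reproduced here.

The dose-series scenario draws per-tissue lognormal jitter (CV 0.10) on
all three conductances — the channel-density spread across real tissues
— and compares graded series against a shared control at matched n=12:
repolarization block at 0.8/0.6/0.4 (the 20–60% block range typical of
E4031/4-AP studies) and a deliberately moderate inward-current
enhancement at 1.1/1.2/1.3. The moderation matters: pushed to 1.5–2×,
the model's plateau prolongs disproportionately toward EAD-like
dynamics and the triangulation slope rises for a reason unrelated to the
repolarization-block mechanism under test. Under these conditions only
the hERG-surrogate series shows a significant slope increase of
triangulation vs APD_MxR (slope-equality Z > 1.96 at the top dose),
robustly across seeds.

## Statistics

- **Variance decomposition** is the plain sequential-SD scheme, not a
  REML mixed model: per-tissue SD across beats (beat level), SD of
  tissue means within mold (tissue level), SD of mold means within batch
  (mold level) — each averaged within batch and reported mean ± SD
  across batches — and the SD of the batch means (a single number; with
  one set of batch means it carries no dispersion). These are the
  directly quotable replicate SDs a screening lab reports; each level is
  upward-contaminated by the levels below it (e.g. tissue means carry
  beat noise /√n_beats), which is visible in the Monte-Carlo recovery:
  at the default nesting (4 batches × 3 molds × 35 tissues × 5 beats,
  SDs 6.4/36.1/31.8/19.3 ms) the beat/tissue/mold medians over 200
  replicates land within ~10% of truth while the batch component — four
  means, contaminated by mold noise — is biased high by ~20–30%.
- **Normality** is a one-sample KS test against a normal with the sample
  mean and SD; the plain (estimated-parameters-ignored, hence
  conservative) p-value is the default and a Lilliefors correction is
  optional.
- **Paired dose tests** are two-tailed Student t-tests; an exactly
  constant nonzero shift has zero difference variance and is flagged
  degenerate rather than assigned an infinite t.
- **Sample size** for a relative change is computed by exact noncentral-t
  power iteration for one-sample/paired designs, returning the smallest
  n reaching the requested power (minimum 2). The convention behind any
  particular published headcount (sidedness, which SD, what "confidence"
  means) is rarely recoverable, so alpha, power and design are explicit
  arguments rather than hard-coded.
- **Shift maps** standardize each (tissue, metric, dose) cell by the
  control mean and SD of that metric over excitable control tissues;
  non-excitable cells are unavailable (rendered black). **Signature
  maps** report mean paired differences vs control normalized by the
  control SD, with paired-t significance at p<0.05. No multiple-testing
  correction is applied by default, matching common screening practice;
  a Holm option exists at the call sites that want it.
- **Slope comparison** fits ordinary least squares of triangulation on
  APD_MxR per dose and tests slope equality against control with
  Z = (b_d − b_ctr)/√(SE_d² + SE_ctr²) on the standard normal. With n=50
  points per fit the test holds its nominal 5% size within Monte-Carlo
  error (the normal reference slightly inflates size at much smaller n).

## Problem sizes and numerical choices

Test and acceptance runs use 8 s recordings (7832 frames) at 0.5 Hz
pacing, 4 tissues per field, 50-waveform oracle sweeps, 200-replicate
variance recovery, 5000-replicate null calibrations and 20000-replicate
power simulations — sizes chosen so the full suite completes in minutes
on one core while keeping Monte-Carlo error well inside the asserted
tolerances. All stochastic operations take explicit seeds; there is no
hidden global random state. CSV/JSON writers use fixed column order and
float formatting, so identical inputs produce byte-identical outputs.

## Limitations

The generator validates the pipeline's measurement logic, not its
robustness to everything real recordings contain: motion, bleaching
drift beyond linear detrending, spatially correlated noise, conduction
within a tissue (each synthetic tissue is perfectly synchronous), and
spontaneous beats are all absent. Passing tests therefore demonstrate
correctness of the definitions and their statistical behavior under the
stated noise model, and the direction claims of the ionic scenario —
not accuracy on any particular experimental dataset. CLI exit codes are
0 (success), 1 (application-level input error), 2 (usage errors from
option validation and stage failures).
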