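# Methods

`arousalpipe` analyzes multimodal recordings from pupil-based biofeedback
experiments in which participants volitionally up- or downregulate their
pupil size, and pairs every analysis stage with a seeded synthetic cohort
generator so that the full chain is testable without human data.  This
note documents the models, the defaults and their rationale, the numerical
choices, and what the synthetic cohorts can and cannot show.

## Experimental designs emulated

Three session layouts are built in (`synthetic.PHASE_DURATIONS`,
`TRIALS_PER_CONDITION`):

* **exp1 (TMS):** 20 trials x {up, down, rest}; 1 s instruction, 4 s
  baseline, 15 s modulation; two TMS pulses per trial (first uniformly in
  3-4 s, second at 11 s after modulation onset), i.e. 40 MEPs per
  condition; pupil, EMG (5 kHz) and R-peak streams.
* **exp2 (EEG):** 30 up + 30 down trials; 2 s instruction, 3 s baseline,
  15 s modulation; pupil, 64-channel EEG (250 Hz) and R-peak streams.
* **exp3 (oddball):** 9 blocks x 13 trials of {up, down, control}; 4 s
  baseline, 18 s modulation carrying 8 tones with onset gaps uniform in
  [1.8, 2.2] s; the first tone is always a standard, each trial carries
  one or two targets with at least two standards between targets, so
  consecutive targets are never closer than 5.4 s.  A 117-trial session
  holds exactly 186 targets and 750 standards; the 69 two-target / 48
  one-target split is the unique integer solution to those totals and is
  generated explicitly.

Condition block orders are counterbalanced with a seeded cyclic Latin
square (cohort-level base permutation, rotated per participant).

## Synthetic cohort model

Each participant draws a latent arousal-regulation factor
`z ~ N(0, latent_arousal_sd)` (default SD 0.4).  The coupled measures —
pupil modulation depth and aperiodic-exponent shift — scale
multiplicatively with `1 + z`, plus independent between-subject noise
sized so the resulting cross-measure correlation between the pupil
modulation index and the slope change is ~0.5-0.6, the regime needed to
exercise the index-correlation analyses.  Uncoupled measures (heart rate,
RMSSD, MEP, P300) get independent between-subject scatter.

Default condition effects (the cohort the acceptance suite uses):
pupil +-0.25 mm (up/down), exponent 1.85/2.15 (down steeper by 0.3),
heart rate +-1.5 bpm, RMSSD -+2.5 ms, MEP 1.15/0.85 mV around a 1.0 mV
rest mean (30% of rest up-down), target P300 7 uV in downregulation vs
5 uV elsewhere, standards evoke a fixed 1 uV late positivity, N100 -3 uV
everywhere.  The default cohort size is 12 participants — the scale at
which the whole test matrix runs on one CPU while every headline effect
is still detected with power >= 0.95.

Signal models:

* **Pupil (60 Hz, two eyes):** baseline diameter per participant
  (N(4.5, 0.5) mm clipped to [3, 6.5]); a raised-cosine ramp reaches the
  condition plateau in 1.5 s (so the 15-s window mean stays within
  0.05 mm of the plateau delta); slow (<=1 Hz) Gaussian fluctuations,
  binocular blink gaps (Poisson, 0.12/s, 100-300 ms) and single-sample
  spike artifacts with a stored ground-truth mask.
* **EEG (250 Hz, 64 channels):** Gaussian noise shaped in the frequency
  domain to a one-sided PSD `P1 * f^-chi` (P1 = 100 uV^2/Hz at 1 Hz) with
  an optional 10 Hz oscillatory bump that is Gaussian in log10 power
  (default height 0.6).  Synthesis draws the complex spectrum directly
  and inverse-transforms (exact spectral control); float32 throughout.
  For oddball trials each tone adds a -3 uV deflection peaking at 100 ms
  (sigma 40 ms, all channels) and a late positivity peaking at 350 ms
  (sigma 80 ms) over the standard centroparietal 24-channel subset.
  Artifact bursts (0.2 s) arrive as a Poisson process whose rate is set so
  ~10% of 3-s analysis bins overlap a burst.  An `erp_windows_only` mode
  synthesizes background only around tone epochs for ERP-only studies.
* **R-peaks:** alternating-jitter construction: intervals alternate
  +-d around 60/HR with extra Gaussian jitter sigma (default 10 ms), with
  `4 d^2 + 2 sigma^2 = RMSSD^2`, so the sample RMSSD matches the target in
  expectation while the mean interval stays 60/HR.  Unreachable
  combinations (RMSSD < sqrt(2) sigma, or intervals that would become
  non-positive) raise.
* **EMG (5 kHz):** 30-800 Hz band-limited background at the configured
  RMS; each pulse injects a biphasic template (140 Hz carrier under a
  6 ms Gaussian envelope, support confined to 15-60 ms post-pulse) scaled
  to the trial's true MEP with unit-mean lognormal variability (sigma
  0.2).

What the generator does **not** model: realistic waveform morphology
(ECG, EMG spikes, ocular artifacts), volume conduction / channel
covariance (channels are independent), non-stationarity within a trial,
eye-movement artifacts in gaze, or behavioral reaction times.  Passing
tests therefore demonstrate correctness of the analysis machinery and
its calibration, not robustness to every pathology of real recordings.

## Online feedback scoring

Samples are rejected for blink flags, diameters outside [1.5, 9] mm, or
velocity relative to the last valid sample above the threshold.  The
threshold's printed value 0.0027 is interpreted as mm/ms (2.7 mm/s) by
default: read literally as mm/s it would reject essentially every
physiological change, contradicting the reflex velocities it was derived
from.  Both unit readings are selectable.  Success requires a strictly
sign-correct mean change (exact zero fails both directions); the feedback
circle is green exactly for success.  The online baseline uses all valid
baseline-phase samples (not only the final second).  Isoluminance uses
Y = 0.2126 R + 0.7152 G + 0.0722 B.

## Offline pupil preprocessing

Per eye: (1) dilation-speed filter — per-sample speed is the larger of
the backward/forward difference rate; threshold = median + 12 MAD;
(2) four deviation-from-trend passes — trend is a zero-phase 4 Hz
Butterworth (order 3) low-pass of the linearly interpolated valid
samples, threshold = median + 12 MAD of absolute residuals, recomputed
per pass; (3) removal of valid islands <= 50 ms isolated by > 40 ms gaps
on both sides (trace edges count as gaps).  Eyes are then averaged on
the raw grid (single-eye value where only one is valid), resampled by
linear interpolation to 1000 Hz (gaps > 2 s stay missing), and smoothed
with the same zero-phase low-pass.  The missing fraction is computed
before interpolation; trials above 50% missing are rejected.

Two numerical floors protect the MAD statistics on low-noise data, where
MAD tends to zero and arbitrarily small residuals would be flagged: the
trend-deviation threshold is floored at 0.01 mm (tracker quantization
scale) and the speed threshold at 1 mm/s (well under physiological peak
velocities).  Neither floor is active on realistically noisy traces.

Baseline correction subtracts the mean of the last 1000 ms before
modulation onset.  The pupil modulation index is the per-millisecond mean
up-minus-down difference over the 15-s window (15,000 points) and its
scalar mean; exp1 uses the mean over the 150 ms before each TMS pulse.

## Spectral slope (aperiodic exponent)

Welch PSD: 1-s segments (`fs` samples), 50% overlap, 1 Hz grid restricted
to 1-45 Hz.  500-ms oddball bins use a single segment zero-padded to 1 s
so the grid is preserved.  The default taper is **Hann**: its fast
sidelobe roll-off keeps low-frequency leakage out of the 30-45 Hz band
even at chi = 3, where Hamming's -43 dB sidelobes floor the band and
destroy the estimate (measured: chi = 3 recovered as 2.4 with Hamming vs
3.006 with Hann).  Any scipy window name can be passed.

The parameterization models log10 power as a line (slope -chi) plus up to
3 Gaussian peaks: OLS line; robust refit keeping points whose clipped
positive residual is below the 2.5th percentile (drops peak-inflated
points); iterative peak extraction from the flattened spectrum (accept
the maximum while above max(2 SD of the flattened spectrum, minimum
height 0); initial width from the half-height crossing; Gaussian fit with
center bounded to the fit range and SD bounded to [0.25, 6] Hz, i.e.
widths 0.5-12 Hz); a joint refit of all peaks; peak-subtracted robust
line refit; R^2 and mean absolute error in log space.  Gaussian fits use
a small box-constrained Levenberg-Marquardt (analytic Jacobian, projection
onto bounds, relative-cost tolerance 1e-5/1e-6, <= 15/25 iterations),
numba-compiled when available with an identical pure-numpy path.

Exact power laws recover chi to machine precision with zero peaks; a tall
peak straddling the fit-range edge is not separable from the aperiodic
component (a limitation shared by all parameterizations of this family).

Bins: exp2 uses one 3-s baseline bin plus five 3-s modulation bins; exp3
uses one 500-ms pre-tone bin plus four post-tone bins.  Artifact-flagged
bins are excluded, spectra are averaged across trials per cell, fitting
happens once per channel on the average, and the whole-head value is the
arithmetic mean of per-channel exponents.  The slope modulation index is
chi_up - chi_down per participant.  Index correlations and the
slope-P300 correlation are computed on the *signed* slope (-chi), the
convention in which "steeper during downregulation" is a positive slope
change; signs are stated in the output tables.

## ERP analysis

Epochs run -100..796 ms at 250 Hz (225 samples) around tone onsets;
baseline correction subtracts the mean over [-100, 0) ms.  Epochs are
dropped for artifact overlap or invalid behavior (missed target, false
alarm).  P300 = mean amplitude over 252-600 ms (inclusive endpoints on
the grid: 88 samples) across the standard centroparietal 24-channel set;
the N100 window is 52-200 ms.

Cluster test: point-wise paired t values thresholded at the two-sided
critical value for p = .05 with df = n-1; suprathreshold points grouped
by sign into spatiotemporally contiguous clusters (channel adjacency =
distance cutoff at 1.6x the median nearest-neighbor spacing, median 5
neighbors on the shipped montage; temporal adjacency = consecutive
samples); cluster mass = summed t.  The null is the maximum |mass| over
sign flips of the participant difference waves — full enumeration when
2^n <= n_perm, else Monte-Carlo — and each cluster's p counts the
observed statistic in its own null (p >= 1/(n_perm+1)); the max statistic
controls the family-wise rate across both signs.  A relative tolerance of
1e-9 on the null >= observed comparison keeps BLAS summation-order noise
from dropping the identity permutation.  The three condition contrasts
are Holm-corrected per window.

## Cardiac and MEP analysis

RR intervals count toward a phase only when both bounding peaks fall
inside it.  Heart rate is 60/RR averaged per phase; RMSSD is the RMS of
successive interval differences in ms (>= 2 intervals).  Exp2 indices:
HR_up - HR_down and RMSSD_down - RMSSD_up; exp1 divides by the resting
control first.

EMG is band-passed 30-800 Hz (Butterworth order 4) with a 50 Hz notch
(Q = 30), zero-phase.  Pre-pulse (bgEMG, RMS over -105..-5 ms) and
post-pulse (MEP peak-to-peak over 15-60 ms) windows are filtered on
segments that never cross the pulse: filtering them jointly lets the
zero-phase high-pass smear MEP energy backwards into the background
window (a defect this package had and fixed; it produces
condition-dependent bgEMG and spurious participant exclusions).
Exclusions run in order: records with bgEMG > 0.01 mV; records above the
participant's pooled mean + 2.5 sample SDs of the remainder; whole
participants whose surviving up/down bgEMG means differ by > 0.001 mV.
The normalized bgEMG difference (up-down)/mean is exported as a
covariate.  Condition means are divided by the rest mean; an optional
participant -> mental-strategy label map adds Holm-corrected per-group
up-vs-down contrasts.

## Statistical layer

Paired/one-sample t with Cohen's d_z (mean difference / SD of
differences); Wilcoxon signed-rank with the exact distribution up to
n = 25 (rank-sum polynomial, midranks doubled to integers; two-sided
p = 2 min(cdf, sf) capped at 1) and the continuity-corrected normal
approximation above; Holm step-down adjustment with monotonicity.

The within-subject ANOVA (1-3 factors) uses the balanced-factorial
decomposition `SS(T) = sum_{V subseteq T} (-1)^{|T|-|V|} R(V)` with
`R(V)` the marginal squared-total term; each effect is tested against
its interaction with subjects.  Greenhouse-Geisser epsilon comes from the
covariance of orthonormal (Helmert) contrast scores,
`eps = tr(S)^2 / (d sum S^2)`, clipped to [1/d, 1], and is applied
whenever eps < 1 for effects with more than one df (the original
gatekeeping by Mauchly's test is out of scope; the policy is
configurable: never / when_violated / always).  Partial eta squared =
SS_effect / (SS_effect + SS_error).

Repeated-measures correlation: both variables centered within subject,
common slope fitted, r_rm = sign(slope) sqrt(SS_m / (SS_m + SS_e)),
df = N_obs - n_subjects - 1, p from the corresponding F; optional
within-subject z-scoring for condition averages.  The
Meng-Rosenthal-Rubin z compares two dependent correlations sharing a
variable via Fisher transforms and the published f/h correction factors.

## Pipelines and problem sizes

`run_exp1/2/3` stream participants from the generator (memory stays at
one participant's data), log rejection counts, and return tidy tables
plus a group-test table; `write_results` emits CSVs and echoes the
effective configuration as JSON.  Stages are selectable so targeted
studies (e.g. a 20-seed power loop for one effect) need not pay for the
full analysis; by default everything runs.  The acceptance suite runs
the calibration studies at 12 participants, 24 channels and 500
Monte-Carlo permutations, and the end-to-end power loops with the stages
relevant to the tested effect (ERP-only exp3 runs use the windowed EEG
generation mode); these sizes are the package's study-scale defaults.

## Known limitations

* Channel covariance and artifact physics are not modeled, so cluster
  extents on synthetic data are optimistic relative to real EEG.
* The broadband (2-40 Hz) exponent carries a small positive bias
  (<= +0.09 at chi = 3) from 1-Hz-resolution Welch smoothing of the
  steep low-frequency end; the narrowband 30-45 Hz default does not.
* The Wilcoxon exact path and the GG policy replace the original
  diagnostics-gated choices (Shapiro-Wilk, Mauchly) with declared rules.
* Confidence intervals for effect sizes are not computed.
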