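# Methods

## The analysis problem

A reach-and-grasp study records multichannel EEG while a subject, cued by
audio, reaches out and performs one of five grasps (palmar, pinch, push,
twist, plug) or stays still (no-movement). Movement execution produces a
movement-related cortical potential (MRCP): a slow negative deflection in
the low-frequency (0.3–3 Hz) EEG beginning roughly half a second before
movement onset, peaking at onset over the sensorimotor midline, and
followed by a condition-dependent positive rebound. The package implements
the full offline chain that turns such recordings into single-trial
decoding results — and, because such recordings are rarely shareable, a
synthetic-subject generator with complete ground truth so every stage is
testable at desk scale.

## Paradigm model

A subject is eight sessions of 60 trials (10 per condition, randomized
within session), 480 trials in total (80 per condition). Each 10-s trial
starts with a readiness beep at 0 s, announces the target condition at 3 s
and cues "Go" at 5 s. EEG is 40 channels of a fronto-parietal 10–20/10-10
montage at 1,000 Hz, in μV. A pressure button marks the moment the hand
leaves the start position (one rising-edge pulse per grasp trial); a force
transducer trace rises when the device is grasped and falls at release.
"AF5" is the montage's spelling of the 10-10 AF7 site; the montage treats
the two labels as aliases.

## Synthetic EEG generator

The generator is the package's substitute for subject recordings and is
first-class, tested code. Its components:

* **MRCP templates.** Each condition's waveform on [−1.5, 3.0] s around
  movement onset is a piecewise ramp plus Gaussian rebound bumps — the
  simplest parametric form with the observed morphology. A shared
  component ramps from −0.5 s to −3 μV at onset and recovers to baseline
  by 0.15 s (the no-movement condition is exactly this, hence flat after
  onset). Each grasp adds a condition-specific extra ramp (2.8–4.4 μV,
  extremum at onset), an exponential post-onset recovery, and a rebound
  bump: large (≈5 μV) near 1.2 s for push and plug, weak (≈1–1.5 μV)
  within 0.2–0.5 s for the rest. Waveforms project through a Gaussian
  spatial map centred between Cz, FCz and C1 (contralateral side
  favoured). An `effect_scale` factor multiplies the whole evoked
  waveform; 0 is the null generator. The study never reports MRCP
  amplitudes in μV, so the template amplitudes are free parameters chosen
  to give realistic single-trial SNR, not claims about the data.
* **Background noise.** 1/f-shaped noise (spectral exponent 1, broadband
  RMS 12 μV per channel) realized by FFT shaping of white noise —
  equivalent to a dense sum of random-phase sinusoids with 1/f amplitude
  scaling. Below 0.1 Hz the spectrum rolls off quadratically, mimicking a
  second-order acquisition high-pass: an amplifier records no DC wander,
  and without this the trial-to-trial baseline offsets are unrealistically
  large. Channels are not independent: the per-channel sources are mixed
  through a Gaussian scalp-distance kernel (radius 0.9 head-radii),
  emulating volume conduction. This matters twice — it is why common
  average referencing removes shared background in real EEG, and it is why
  an "any channel beyond 3 SD" outlier rule rejects ~10% of clean trials
  rather than half of them (33 spatially independent channels would give
  66 effectively independent 3-SD tests per trial). The smoothing radius
  was set so the end-to-end rejection fraction of the default generator
  matches the ~12% a careful lab reports.
* **Artifacts.** Stereotyped biphasic blinks (90 μV, Poisson 8/min)
  through a fixed frontal map (FP ≫ AF > F rows); 50-Hz line interference
  (1.5 μV, per-channel gain and phase); rare focal bursts (260–400 μV,
  200 ms, probability 0.05/trial) placed inside the analysis epoch of a
  known trial and channel so the ±200 μV rule has exact ground truth.
* **Behavior.** RT is a truncated normal, mean 0.5 s, SD 0.15 s — a
  plausible auditory reaction time; with probability 0.05 the trial comes
  from a slow component (mean 2.3 s) so the 2-s screening rule has work to
  do. Grasp start is 0.98–1.18 s after onset by condition; durations share
  one distribution across conditions (mean 1.5 s, between-subject SD
  0.12 s, within 0.15 s), i.e. the duration ANOVA's null is true by
  construction. Force traces are smoothed trapezoids — only threshold
  crossings are consumed downstream.

What the generator does **not** emulate: muscle/EMG artifacts, cue-evoked
auditory potentials, non-stationary impedance drift, inter-subject
morphology differences beyond the seed, or any genuine neurovascular
variability. Passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated, not that real recordings will reach
any particular accuracy.

## Preprocessing and artifact rejection

The stage order is fixed and logged: RT screening → 33-channel selection
(FP1, FP2, AF3, AF4, AF5, F5, F6 excluded as blink-dominated) → 40-Hz
zero-phase low-pass → per-trial artifact statistics → ICA ocular cleanup →
common average reference → 0.3–3 Hz zero-phase 4th-order Butterworth
band-pass → decimation to 100 Hz → epoching [−1.5, 2.5) s around the
virtual movement onset, dropping marked trials.

Numerical choices: zero-phase filters are the forward–backward application
of the designed Butterworth (odd-symmetric padding; effective magnitude
order doubled); "4th-order band-pass" means four poles in total.
Decimation adds no separate anti-alias stage because the 40-Hz and 3-Hz
filters precede it. Epoch windows are half-open in samples,
`[onset + round(lo·fs), onset + round(hi·fs))`, which makes a 4-s window
at 100 Hz exactly 400 samples with t = 0 included and removes
off-by-one ambiguity everywhere downstream. The amplifier's own 0.05–100 Hz
band-pass and 50-Hz notch are implemented but off by default — they
describe hardware, not analysis.

Trial screening: RT strictly greater than 2 s (an RT of exactly 2 s is
kept); any sample of any retained channel strictly beyond ±200 μV; joint
probability (mean negative log of the channel's pooled 50-bin empirical
amplitude density over the trial) and sample kurtosis, each z-scored across
trials within channel, rejecting on any |z| > 3. Aggregation is "any
channel exceeds" — conservative, aimed at focal channel noise. Fewer than
10 trials make the histogram unstable; the screen then warns and keeps
everything.

Ocular cleanup fits FastICA on a 1-Hz high-passed (and decimated — spatial
filters need samples, not rate) copy and applies the unmixing to the
analysis data. Components are flagged automatically when their time course
correlates with the EOG reference (|r| ≥ 0.7) or their absolute scalp
weights concentrate ≥ 0.6 on frontal channels, then zeroed and the rest
projected back; with nothing flagged the data passes through bit-exact.
The study removed ~20 of 33 components per subject by visual inspection;
the automated dual criterion typically flags far fewer — a known fidelity
gap accepted in exchange for reproducibility. On this synthetic background
(Gaussian by construction) FastICA's rotation is only weakly identified
and routinely stops at the iteration cap; the pipeline treats that as a
warning, while library users get an error with iteration diagnostics by
default.

## Behavior

RT is (first button release after Go − Go)/fs. The virtual movement onset
is Go + the subject's mean RT pooled over all retained grasp trials — the
screening precedes the mean, so a single slow trial moves no onset. The
same offset applies to no-movement trials, which share the Go event.
Grasp start/release are the first upward and last downward crossings of
10% of the trial's force maximum (scale-free, since only crossings
matter). Per-condition mean durations feed a one-way repeated-measures
ANOVA, F = MS_condition/MS_(condition × subject) with df (k−1, (k−1)(n−1)),
with Mauchly's W (orthonormal-contrast covariance, one-term chi-square
approximation) and a Greenhouse–Geisser corrected p that becomes the
headline p only when sphericity is rejected at 0.05.

## MRCP statistics

Grand averages pool kept trials across subjects (a subject-mean mode
exists behind a flag) with a t-based 95% CI — correct small-sample
coverage where a normal CI would undercover. Condition contrasts are
two-sided Wilcoxon rank-sum tests per time sample: exact enumeration for
n_A + n_B ≤ 20 without ties, normal approximation with tie correction
otherwise, all-tied samples get p = 1. No multiple-comparison correction
is applied by default, matching how sample-wise MRCP significance is
conventionally displayed; Bonferroni/FDR switches exist. Topographic
frames average each channel over a time window and pair amplitudes with
schematic 2-D montage coordinates.

## Decoding

Windows are labeled by their END time and tile the half-open tROI
(−1.0, 2.5] s in 50-ms steps — exactly 70 models, each causal. A window
labeled t uses the half-open sample range [t − 0.5, t): the 10 amplitudes
at t − 0.50 … t − 0.05 s per channel, channels concatenated in montage
order (33 × 10 = 330 features). The half-open convention is applied
uniformly; a closed-interval convention would give 71 models and would
need a sample at 2.5 s that a 400-sample epoch does not contain.

The classifier is shrinkage-regularized LDA: pooled class-mean-centered
covariance Σ̂ (1/(n−1)), target νI with ν = trace(Σ̂)/d, analytic
Ledoit–Wolf/Schäfer–Strimmer intensity λ* clamped to [0, 1],
Σ̃ = (1−λ*)Σ̂ + λ*νI, w = Σ̃⁻¹(μ₂−μ₁), bias at the midpoint. Multiclass
uses one-vs-one majority voting over the 10 pairwise models; ties resolve
by the largest sum of signed decision values over the tied classes'
models, then the lowest class label — fully deterministic. Accuracy
curves use stratified 5-fold cross-validation repeated 10 times,
repetition r reshuffling with seed + r; the curve reports the mean and SD
over the 50 fold accuracies. Peaks resolve ties to the earliest window.
The chance level is the one-sided adjusted-Wald upper bound around 1/k:
with p₀ = 1/k, x = np₀ and z the 1−α normal quantile,
p̃ = (x + z²/2)/(n + z²) and bound = p̃ + z√(p̃(1−p̃)/(n + z²)). A chance
threshold is a one-sided statement, hence the one-sided quantile; the
formula is validated against the exact binomial quantile. Features are
raw window amplitudes (no window-mean subtraction). The grand-average
curve is the pointwise mean of subject curves, so its peak can only be
≤ the mean of subject-specific peaks.

## Calibration and problem sizes

Desk-scale checks use deliberately small designs: null calibration runs 20
seeded subjects of 2 sessions × 10 trials/condition with `effect_scale 0`
and one CV repetition (the ocular-ICA stage is skipped there — a
condition-blind cleanup cannot create class information, and the null
statement concerns the decoding chain); signal recovery runs 3 seeded
subjects of 4 sessions with the full cleaning chain and two repetitions.
The acceptance script uses 10 null seeds and 2 recovery seeds. Under these
conditions the default generator lands where the emulated study reports:
~15–18% of trials rejected, grasp start ≈ 1.15 s after onset, binary
grasp-vs-no-movement peaks of 70–100% against a ≈ 60% chance bound, and a
five-class grand-average peak near 40% (bound ≈ 25%) occurring 1–2 s
after movement onset.

## Known limitations

* The generator's background is Gaussian; ICA component identification on
  it is weaker than on real EEG, and the automated flagging criterion is
  not a substitute for expert review of real recordings.
* Per-condition grasp-start means differ slightly by design, so force
  timing carries a small amount of condition information; it never enters
  the EEG or the decoder.
* The rank-sum normal approximation differs from exact enumeration by up
  to ≈ 0.011 at n = 8+8 (mid-range p); the package uses exact enumeration
  in exactly that regime.
* Mauchly's p uses the one-term chi-square approximation; reference
  implementations adding the second Box term differ in p by ≲ 0.01.
* The pipeline holds one subject's continuous data in memory (a full
  8-session subject at 1,000 Hz is ≈ 1.5 GB); intermediates are released
  eagerly, but simultaneous multi-subject processing is sequential by
  design.
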