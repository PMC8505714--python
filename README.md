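# mrcpdecode

Single-trial decoding of reach-and-grasp movements from movement-related
cortical potentials (MRCPs) in multichannel EEG — the full offline
analysis chain plus a paradigm-faithful synthetic-subject generator with
ground truth, so every stage is verifiable without access to subject
recordings.

**Who it is for.** BCI / neurophysiology researchers who want a tested,
reproducible reference implementation of the classic low-frequency MRCP
decoding pipeline: five grasp types (palmar, pinch, push, twist, plug)
plus a no-movement condition, recorded in 10-s cue-guided trials over a
40-channel fronto-parietal 10–20 montage at 1,000 Hz.

**What it computes.** For epochs x time-locked to the *virtual movement
onset* (Go cue + the subject's mean reaction time over retained trials):

* preprocessing — 33-channel selection, zero-phase Butterworth filtering
  (40-Hz low-pass; 0.3–3 Hz band-pass), common average reference,
  decimation to 100 Hz, epoching [−1.5, 2.5) s;
* artifact handling — RT > 2 s screening, ±200 μV thresholding,
  joint-probability/kurtosis outlier rejection (|z| > 3 on any channel),
  ICA-based ocular cleanup with automated component flagging;
* MRCP statistics — grand averages with t-based 95% CIs, sample-wise
  Wilcoxon rank-sum contrasts, topographic frames;
* decoding — a 500-ms window sliding in 50-ms steps over the tROI
  (−1.0, 2.5] s (70 models, end-labeled), 10 amplitudes per channel per
  window (d = 330), shrinkage-regularized LDA

  w = Σ̃⁻¹(μ₂ − μ₁),  Σ̃ = (1 − λ*)Σ̂ + λ* ν I,  ν = tr(Σ̂)/d,

  with the analytic Ledoit–Wolf shrinkage intensity λ*, one-vs-one
  multiclass voting, stratified 5-fold × 10 cross-validation, peak
  accuracy and confusion matrices, and the one-sided adjusted-Wald chance
  bound p̃ + z√(p̃(1−p̃)/(n+z²)), p̃ = (n/k + z²/2)/(n + z²).

## Worked example

Simulate one subject (2 sessions × 60 trials), run the preprocessing and
rejection chain, and decode push-vs-no-movement and the five-class
problem:

```python
import numpy as np
from mrcpdecode import chance_upper_bound, cross_validated_curve, peak_performance
from mrcpdecode.pipeline import PipelineConfig, process_subject

cfg = PipelineConfig(n_subjects=1, experiment=dict(n_sessions=2))
epochs, summary, rejection, ica, sim = process_subject(cfg, subject_seed=42,
                                                       subject_id="S1")
print(f"kept {epochs.kept_mask.sum()}/{epochs.n_trials} trials "
      f"({100 * rejection.fraction_rejected:.1f}% rejected), "
      f"mean RT {summary.mean_rt_s:.3f} s")

push = cross_validated_curve(epochs, classes=[3, 6], folds=5,
                             repetitions=2, seed=1)
acc, t = peak_performance(push)
print(f"push vs no-movement: peak {acc:.3f} at {t:.2f} s "
      f"(chance bound {chance_upper_bound(push.n_trials, 2).bound:.3f})")

multi = cross_validated_curve(epochs, classes=[1, 2, 3, 4, 5], folds=5,
                              repetitions=2, seed=1)
acc, t = peak_performance(multi)
print(f"five-class: peak {acc:.3f} at {t:.2f} s "
      f"(chance bound {chance_upper_bound(multi.n_trials, 5).bound:.3f})")
```

prints

```
kept 102/120 trials (15.0% rejected), mean RT 0.591 s
push vs no-movement: peak 0.961 at 1.35 s (chance bound 0.632)
five-class: peak 0.453 at 1.60 s (chance bound 0.282)
```

Read: 15% of trials fell to the artifact screens (the generator injects
bursts, blinks and slow reactions on purpose); the binary decoder clears
its chance bound decisively with the peak during the grasp itself
(~1.4 s after movement onset); the five-class decoder peaks at 45%
against a 28% bound — decoding is hard but clearly above chance, and the
peak lies after onset, where the condition-specific rebound lives.

The same chain is scriptable end to end:

```sh
mrcpdecode run --seed 1 --out runs/demo          # simulate → … → tables
mrcpdecode simulate --seed 1 --out data/s01 --brainvision
mrcpdecode report --run-dir runs/demo
```

`run` writes per-subject ground truth, behavior, rejection and curve
CSVs, grand-average/significance/topography tables, the three
peak-performance tables, a pooled confusion matrix and a manifest with
SHA-256 digests of every artifact (identical config + seed ⇒ identical
digests).

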