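# gammareplay

Detection of spontaneous motor-pattern **reactivation** in human NREM
sleep from intracranial EEG (iEEG), using high-gamma envelope decoding.

Models of memory consolidation hold that the sleeping brain replays
activity patterns from recent waking experience. This package
implements, end to end, a subject-level test of that idea for motor
learning: extract the spatial pattern of broadband high-gamma
(60–140 Hz) amplitude that distinguishes finger movements from rest in
wakefulness, train a linear classifier on it, apply the classifier to
unlabeled sleep data before and after learning, and ask whether
"motor"-labeled sleep windows become more frequent after the task.

It is aimed at electrophysiologists and methods researchers who want a
tested, reusable reference implementation of this decoding-based
reactivation analysis — and, because clinical iEEG is rarely shareable,
it ships a synthetic-data generator that emulates the full experiment
(multichannel 1/f signals, line noise, press-locked gamma bursts,
sleep architecture, injectable reactivation events with known ground
truth) so every stage is verifiable.

## The method in brief

For channels *j* = 1…N (bipolar depth / common-average grid montage,
IED-rate > 6.5/min excluded, anatomically labeled by a voxel-cloud
probability algorithm):

- envelope: per 10-Hz band *b* in 60–140 Hz,
  `A_b(t) = |Hilbert(BP_b(x))|`, smoothed 0.03 s, z-scored with the
  rest-session mean/SD, averaged over bands;
- trials: 0.3-s windows (press-centered = motor; rest tiling = rest;
  50%-overlapping within 30-s NREM epochs = unlabeled), feature =
  per-channel window mean, rejection if any sample > 10 a.u.;
- decoder: linear SVM `d(x) = β·((x−μ)/σ) + b`, decoding accuracy =
  mean of 5 stratified CV folds;
- reactivation: per-epoch motor-vote proportion, sleepPre vs sleepPost
  compared by a left-tailed Wilcoxon rank-sum (α = 0.025), effect size
  `r = z/√n`, reactivation index = Δmedian × number of post epochs.

See `docs/methods.md` for the full specification of every stage.

## Worked example

```python
from gammareplay import SynthConfig
from gammareplay.pipeline import RunConfig, run_subject

cfg = SynthConfig(
    n_channels=8, fs=250.0, motor_channel_fraction=0.25,
    rest_duration=60.0, sleep_epochs_pre=12, sleep_epochs_post=12,
    true_motor_window_rate_pre=0.05,   # baseline motor-like events
    true_motor_window_rate_post=0.20,  # reactivating subject
    seed=3,
)
report = run_subject(RunConfig(synth=cfg, seed=3, modes=("all",)))
m = report["modes"]["all"]
print(f"DA = {m['decoding_accuracy']:.3f}")
print(f"median votes pre/post = {m['median_pre']:.3f} / {m['median_post']:.3f}")
print(f"z = {m['z']:.2f}, p = {m['p']:.2g}, r = {m['r']:.2f}")
print(f"reactivation index = {m['reactivation_index']:.2f}")
```

Output:

```
DA = 0.995
median votes pre/post = 0.047 / 0.249
z = -3.84, p = 6.2e-05, r = -0.84
reactivation index = 2.22
```

The decoder separates motor from rest trials almost perfectly on this
synthetic subject (DA 0.995). During sleep, 4.7% of 0.3-s windows per
30-s NREM epoch are voted "motor" before learning versus 24.9% after —
the injected ground-truth difference (per-slot rates 0.05 → 0.20) —
and the left-tailed rank-sum flags the increase (negative z, p well
below the 0.025 criterion). The reactivation index is the median
difference scaled by the number of post-learning sleep epochs.

A thin CLI wraps the same calls: `gammareplay synth --out dir/ --seed 1`
writes a synthetic session bundle; `gammareplay run --config cfg.yaml
--out report.json` runs the pipeline and writes the JSON report.

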