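# Methods

`gammareplay` implements a complete analysis chain for detecting the
spontaneous re-occurrence, during NREM sleep, of the spatial high-gamma
activity pattern evoked by a finger-tapping task in intracranial EEG
(iEEG), together with a synthetic-data generator that makes every stage
testable against known ground truth.

## The analysis model

The underlying assumption is that local neural processing is indexed by
broadband high-gamma (60–140 Hz) amplitude. Finger movements evoke a
spatial pattern of gamma amplitude across implanted electrodes; if that
pattern re-occurs ("reactivates") during subsequent sleep, a classifier
trained to separate movement from rest in wakefulness will label more
sleep windows as "motor" after learning than before.

The chain, in execution order:

1. **Preprocessing.** Each session (rest, task, pre-learning sleep,
   post-learning sleep, retest) is de-meaned and the line-noise bands
   (58–62 Hz, and 118–122 Hz when the sampling rate supports it)
   removed with a zero-phase 4th-order Butterworth band-stop. Depth
   leads are re-referenced to a bipolar montage (contact *i* minus
   contact *i*+1 within a lead; n contacts → n−1 channels at the pair
   midpoints); grids to the common average. Channels with interictal
   epileptiform discharge (IED) rates above 6.5 events/min (strictly
   greater; pooled over sessions, duration-weighted) are excluded, as
   are channels on a caller-supplied bad list.
2. **Electrode labeling (ELA).** Each (re-referenced) electrode is
   modeled as a voxel cloud on the 1-mm label lattice: depth contacts
   as a capsule ("cigar": cylinder of length 4 mm with hemispherical
   caps, diameter 3 mm) along the lead axis; grid contacts as a
   3-mm-diameter sphere intersected with the cortical-surface voxel
   mask. The probability of a region is the fraction of cloud voxels
   inside that region's voxels. If nothing intersects, the geometry
   grows by (Δlength 1 mm, Δdiameter 0.5 mm) — grids by Δdiameter
   0.5 mm — and retries, up to 50 times. The winner is the
   highest-probability region; ties break by smaller distance between
   the electrode and the centroid of the intersecting voxels, then
   lexicographically. Labels in the frontal, cingulate and parietal
   cortices, striatum, hippocampus and cerebellum (DKT names shipped in
   `motor_network_labels.yaml`) form the "motor-learning network"
   channel subset.
3. **Gamma envelope.** Successive 10-Hz bands spanning 60–140 Hz
   (60–100 Hz at 250 Hz sampling) are band-passed with a zero-phase
   forward–reverse Hamming windowed-sinc FIR of `round(3·fs/lo)` taps,
   Hilbert-transformed, smoothed with a 0.03-s moving average, z-scored
   per channel and band with the mean/SD of the rest session, and the
   bands averaged with equal weight.
4. **Trials.** 0.3-s windows: centered on each correct press (motor
   class, learning + retest; a flag excludes retest), non-overlapping
   tiling of the rest session (rest class), and 50%-overlapping tiling
   of each 30-s N2/N3 sleep epoch (unlabeled; windows never cross epoch
   boundaries — 199 per epoch at 2000 Hz, 196 at 250 Hz where the
   0.15-s step rounds to 38 samples). A trial is rejected iff any
   envelope sample on any retained channel strictly exceeds 10 a.u.;
   the per-channel feature is the window-mean envelope. Classes are
   balanced by uniformly down-sampling the larger class.
5. **Decoding.** A soft-margin linear SVM (C = 1, unit kernel scale) on
   standardized features. Decoding accuracy (DA) is the mean of five
   fold accuracies of a stratified seeded 5-fold cross-validation with
   standardization refit inside each training split (refitting avoids
   leakage; whether the original analysis refit per split is not
   documented, so this is the conservative choice). The full-data model
   votes motor/rest on every valid sleep trial.
6. **Statistics.** Motor-vote proportions per 30-s NREM epoch are
   compared between the sleep periods with a left-tailed Wilcoxon
   rank-sum test (alternative: larger proportions after learning; z
   reported negative under the alternative), α = 0.025, effect size
   r = z/√n. For total n ≤ 12 the p value is the exact permutation tail
   mass; otherwise a normal approximation with midrank tie correction
   and a sign-symmetric continuity correction. Group level: two-tailed
   paired t on per-subject medians; the reactivation index
   (Δmedian × post-epoch count) is Pearson-correlated with the
   behavioral performance index and, as a control, with the elapsed
   time between the sleep periods. Tapping performance: correct
   repetitions slower than pooled mean + 3 SD are excluded, accepted
   durations normalized to their overall mean; block contrasts 2:3,
   9:10 (improvement % = 100·(m23−m910)/m23) and 12:13 (performance
   index = m910−m1213); repeated-measures ANOVA across subjects with
   Greenhouse–Geisser correction (via pingouin) plus post-hoc paired t.
   Spectral QC: DPSS multitaper power spectra (0.5–25 Hz, regridded to
   0.5-Hz steps; mne) per 30-s segment, averaged over segments and
   channels, log-transformed, for all channels and the top-5/bottom-5
   |β| subsets.

## The synthetic generator

`SynthConfig`/`generate_session` emulate one experimental subject:
1/f-shaped background noise (power ∝ 1/f^1.5, unit SD) per channel,
60 Hz (plus 120 Hz at 2000 Hz sampling) sinusoidal line noise, and a
motor-evoked response modeled as broadband 60–140 Hz noise in a 0.3-s
raised-cosine window. A shared burst source couples into each
"motor" contact with a per-contact gain drawn uniformly from 0.5–1.5 ×
`gamma_burst_snr` — contact-to-contact gain differences are what
survives the bipolar montage, as for a real focal source. Each event
additionally carries lognormal amplitude jitter (σ = 0.3, unit mean)
and ±0.1-s latency jitter. Sleep sessions add 1/f-shaped activity
low-passed at 4 Hz (amplitude 4 × background SD) and 13-Hz spindle
bursts; hypnograms are nap-like (mostly N2/N3, brief wake/REM
intrusions). Injected "reactivation" events place the same motor burst
into NREM epochs: each non-overlapping 0.3-s slot (100 per epoch) is
injected independently with probability `true_motor_window_rate_pre` /
`_post`. IED-like events are 70-ms biphasic sharp transients at 8 ×
background SD on configured channels; artifacts are 0.2-s broadband
excursions at 15 × background SD on all channels, sized so the
normalized envelope exceeds the 10 a.u. rejection threshold. Event
counts per session are deterministic (rate × duration, positions
random): Poisson counts would make each session's realized event
density differ from the rest session used for normalization and
masquerade as session non-stationarity. All randomness flows through
one seeded generator; identical configs are bit-identical.

Defaults mirror the recording structure of the motivating experiment:
2000 Hz sampling (250 Hz variant), ~4-min rest, ten 30-s learning
blocks plus three retest blocks, ~52/38-min sleep periods. Press rate
(2/s) is a free parameter — the experiment did not report inter-press
intervals. The tapping-log learning curve decays exponentially to
~82% of its early-block level so the downstream improvement statistic
lands near 18%.

### What the generator does not emulate

Real epileptic iEEG non-stationarity (state-dependent baseline drifts,
electrode impedance changes), genuine IED morphology and propagation,
REM-specific phenomena, volume-conducted correlation structure between
leads, and any behavioral coupling between tapping speed and neural
burst amplitude. Passing tests therefore show that the chain is
correct and calibrated under stationary, event-driven conditions — not
that the statistical test is robust to the session-level
non-stationarities of clinical recordings.

## Calibration choices

`gamma_burst_snr` defaults to 4.0. At low SNR many sleep trials fall
near the decision boundary, and the per-session sampling fluctuation
of band power (a shared offset across all epochs of a period) inflates
the between-period variance of vote proportions: the rank-sum null
becomes strongly overdispersed (empirically z SD ≈ 1.2–3), exactly the
within-subject pseudoreplication risk of comparing two sessions. At
SNR 4 the votes are event-driven, epochs are effectively independent,
and the per-subject test holds its nominal 2.5% level. The null
experiments use a nonzero baseline rate (0.10 in both periods):
motor-like patterns also occur in pre-learning sleep, and a rate of
exactly zero makes the vote series degenerate (all proportions 0).

Problem sizes for the simulation studies: 8 depth contacts (two leads)
at 250 Hz, 60-s rest, ten learning blocks, 12 + 12 sleep epochs —
small enough to run hundreds of independent subjects, large enough
that the rank-sum uses its normal-approximation regime (~22 NREM
epochs per subject).

## Numerical and design notes

- "Cigar" cloud realized as a capsule (cylinder + hemispherical caps),
  voxel membership by voxel-center inclusion on the 1-mm lattice; this
  makes exact brute-force enumeration feasible as a test oracle.
- FIR band-pass order `round(3·fs/lo)` taps ("3 cycles of the low
  cut-off"); filtering uses reflect padding of one filter length.
  Band partition uses half-open [lo, lo+10) bands.
- The second notch band is skipped when it reaches within 10% of
  Nyquist (118–122 Hz at 250 Hz sampling).
- The IED detector is a deliberate stand-in (10–60 Hz analytic
  amplitude, threshold median + 8·MAD, supra-threshold excursions
  closer than 120 ms merged), not the published adaptive-envelope
  algorithm; its false-positive rate on clean channels is < 1/min.
  The 6.5/min exclusion rule itself is exact. IED rates are pooled
  over sessions per channel (per-session thresholds would exclude
  different channels per session).
- Rank-sum: continuity correction shrinks |W − μ| by 0.5 toward the
  null, which keeps z antisymmetric under swapping the periods.
  Constant pooled data yields z = 0, p = 1 with a degenerate flag.
- Bad-channel exclusion is a config input (the visual review step is
  not implementable); the synthetic ground truth can supply it.
- NREM for the vote analysis is N2 ∪ N3. Descriptive hypnogram
  summaries count N2/N3 by default with an `include_n1` option, since
  whether N1 belongs in "NREM minutes" is a reporting convention.
- The artifact threshold is evaluated on retained channels only
  (post channel-selection).
- A single-channel (or all-equal |β|) area summary rescales to 1 by
  convention.

## Known limitations

- The LDA confirmation analysis, visual sleep staging, MRI/CT
  coregistration, surface reconstruction and the grid-projection
  energy minimization are out of scope; hypnograms, coordinates and
  surface masks are inputs.
- EDF export is not provided; sessions are written as `.npy` arrays
  with JSON metadata and CSV sidecars.
- The exact-permutation branch of the rank-sum is O(C(n, k)) and only
  used for n ≤ 12.
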