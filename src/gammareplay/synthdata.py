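"""Synthetic iEEG session generator with known ground truth.

Emulates the structure of an intracranial motor-reactivation experiment:
a short eyes-closed rest session, a blocked finger-tapping task, a nap
(post-learning sleep), a control sleep period before learning, and a
retest. Signals are 1/f-shaped background noise plus sinusoidal line
noise; "motor-network" channels additionally carry broadband 60-140 Hz
amplitude bursts in a 0.3-s raised-cosine window centered on each button
press, and sleep sessions carry injected motor-like gamma windows at
configurable per-period rates — the ground truth against which the
reactivation statistics are validated. Optional interictal-discharge-like
sharp transients and large broadband artifacts exercise the exclusion
rules downstream.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SynthConfig.seed``; identical configs produce bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .containers import NREM_STAGES, Recording, make_channel_info

logger = logging.getLogger("gammareplay")

VALID_FS = (250.0, 2000.0)

#: Length of one hypnogram epoch in seconds.
EPOCH_SEC = 30.0

#: Length of the press-locked / sleep analysis window in seconds.
WINDOW_SEC = 0.3


@dataclass
class SynthConfig:
    """Parameters of one synthetic subject.

    Session sizes default to the study conditions: ~4 min rest, ten 30-s
    learning blocks plus three retest blocks, and sleep periods of about
    52 min (pre) and 38 min (post). ``true_motor_window_rate_*`` is the
    probability that each non-overlapping 0.3-s slot of an NREM sleep
    epoch carries an injected motor-like gamma window.
    """

    n_channels: int = 60
    fs: float = 2000.0
    motor_channel_fraction: float = 0.2
    gamma_burst_snr: float = 4.0
    press_rate: float = 2.0  # presses per second during task blocks
    rest_duration: float = 240.0
    task_blocks: int = 10
    retest_blocks: int = 3
    sleep_epochs_pre: int = 104
    sleep_epochs_post: int = 77
    true_motor_window_rate_pre: float = 0.05
    true_motor_window_rate_post: float = 0.20
    ied_channel_ids: tuple = ()
    ied_rate: float = 12.0  # events/min on the IED channels
    artifact_rate: float = 2.0  # broadband artifacts/min, all channels
    artifact_amp: float = 15.0  # x background SD; drives envelope >> 10 z
    line_noise_amp: float = 1.0
    burst_gain_jitter_sd: float = 0.3  # lognormal sigma of per-event gain
    burst_latency_jitter_sec: float = 0.1  # uniform onset jitter
    noise_exponent: float = 1.5  # power ~ 1/f**exponent
    slow_amp: float = 4.0  # <4 Hz sleep activity, x background SD
    spindle_amp: float = 1.5
    contacts_per_lead: int = 6
    correct_press_prob: float = 0.92
    # tapping-log learning curve: duration(block) = d_inf + (d0-d_inf)*exp(-(b-1)/tau)
    tap_d0: float = 3.3
    tap_d_inf: float = 2.4
    tap_tau: float = 3.0
    tap_noise_sd: float = 0.25
    tap_outlier_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if float(self.fs) not in VALID_FS:
            raise ValueError(f"fs must be one of {VALID_FS}, got {self.fs}")
        for name in ("rest_duration",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "motor_channel_fraction",
            "true_motor_window_rate_pre",
            "true_motor_window_rate_post",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.task_blocks < 1 or self.retest_blocks < 1:
            raise ValueError("task_blocks and retest_blocks must be >= 1")

    @property
    def n_motor_channels(self) -> int:
        return int(round(self.motor_channel_fraction * self.n_channels))

    @property
    def gamma_band(self) -> tuple:
        hi = 140.0 if self.fs == 2000.0 else 100.0
        return (60.0, hi)


@dataclass
class GroundTruth:
    """What was injected: sleep motor windows, burst gains, learning curve."""

    injected_windows: dict  # period -> list of (epoch_idx, onset_sample)
    burst_gain: np.ndarray  # per-channel gain of motor bursts
    tapping_params: dict
    true_labels: list = field(default_factory=list)  # per-channel region
    artifact_samples: dict = field(default_factory=dict)  # session -> onsets

    def n_injected(self, period: str) -> int:
        return len(self.injected_windows.get(period, []))


@dataclass
class SynthBundle:
    """Everything :func:`generate_session` produces for one subject."""

    recordings: dict  # session tag -> Recording
    channels: pd.DataFrame
    events: pd.DataFrame  # columns: session, sample, type, block, correct
    hypnograms: dict  # period -> list of stages
    ground_truth: GroundTruth
    label_volume: "LabelVolume"
    tapping_log: pd.DataFrame
    config: SynthConfig


# --------------------------------------------------------------------------
# label-volume phantom
# --------------------------------------------------------------------------

#: Phantom regions: name -> (x, y, z) box bounds in mm, on a 1 mm lattice.
#: Boxes are separated by unlabeled gaps so cloud expansion is exercised.
PHANTOM_REGIONS = {
    "precentral": ((2, 22), (2, 26), (2, 22)),
    "superiorfrontal": ((26, 46), (2, 26), (2, 22)),
    "superiorparietal": ((2, 22), (30, 54), (2, 22)),
    "hippocampus": ((26, 46), (30, 54), (2, 22)),
    "superiortemporal": ((2, 22), (2, 26), (26, 44)),
    "middletemporal": ((26, 46), (2, 26), (26, 44)),
}


@dataclass
class LabelVolume:
    """1-mm isotropic integer label grid with a surface-voxel mask.

    ``origin`` is the world coordinate (mm) of the center of voxel
    (0, 0, 0); the world-to-voxel map is a pure translation.
    """

    labels: np.ndarray  # int array, 0 = unlabeled
    names: dict  # label id -> region name
    origin: np.ndarray
    surface: np.ndarray | None = None  # bool mask of surface voxels

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def world_to_voxel(self, coords: np.ndarray) -> np.ndarray:
        return np.rint(np.asarray(coords, dtype=float) - self.origin).astype(int)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) + self.origin

    def label_at(self, coord) -> str:
        """Region name at a world coordinate; 'gap' if unlabeled."""
        i, j, k = self.world_to_voxel(np.asarray(coord))
        if not (
            0 <= i < self.shape[0] and 0 <= j < self.shape[1] and 0 <= k < self.shape[2]
        ):
            raise ValueError(f"coordinate {coord} outside the label volume")
        lab = int(self.labels[i, j, k])
        return self.names.get(lab, "gap") if lab != 0 else "gap"


def _build_phantom_volume() -> LabelVolume:
    shape = (50, 58, 48)
    labels = np.zeros(shape, dtype=np.int16)
    names = {}
    for lab_id, (name, ((x0, x1), (y0, y1), (z0, z1))) in enumerate(
        PHANTOM_REGIONS.items(), start=1
    ):
        labels[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = lab_id
        names[lab_id] = name
    # surface voxels: labeled voxels with at least one unlabeled 6-neighbor
    lab = labels > 0
    interior = lab.copy()
    for axis in range(3):
        interior &= np.roll(lab, 1, axis) & np.roll(lab, -1, axis)
    surface = lab & ~interior
    return LabelVolume(labels, names, origin=np.zeros(3), surface=surface)


def generate_label_volume(config: SynthConfig) -> tuple:
    """Build the label-volume phantom and electrode coordinates.

    Leads of ``contacts_per_lead`` depth contacts are placed along the
    x axis, each lead well inside one phantom region (motor channels in
    the precentral box, the remainder cycling through the other
    regions). Returns ``(LabelVolume, ChannelInfo DataFrame)`` with the
    ground-truth region recorded per contact.
    """
    volume = _build_phantom_volume()
    rng = np.random.default_rng(config.seed + 101)
    n = config.n_channels
    cpl = config.contacts_per_lead
    n_motor = config.n_motor_channels

    # non-motor leads cycle through these, alternating in- and
    # out-of-network regions so small montages exercise the network filter
    other_regions = [
        "superiorfrontal",
        "superiortemporal",
        "superiorparietal",
        "middletemporal",
        "hippocampus",
    ]

    names, kinds, leads, coords, contacts, true_labels = [], [], [], [], [], []
    is_motor = []
    lead_idx = 0
    other_i = 0
    ch = 0
    while ch < n:
        n_contacts = min(cpl, n - ch)
        if ch < n_motor:
            region = "precentral"
        else:
            region = other_regions[other_i % len(other_regions)]
            other_i += 1
        (x0, x1), (y0, y1), (z0, z1) = PHANTOM_REGIONS[region]
        # keep contacts >= 3 mm inside the box; spacing 2.5 mm along x
        span = (n_contacts - 1) * 2.5
        x_start = x0 + 3 + rng.uniform(0, max(0.0, (x1 - x0 - 6) - span))
        y = rng.uniform(y0 + 4, y1 - 4)
        z = rng.uniform(z0 + 4, z1 - 4)
        for c in range(n_contacts):
            names.append(f"L{lead_idx}-{c}")
            kinds.append("depth")
            leads.append(f"L{lead_idx}")
            contacts.append(c)
            coord = np.array([x_start + 2.5 * c, y, z])
            coords.append(coord)
            true_labels.append(volume.label_at(coord))
            is_motor.append(region == "precentral")
        ch += n_contacts
        lead_idx += 1

    channels = make_channel_info(names, kinds, leads, np.array(coords), contacts)
    channels["true_label"] = true_labels
    channels["is_motor"] = is_motor
    return volume, channels


# --------------------------------------------------------------------------
# signal primitives
# --------------------------------------------------------------------------


def powerlaw_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float = 1.5,
) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f**exponent, unit SD."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


_BURST_TAPS: dict = {}


def _burst_taps(fs: float, band: tuple) -> np.ndarray:
    key = (fs, band)
    if key not in _BURST_TAPS:
        lo, hi = band
        _BURST_TAPS[key] = signal.firwin(
            65, [lo, min(hi, 0.45 * fs)], pass_zero=False, fs=fs
        )
    return _BURST_TAPS[key]


def _gamma_bursts(
    rng: np.random.Generator, k: int, n: int, fs: float, band: tuple
) -> np.ndarray:
    """k unit-SD band-limited noise bursts, tapered by a raised cosine."""
    if k == 0:
        return np.empty((0, n))
    taps = _burst_taps(fs, band)
    x = signal.filtfilt(taps, [1.0], rng.standard_normal((k, n + 130)), axis=-1)
    x = x[:, 65 : 65 + n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x / sd) * np.hanning(n)


def _ied_transient(fs: float) -> np.ndarray:
    """70-ms biphasic sharp transient (derivative-of-Gaussian), peak 1."""
    n = max(3, int(round(0.070 * fs)))
    t = np.linspace(-2.5, 2.5, n)
    w = -t * np.exp(-(t**2) / 2.0)
    return w / np.abs(w).max()


def _add_events_at(data: np.ndarray, onsets, template_fn, amplitude) -> None:
    """Add `template_fn(length)`-shaped events in place at sample onsets."""
    n = data.shape[-1]
    for onset in onsets:
        tpl = template_fn()
        stop = min(onset + len(tpl), n)
        if onset < 0 or onset >= n:
            continue
        data[..., onset:stop] += amplitude * tpl[: stop - onset]


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------


def _make_hypnogram(rng: np.random.Generator, n_epochs: int) -> list:
    """Nap-like stage sequence: mostly N2/N3 with brief W/REM intrusions."""
    stages = []
    for i in range(n_epochs):
        if i == 0:
            stages.append("W")
        elif rng.random() < 0.05:
            stages.append("REM")
        else:
            stages.append("N3" if rng.random() < 0.3 else "N2")
    if not any(s in NREM_STAGES for s in stages):
        stages[-1] = "N2"  # a sleep period always contains some NREM
    return stages


def _rate_onsets(
    rng: np.random.Generator, n_samples: int, fs: float, rate_per_min: float
) -> np.ndarray:
    """Uniformly placed event onsets at a fixed count = rate x duration.

    The count is deterministic (rounded) rather than Poisson so that
    every session carries the same event density; random counts would
    shift each session's envelope baseline relative to the rest session
    and masquerade as non-stationarity.
    """
    if rate_per_min <= 0:
        return np.array([], dtype=int)
    k = int(round(rate_per_min * n_samples / fs / 60.0))
    return np.sort(rng.integers(0, n_samples, size=k))


def _background(cfg: SynthConfig, rng, n_samples: int) -> np.ndarray:
    data = powerlaw_noise(rng, cfg.n_channels, n_samples, cfg.fs, cfg.noise_exponent)
    t = np.arange(n_samples) / cfg.fs
    line = cfg.line_noise_amp * np.sin(2 * np.pi * 60.0 * t)
    if cfg.fs == 2000.0:
        line = line + 0.5 * cfg.line_noise_amp * np.sin(2 * np.pi * 120.0 * t)
    data += line
    return data


def _sleep_activity(cfg: SynthConfig, rng, n_samples: int) -> np.ndarray:
    """Slow (<4 Hz) activity plus sleep-spindle bursts, one row per channel.

    The slow component is 1/f-shaped inside the low-pass band so the
    sleep-vs-wake power increase is visible across all of 0.5-4 Hz, not
    only at the lowest bins.
    """
    slow = powerlaw_noise(rng, cfg.n_channels, n_samples, cfg.fs, 1.0)
    sos = signal.butter(4, 4.0, btype="low", fs=cfg.fs, output="sos")
    slow = signal.sosfiltfilt(sos, slow, axis=-1)
    sd = slow.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    slow = cfg.slow_amp * slow / sd
    # spindles: ~3/min, 1 s, 13 Hz, shared across channels
    out = slow
    spindle_len = int(round(1.0 * cfg.fs))
    t = np.arange(spindle_len) / cfg.fs
    tpl = np.sin(2 * np.pi * 13.0 * t) * np.hanning(spindle_len)
    for onset in _rate_onsets(rng, n_samples - spindle_len, cfg.fs, 3.0):
        out[:, onset : onset + spindle_len] += cfg.spindle_amp * tpl
    return out


def _resolve_ied_channels(cfg: SynthConfig) -> np.ndarray:
    return np.asarray(cfg.ied_channel_ids, dtype=int)


def generate_session(config: SynthConfig) -> SynthBundle:
    """Generate one complete synthetic subject.

    Returns a :class:`SynthBundle` with one :class:`Recording` per
    session tag (rest, task, sleepPre, sleepPost, retest), the channel
    table with phantom coordinates and ground-truth labels, the press
    event table, per-period hypnograms, the tapping log, and the
    injection ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    volume, channels = generate_label_volume(cfg)
    motor_mask = channels["is_motor"].to_numpy()
    # per-contact coupling gains: a shared burst source couples with a
    # different strength into each motor contact, so spatial contrasts
    # (e.g. a bipolar montage) retain the burst
    burst_gain = np.where(
        motor_mask, cfg.gamma_burst_snr * rng.uniform(0.5, 1.5, cfg.n_channels), 0.0
    )
    ied_ch = _resolve_ied_channels(cfg)
    win = int(round(WINDOW_SEC * cfg.fs))
    epoch_samp = int(round(EPOCH_SEC * cfg.fs))

    recordings: dict = {}
    events_rows = []
    hypnograms: dict = {}
    injected: dict = {"sleepPre": [], "sleepPost": []}
    artifact_samples: dict = {}

    def decorate(data: np.ndarray, session: str) -> None:
        """IEDs and artifacts, common to every session."""
        n = data.shape[1]
        tpl = _ied_transient(cfg.fs)
        for ch in ied_ch:
            onsets = _rate_onsets(rng, n - len(tpl), cfg.fs, cfg.ied_rate)
            _add_events_at(data[ch], onsets, lambda: tpl, 8.0)
        art_len = int(round(0.2 * cfg.fs))
        art_onsets = _rate_onsets(rng, n - art_len, cfg.fs, cfg.artifact_rate)
        for onset in art_onsets:
            data[:, onset : onset + art_len] += cfg.artifact_amp * rng.standard_normal(
                (cfg.n_channels, art_len)
            )
        artifact_samples[session] = art_onsets.tolist()

    jit = int(round(cfg.burst_latency_jitter_sec * cfg.fs))
    gain_sd = cfg.burst_gain_jitter_sd

    def add_bursts(data: np.ndarray, onsets) -> None:
        """Event-to-event variability: lognormal amplitude (unit mean)
        and uniform onset jitter around the nominal window."""
        onsets = [o for o in onsets if o >= 0]
        k = len(onsets)
        bursts = _gamma_bursts(rng, k, win, cfg.fs, cfg.gamma_band)
        gains = rng.lognormal(mean=-0.5 * gain_sd**2, sigma=gain_sd, size=k)
        jitters = rng.integers(-jit, jit + 1, size=k) if jit > 0 else np.zeros(k, int)
        for onset, burst, g, dj in zip(onsets, bursts, gains, jitters):
            start = max(0, onset + int(dj))
            stop = min(start + win, data.shape[1])
            seg = burst[: stop - start]
            data[motor_mask, start:stop] += (
                g * burst_gain[motor_mask, None] * seg[None, :]
            )

    # --- rest ---------------------------------------------------------
    n_rest = int(round(cfg.rest_duration * cfg.fs))
    rest = _background(cfg, rng, n_rest)
    decorate(rest, "rest")
    recordings["rest"] = Recording(rest, cfg.fs, "rest", list(channels["name"]))

    # --- task and retest ---------------------------------------------
    for session, n_blocks, first_block in (
        ("task", cfg.task_blocks, 1),
        ("retest", cfg.retest_blocks, cfg.task_blocks + 1),
    ):
        n_samp = n_blocks * epoch_samp
        data = _background(cfg, rng, n_samp)
        press_samples = []
        burst_onsets = []
        for b in range(n_blocks):
            start, stop = b * epoch_samp, (b + 1) * epoch_samp
            k = rng.poisson(cfg.press_rate * EPOCH_SEC)
            onsets = np.sort(rng.integers(start, stop - win, size=k))
            for onset in onsets:
                correct = bool(rng.random() < cfg.correct_press_prob)
                # press event sample = window center
                press_samples.append((onset + win // 2, first_block + b, correct))
                if correct:
                    burst_onsets.append(int(onset))
        add_bursts(data, burst_onsets)
        decorate(data, session)
        recordings[session] = Recording(data, cfg.fs, session, list(channels["name"]))
        for sample, block, correct in press_samples:
            events_rows.append(
                {
                    "session": session,
                    "sample": int(sample),
                    "type": "press",
                    "block": int(block),
                    "correct": correct,
                }
            )

    # --- sleep periods ------------------------------------------------
    slots_per_epoch = int(EPOCH_SEC / WINDOW_SEC)  # non-overlapping slots
    for period, n_epochs, rate in (
        ("sleepPre", cfg.sleep_epochs_pre, cfg.true_motor_window_rate_pre),
        ("sleepPost", cfg.sleep_epochs_post, cfg.true_motor_window_rate_post),
    ):
        n_samp = n_epochs * epoch_samp
        data = _background(cfg, rng, n_samp)
        data += _sleep_activity(cfg, rng, n_samp)
        hypno = _make_hypnogram(rng, n_epochs)
        hypnograms[period] = hypno
        period_onsets = []
        for ep, stage in enumerate(hypno):
            if stage not in NREM_STAGES or rate <= 0:
                continue
            hit = rng.random(slots_per_epoch) < rate
            for slot in np.nonzero(hit)[0]:
                onset = ep * epoch_samp + slot * win
                injected[period].append((ep, int(onset)))
                period_onsets.append(onset)
        add_bursts(data, period_onsets)
        decorate(data, period)
        recordings[period] = Recording(data, cfg.fs, period, list(channels["name"]))

    tapping = generate_tapping_log(cfg)
    gt = GroundTruth(
        injected_windows=injected,
        burst_gain=burst_gain,
        tapping_params={
            "d0": cfg.tap_d0,
            "d_inf": cfg.tap_d_inf,
            "tau": cfg.tap_tau,
        },
        true_labels=list(channels["true_label"]),
        artifact_samples=artifact_samples,
    )
    events = pd.DataFrame(
        events_rows, columns=["session", "sample", "type", "block", "correct"]
    )
    return SynthBundle(
        recordings=recordings,
        channels=channels,
        events=events,
        hypnograms=hypnograms,
        ground_truth=gt,
        label_volume=volume,
        tapping_log=tapping,
        config=cfg,
    )


# --------------------------------------------------------------------------
# behavioral log
# --------------------------------------------------------------------------


def generate_tapping_log(config: SynthConfig) -> pd.DataFrame:
    """Simulate per-repetition sequence durations with a learning curve.

    Correct-repetition durations follow an exponential decay toward an
    asymptote across learning blocks, stay at the plateau during retest,
    and carry Gaussian noise; a configurable fraction are replaced by
    extreme outliers (4x the trend) that the mean+3SD rule should catch.
    Columns: ``block, repetition, duration, correct``.
    """
    cfg = config
    if cfg.task_blocks < 10:
        raise ValueError("need >= 10 learning blocks for the block contrasts")
    if cfg.retest_blocks < 3:
        raise ValueError("need >= 3 retest blocks")
    rng = np.random.default_rng(cfg.seed + 202)
    rows = []
    n_blocks = cfg.task_blocks + cfg.retest_blocks
    for b in range(1, n_blocks + 1):
        if b <= cfg.task_blocks:
            trend = cfg.tap_d_inf + (cfg.tap_d0 - cfg.tap_d_inf) * np.exp(
                -(b - 1) / cfg.tap_tau
            )
        else:
            trend = cfg.tap_d_inf
        n_reps = max(3, int(round(EPOCH_SEC / max(trend, 1e-9))))
        for rep in range(n_reps):
            dur = trend + cfg.tap_noise_sd * rng.standard_normal()
            dur = max(dur, 0.2)
            if cfg.tap_outlier_fraction > 0 and rng.random() < cfg.tap_outlier_fraction:
                dur = 4.0 * max(trend, 1.0)
            rows.append(
                {
                    "block": b,
                    "repetition": rep,
                    "duration": dur,
                    "correct": bool(rng.random() < 0.95),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# on-disk format (documented array + sidecar files; no EDF writer used)
# --------------------------------------------------------------------------


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> None:
    """Write a bundle as .npy arrays + JSON metadata + CSV sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, rec in bundle.recordings.items():
        np.save(out / f"{tag}.npy", rec.data.astype(np.float32))
        (out / f"{tag}.json").write_text(
            json.dumps({"fs": rec.fs, "session": tag, "channels": rec.channel_names})
        )
    bundle.channels.to_csv(out / "channels.csv", index=False)
    bundle.events.to_csv(out / "events.csv", index=False)
    bundle.tapping_log.to_csv(out / "tapping_log.csv", index=False)
    for period, stages in bundle.hypnograms.items():
        pd.DataFrame({"epoch": range(len(stages)), "stage": stages}).to_csv(
            out / f"hypnogram_{period}.csv", index=False
        )
    gt = bundle.ground_truth
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "injected_windows": gt.injected_windows,
                "burst_gain": gt.burst_gain.tolist(),
                "tapping_params": gt.tapping_params,
                "true_labels": gt.true_labels,
                "artifact_samples": gt.artifact_samples,
            },
            indent=1,
        )
    )
    np.save(out / "label_volume.npy", bundle.label_volume.labels)
    (out / "label_volume.json").write_text(
        json.dumps(
            {
                "names": {str(k): v for k, v in bundle.label_volume.names.items()},
                "origin": bundle.label_volume.origin.tolist(),
            }
        )
    )
    (out / "config.json").write_text(json.dumps(asdict(bundle.config), default=list))
    logger.info("wrote synthetic bundle to %s", out)
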