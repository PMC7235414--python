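"""Trial epoching, artifact rejection, featurization and class balancing.

Trials are 0.3-s windows of the normalized gamma envelope: centered on
each correct button press (motor class), tiled without overlap over the
rest session (rest class), or tiled with 50% overlap within each 30-s
NREM (N2/N3) sleep epoch (unlabeled). A trial is rejected iff any
envelope sample on any retained channel strictly exceeds 10 a.u.
(z-units); the per-channel feature is the mean envelope over the
window. Classes are balanced by uniform down-sampling of the larger
class.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import NREM_STAGES, TrialMatrix
from .gammaenv import EnvelopeSeries

logger = logging.getLogger("gammareplay")

WINDOW_SEC = 0.3
EPOCH_SEC = 30.0
ARTIFACT_THRESHOLD = 10.0  # a.u. (z-units); strictly greater rejects


def window_length(fs: float) -> int:
    return int(round(WINDOW_SEC * fs))


def epoch(
    env: EnvelopeSeries,
    mode: str,
    press_samples: np.ndarray | None = None,
    hypnogram: list | None = None,
) -> list[tuple[int, int]]:
    """Trial start indices as ``(start_sample, epoch_id)`` pairs.

    mode='motor': windows centered on each press sample (presses too
    close to a recording edge are skipped with a warning); 'rest':
    non-overlapping tiling from the start, final partial window dropped;
    'sleep': per 30-s N2/N3 epoch, 50%-overlapping windows that never
    cross the epoch boundary. Wake trials get epoch_id -1.
    """
    w = window_length(env.fs)
    n = env.n_samples
    trials: list[tuple[int, int]] = []
    if mode == "motor":
        if press_samples is None:
            raise ValueError("motor mode requires press samples")
        for press in np.asarray(press_samples, dtype=int):
            start = press - w // 2
            if start < 0 or start + w > n:
                logger.warning(
                    "press at sample %d within half a window of an edge; skipped",
                    press,
                )
                continue
            trials.append((int(start), -1))
    elif mode == "rest":
        for start in range(0, n - w + 1, w):
            trials.append((start, -1))
    elif mode == "sleep":
        if hypnogram is None:
            raise ValueError("sleep mode requires a hypnogram")
        step = int(round(WINDOW_SEC / 2.0 * env.fs))
        epoch_samp = int(round(EPOCH_SEC * env.fs))
        for ep, stage in enumerate(hypnogram):
            if stage not in NREM_STAGES:
                continue
            ep_start = ep * epoch_samp
            ep_stop = min((ep + 1) * epoch_samp, n)
            start = ep_start
            while start + w <= ep_stop:
                trials.append((start, ep))
                start += step
    else:
        raise ValueError(f"unknown epoching mode {mode!r}")
    return trials


def reject_and_featurize(
    env: EnvelopeSeries,
    trials: list[tuple[int, int]],
    label: str,
    threshold: float = ARTIFACT_THRESHOLD,
) -> TrialMatrix:
    """Mean-envelope features per trial, with strict > threshold rejection.

    A trial is invalid iff any sample of any channel inside its window
    exceeds ``threshold`` (strictly); invalid trials keep their row but
    are flagged. The rejection percentage is logged per session.
    """
    if threshold <= 0:
        raise ValueError("artifact threshold must be positive")
    w = window_length(env.fs)
    n_trials = len(trials)
    feats = np.zeros((n_trials, env.data.shape[0]))
    valid = np.ones(n_trials, dtype=bool)
    epoch_ids = np.full(n_trials, -1, dtype=int)
    for i, (start, ep) in enumerate(trials):
        seg = env.data[:, start : start + w]
        feats[i] = seg.mean(axis=-1)
        valid[i] = not np.any(seg > threshold)
        epoch_ids[i] = ep
    tm = TrialMatrix(
        feats,
        np.array([label] * n_trials, dtype=object),
        epoch_ids,
        valid,
        env.session,
        list(env.channel_names),
    )
    if n_trials:
        logger.info(
            "session %s: %.2f%% of %d trials rejected",
            env.session,
            100.0 * tm.rejection_fraction,
            n_trials,
        )
    return tm


def concatenate(tms: list[TrialMatrix], session: str = "") -> TrialMatrix:
    feats = np.vstack([t.features for t in tms])
    return TrialMatrix(
        feats,
        np.concatenate([t.labels for t in tms]),
        np.concatenate([t.epoch_id for t in tms]),
        np.concatenate([t.valid for t in tms]),
        session or tms[0].session,
        tms[0].channel_names,
    )


def balance_classes(
    motor: TrialMatrix, rest: TrialMatrix, seed: int
) -> TrialMatrix:
    """Down-sample the larger class (valid trials only) to the smaller.

    Selection is uniform without replacement from ``seed``; the output
    contains ``2 * min(n_motor, n_rest)`` trials, motor rows first.
    """
    motor_v = motor.valid_subset()
    rest_v = rest.valid_subset()
    if motor_v.n_trials == 0 or rest_v.n_trials == 0:
        raise ValueError("both classes must contain at least one valid trial")
    rng = np.random.default_rng(seed)
    n = min(motor_v.n_trials, rest_v.n_trials)

    def take(tm: TrialMatrix) -> TrialMatrix:
        if tm.n_trials == n:
            return tm
        idx = np.sort(rng.choice(tm.n_trials, size=n, replace=False))
        return TrialMatrix(
            tm.features[idx],
            tm.labels[idx],
            tm.epoch_id[idx],
            tm.valid[idx],
            tm.session,
            tm.channel_names,
        )

    return concatenate([take(motor_v), take(rest_v)], session="balanced")
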