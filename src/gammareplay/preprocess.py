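"""Recording cleanup: de-meaning, notch filtering, re-referencing, and
channel exclusion (bad channels, high interictal-discharge-rate channels,
motor-network restriction).

The notch is a zero-phase 4th-order Butterworth band-stop at 58-62 Hz
(and 118-122 Hz when the sampling rate allows). Depth electrodes are
re-referenced to a bipolar montage within each lead; grid electrodes to
the common average of the retained grid channels. Channels whose
interictal-discharge rate exceeds 6.5 events/min are excluded; the
detector here is a deliberately simple band-limited envelope threshold
(see :func:`ied_channel_rates`), not the published adaptive-envelope
algorithm.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .containers import PreprocessReport, Recording

logger = logging.getLogger("gammareplay")

IED_RATE_THRESHOLD = 6.5  # events/min; strictly greater excludes

NOTCH_BANDS = ((58.0, 62.0), (118.0, 122.0))


def _load_network_labels() -> set:
    ref = importlib.resources.files("gammareplay").joinpath(
        "motor_network_labels.yaml"
    )
    table = yaml.safe_load(ref.read_text())
    labels: set = set()
    for group, names in table.items():
        if group == "version":
            continue
        labels.update(names)
    return labels


#: DKT labels forming the motor-learning network (frontal, cingulate,
#: parietal cortices, striatum, hippocampus, cerebellum).
MOTOR_NETWORK_LABELS = _load_network_labels()


def demean_notch(rec: Recording) -> Recording:
    """De-mean each channel and band-stop filter the line-noise bands.

    Uses a zero-phase (forward-reverse) 4th-order Butterworth band-stop
    at 58-62 Hz, and additionally 118-122 Hz when that band lies below
    Nyquist (it does not at 250 Hz sampling).
    """
    bad = np.nonzero(~np.isfinite(rec.data).all(axis=1))[0]
    if bad.size:
        names = [rec.channel_names[i] for i in bad]
        raise ValueError(f"non-finite samples in channel(s) {names}")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    for lo, hi in NOTCH_BANDS:
        # skip bands at or near Nyquist (118-122 Hz at 250 Hz sampling)
        if hi >= 0.45 * rec.fs:
            continue
        sos = signal.butter(4, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)
    return Recording(data, rec.fs, rec.session, list(rec.channel_names))


def rereference(
    rec: Recording, channels: pd.DataFrame
) -> tuple[Recording, pd.DataFrame]:
    """Bipolar montage (depth leads) or common average reference (grids).

    Depth: output channel i is contact i minus contact i+1 within each
    lead (a lead of n contacts yields n-1 bipolar channels whose
    coordinates are the contact-pair midpoints). Grid: each channel
    minus the per-sample mean over all retained grid channels. Mixing
    the two kinds in one call is an error, as is a single-contact lead.
    """
    kinds = set(channels["kind"])
    if len(kinds) != 1:
        raise ValueError(f"cannot mix electrode kinds in one call: {sorted(kinds)}")
    kind = kinds.pop()
    name_to_row = {n: i for i, n in enumerate(rec.channel_names)}

    if kind == "grid":
        rows = [name_to_row[n] for n in channels["name"]]
        data = rec.data[rows]
        data = data - data.mean(axis=0, keepdims=True)
        out_channels = channels.reset_index(drop=True).copy()
        return Recording(data, rec.fs, rec.session, list(channels["name"])), out_channels

    # depth -> bipolar within leads, ordered by contact number
    out_rows = []
    new_meta = []
    for lead, grp in channels.groupby("lead", sort=False):
        grp = grp.sort_values("contact")
        if len(grp) < 2:
            raise ValueError(f"lead {lead} has a single contact; cannot re-reference")
        for (_, a), (_, b) in zip(grp.iloc[:-1].iterrows(), grp.iloc[1:].iterrows()):
            ia, ib = name_to_row[a["name"]], name_to_row[b["name"]]
            out_rows.append(rec.data[ia] - rec.data[ib])
            new_meta.append(
                {
                    "name": f"{a['name']}-{b['name']}",
                    "kind": "depth",
                    "lead": lead,
                    "contact": int(a["contact"]),
                    "x": (a["x"] + b["x"]) / 2.0,
                    "y": (a["y"] + b["y"]) / 2.0,
                    "z": (a["z"] + b["z"]) / 2.0,
                    "bad": bool(a.get("bad", False) or b.get("bad", False)),
                    "label": "",
                    "ied_rate": np.nan,
                }
            )
    out_channels = pd.DataFrame(new_meta)
    data = np.vstack(out_rows)
    return (
        Recording(data, rec.fs, rec.session, list(out_channels["name"])),
        out_channels,
    )


def ied_channel_rates(
    rec: Recording, k_mad: float = 8.0, merge_ms: float = 120.0
) -> np.ndarray:
    """Per-channel interictal-discharge rate (events/min), stand-in detector.

    Band-passes 10-60 Hz, takes the analytic amplitude, thresholds at
    ``median + k_mad * MAD`` per channel, and merges detections closer
    than ``merge_ms``. Requires at least 60 s of data for a stable rate.
    """
    if rec.duration < 60.0:
        raise ValueError(
            f"recording of {rec.duration:.1f} s is too short for rate estimation"
        )
    sos = signal.butter(
        4, [10.0, min(60.0, 0.45 * rec.fs)], btype="bandpass", fs=rec.fs, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    env = np.abs(signal.hilbert(filtered, axis=-1))
    med = np.median(env, axis=-1, keepdims=True)
    mad = np.median(np.abs(env - med), axis=-1, keepdims=True)
    thresh = med + k_mad * mad
    merge = int(round(merge_ms / 1000.0 * rec.fs))
    minutes = rec.duration / 60.0
    rates = np.zeros(rec.n_channels)
    for ch in range(rec.n_channels):
        above = env[ch] > thresh[ch, 0]
        if not above.any():
            continue
        d = np.diff(above.astype(int))
        onsets = np.nonzero(d == 1)[0] + 1
        offsets = np.nonzero(d == -1)[0] + 1
        if above[0]:
            onsets = np.r_[0, onsets]
        if above[-1]:
            offsets = np.r_[offsets, len(above)]
        # merge supra-threshold excursions separated by < merge window
        # (filter ring-down re-crossings belong to the same discharge)
        count = 0
        last_off = -np.inf
        for on, off in zip(onsets, offsets):
            if on - last_off > merge:
                count += 1
            last_off = off
        rates[ch] = count / minutes
    return rates


def pooled_ied_rates(recordings: dict, **kwargs) -> np.ndarray:
    """Duration-weighted pooled rate over sessions, per channel."""
    total_minutes = 0.0
    total_counts = None
    for rec in recordings.values():
        minutes = rec.duration / 60.0
        rates = ied_channel_rates(rec, **kwargs)
        counts = rates * minutes
        total_counts = counts if total_counts is None else total_counts + counts
        total_minutes += minutes
    return total_counts / total_minutes


def select_channels(
    channels: pd.DataFrame,
    rates: np.ndarray,
    bad_list: list | None = None,
    threshold: float = IED_RATE_THRESHOLD,
    network_filter: bool = False,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop bad channels, high-IED-rate channels, and (optionally)
    channels outside the motor-learning network.

    The rate rule is strictly greater: a channel at exactly
    ``threshold`` events/min is retained. With ``network_filter`` every
    channel must carry a label; channels whose label is not in
    :data:`MOTOR_NETWORK_LABELS` are dropped.
    """
    bad_list = list(bad_list or [])
    channels = channels.reset_index(drop=True).copy()
    channels["ied_rate"] = np.asarray(rates, dtype=float)
    keep = ~channels["name"].isin(bad_list)
    ied_excluded = channels.loc[channels["ied_rate"] > threshold, "name"].tolist()
    keep &= ~(channels["ied_rate"] > threshold)
    if network_filter:
        if (channels["label"] == "").any():
            raise ValueError("network filtering requires every channel labeled")
        keep &= channels["label"].isin(MOTOR_NETWORK_LABELS)
    retained = channels.loc[keep].reset_index(drop=True)
    if retained.empty:
        raise ValueError("channel selection removed every channel")
    report = PreprocessReport(
        excluded_bad_channels=[b for b in bad_list if b in set(channels["name"])],
        ied_rates=dict(zip(channels["name"], channels["ied_rate"])),
        excluded_ied_channels=ied_excluded,
        reference_scheme="bipolar"
        if (channels["kind"] == "depth").all()
        else "common_average",
    )
    n_dropped = len(channels) - len(retained)
    logger.info(
        "channel selection: retained %d / %d (%d dropped)",
        len(retained),
        len(channels),
        n_dropped,
    )
    return retained, report
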