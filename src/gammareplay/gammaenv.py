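"""Normalized broadband high-gamma envelope estimation.

The decoding signal is the analytic amplitude of the signal in
successive 10-Hz bands spanning 60-140 Hz (60-100 Hz at 250 Hz
sampling): each band is band-pass filtered with a zero-phase
forward-reverse windowed-sinc FIR (order = 3 cycles of the low cut-off),
Hilbert-transformed, smoothed with a 0.03-s moving average, z-scored
against the rest-session statistics of that channel/band, and the bands
averaged with equal weight into one envelope time series per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len
from scipy.ndimage import uniform_filter1d

from .containers import Recording

logger = logging.getLogger("gammareplay")

SMOOTH_SEC = 0.03


def band_set(fs: float) -> list[tuple[float, float]]:
    """Half-open 10-Hz analysis bands for the given sampling rate."""
    top = 140.0 if fs >= 2000.0 else 100.0
    return [(lo, lo + 10.0) for lo in np.arange(60.0, top, 10.0)]


@dataclass
class EnvelopeSeries:
    """Channels x samples normalized envelope (z-units relative to rest)."""

    data: np.ndarray
    fs: float
    session: str
    channel_names: list[str]
    bands: list[tuple[float, float]]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def band_envelope(rec: Recording, band: tuple[float, float]) -> np.ndarray:
    """Raw (unnormalized) analytic amplitude of ``rec`` in one band.

    FIR order = round(3 * fs / lo) taps, applied forward and reverse
    (zero phase, reflect padding of one filter length); envelope from
    the Hilbert transform, then smoothed over round(0.03 * fs) samples.
    """
    lo, hi = band
    if hi >= rec.fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist for fs={rec.fs}")
    ntaps = int(round(3.0 * rec.fs / lo))
    taps = signal.firwin(ntaps, [lo, hi], pass_zero=False, fs=rec.fs, window="hamming")
    padlen = min(ntaps, rec.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=-1,
                               padtype="even", padlen=padlen)
    nfft = next_fast_len(rec.n_samples)
    analytic = signal.hilbert(filtered, N=nfft, axis=-1)[..., : rec.n_samples]
    env = np.abs(analytic)
    width = max(1, int(round(SMOOTH_SEC * rec.fs)))
    return uniform_filter1d(env, size=width, axis=-1, mode="reflect")


def rest_statistics(
    band_envelopes_rest: dict, rest_slice: slice | None = None
) -> dict:
    """Per-(band, channel) mean/SD over the rest samples.

    ``band_envelopes_rest`` maps band -> channels x samples raw envelope
    of the rest session. A zero SD on any channel/band is an error.
    """
    stats = {}
    for band, env in band_envelopes_rest.items():
        seg = env if rest_slice is None else env[:, rest_slice]
        mu = seg.mean(axis=-1)
        sd = seg.std(axis=-1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero rest SD in band {band} on channel index(es) {zero.tolist()}"
            )
        stats[band] = (mu, sd)
    return stats


def normalize_and_average(
    band_envelopes: dict, stats: dict, fs: float, session: str,
    channel_names: list[str],
) -> EnvelopeSeries:
    """Z-score each band envelope with the rest statistics, then average.

    Normalization constants come only from the rest session, so session
    order cannot affect the result.
    """
    bands = sorted(band_envelopes)
    acc = None
    for band in bands:
        mu, sd = stats[band]
        z = (band_envelopes[band] - mu[:, None]) / sd[:, None]
        acc = z if acc is None else acc + z
    data = acc / len(bands)
    return EnvelopeSeries(data, fs, session, list(channel_names), bands)


def compute_envelopes(
    recordings: dict, rest_key: str = "rest"
) -> dict:
    """Full envelope stage for a set of sessions sharing channels.

    Computes per-band raw envelopes for every session, derives the
    normalization statistics from the rest session, and returns
    ``{session: EnvelopeSeries}``.
    """
    rest = recordings[rest_key]
    bands = band_set(rest.fs)
    raw = {
        tag: {band: band_envelope(rec, band) for band in bands}
        for tag, rec in recordings.items()
    }
    stats = rest_statistics(raw[rest_key])
    out = {}
    for tag, rec in recordings.items():
        out[tag] = normalize_and_average(
            raw[tag], stats, rec.fs, tag, rec.channel_names
        )
    return out
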