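"""Core data containers shared across the pipeline stages.

The pipeline moves a small number of well-defined objects between stages:
raw multichannel recordings, per-channel metadata, trial feature matrices,
fitted linear decoding models, and per-sleep-epoch vote series. They are
plain dataclasses around numpy arrays / pandas frames so that every stage
can be used and tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Session tags used throughout the pipeline, in experiment order.
SESSIONS = ("rest", "task", "sleepPre", "sleepPost", "retest")

#: Hypnogram vigilance stages (30-s epochs).
STAGES = ("W", "N1", "N2", "N3", "REM")

#: Stages counted as NREM for the reactivation (vote) analysis.
NREM_STAGES = ("N2", "N3")


@dataclass
class Recording:
    """A multichannel iEEG session: ``data`` is channels x samples (a.u.)."""

    data: np.ndarray
    fs: float
    session: str
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs


def make_channel_info(
    names: list[str],
    kinds: list[str],
    leads: list[str],
    coords: np.ndarray,
    contact_order: list[int] | None = None,
) -> pd.DataFrame:
    """Build the per-channel metadata table.

    Columns: ``name, kind (depth|grid), lead, contact, x, y, z, bad,
    label, ied_rate``. Coordinates are in mm in the label-volume frame.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(names), 3):
        raise ValueError("coords must be (n_channels, 3)")
    if contact_order is None:
        contact_order = list(range(len(names)))
    return pd.DataFrame(
        {
            "name": names,
            "kind": kinds,
            "lead": leads,
            "contact": contact_order,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "bad": False,
            "label": "",
            "ied_rate": np.nan,
        }
    )


@dataclass
class TrialMatrix:
    """Trials x channels mean-envelope features with labels and validity.

    ``labels`` entries are ``motor``, ``rest`` or ``unlabeled``;
    ``epoch_id`` is the 30-s sleep-epoch index a trial came from (or -1
    for wake trials). Rejected trials stay in the table with
    ``valid=False`` so rejection percentages remain computable.
    """

    features: np.ndarray
    labels: np.ndarray
    epoch_id: np.ndarray
    valid: np.ndarray
    session: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.epoch_id = np.asarray(self.epoch_id, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.epoch_id) == len(self.valid) == n):
            raise ValueError("TrialMatrix fields have inconsistent lengths")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def rejection_fraction(self) -> float:
        if self.n_trials == 0:
            return 0.0
        return 1.0 - self.valid.mean()

    def valid_subset(self) -> "TrialMatrix":
        m = self.valid
        return TrialMatrix(
            self.features[m],
            self.labels[m],
            self.epoch_id[m],
            self.valid[m],
            self.session,
            self.channel_names,
        )


@dataclass
class DecodingModel:
    """Linear motor-vs-rest classifier in standardized feature space.

    Decision value d(x) = beta . ((x - mu) / sigma) + bias; the trial is
    voted ``motor`` iff d(x) > 0.
    """

    beta: np.ndarray
    bias: float
    mu: np.ndarray
    sigma: np.ndarray
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"feature dimension {features.shape[1]} does not match "
                f"model dimension {self.beta.shape[0]}"
            )
        return ((features - self.mu) / self.sigma) @ self.beta + self.bias


@dataclass
class CVResult:
    """Per-fold accuracies and their mean (decoding accuracy, DA)."""

    fold_accuracies: np.ndarray

    @property
    def decoding_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class VoteSeries:
    """Per-30-s-NREM-epoch proportion of motor votes for one sleep period."""

    period: str
    epoch_ids: np.ndarray
    proportions: np.ndarray
    n_accepted: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_ids = np.asarray(self.epoch_ids, dtype=int)
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.n_accepted = np.asarray(self.n_accepted, dtype=int)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_ids)

    @property
    def median(self) -> float:
        return float(np.median(self.proportions))


@dataclass
class TestResult:
    """Rank-sum comparison result: z statistic, p value, effect size r."""

    z: float
    p: float
    r: float
    n_total: int
    significant: bool
    degenerate: bool = False


@dataclass
class PerformanceSummary:
    """Per-subject tapping performance: normalized durations and contrasts.

    ``improvement_pct`` = 100 * (m23 - m910) / m23 over the normalized
    block means; ``performance_index`` = m910 - m1213 (learning blocks
    9:10 minus retest blocks 12:13).
    """

    normalized: pd.DataFrame
    excluded_pct: float
    n_accepted: int
    baseline_mean: float
    block_means: dict
    improvement_pct: float
    performance_index: float


@dataclass
class PreprocessReport:
    """Bookkeeping of channel exclusions and the reference scheme used."""

    excluded_bad_channels: list[str]
    ied_rates: dict
    excluded_ied_channels: list[str]
    reference_scheme: str

    def __post_init__(self) -> None:
        if set(self.excluded_bad_channels) & set(self.excluded_ied_channels):
            # overlap is legal (a bad channel may also be IED-laden) but the
            # retained set must be disjoint from both; enforced in selection
            pass
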