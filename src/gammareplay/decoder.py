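"""Linear motor-vs-rest decoding.

A soft-margin linear support-vector machine (C = 1, unit kernel scale)
on standardized mean-envelope features. Decoding accuracy (DA) is the
mean of the five fold accuracies of a stratified, seeded 5-fold
cross-validation in which standardization is refit within each training
split. The fitted full model predicts a motor/rest vote for each
unlabeled sleep trial; per-area weight contributions are summarized as
the per-area maximum of the min-max-rescaled |beta|.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import CVResult, DecodingModel, TrialMatrix

logger = logging.getLogger("gammareplay")

SVM_C = 1.0


def _check_balanced(tm: TrialMatrix) -> tuple[np.ndarray, np.ndarray]:
    tm = tm.valid_subset()
    y = (tm.labels == "motor").astype(int)
    counts = np.bincount(y, minlength=2)
    if counts[0] != counts[1] or counts.sum() == 0:
        raise ValueError(
            f"trial matrix must be class-balanced (got {counts[1]} motor / "
            f"{counts[0]} rest); balance first"
        )
    return tm.features, y


def crossvalidate(tm: TrialMatrix, k: int = 5, seed: int = 0) -> CVResult:
    """Stratified seeded k-fold decoding accuracy.

    Each fold fits standardization and the SVM on the training split
    only; fold accuracy is the fraction of validation trials correctly
    labeled, and DA is the mean over folds.
    """
    X, y = _check_balanced(tm)
    if min(np.bincount(y)) < k:
        raise ValueError(f"need at least {k} trials per class for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=SVM_C)
        clf.fit(scaler.transform(X[train]), y[train])
        accs.append(float(np.mean(clf.predict(scaler.transform(X[test])) == y[test])))
    return CVResult(np.array(accs))


def train_full(tm: TrialMatrix) -> DecodingModel:
    """Fit the soft-margin linear SVM on the full balanced trial set."""
    X, y = _check_balanced(tm)
    if np.all(X == X[0]):
        raise ValueError("degenerate trial matrix: all feature rows identical")
    scaler = StandardScaler().fit(X)
    if np.any(scaler.scale_ == 0):
        raise ValueError("zero-variance feature; cannot standardize")
    clf = SVC(kernel="linear", C=SVM_C)
    clf.fit(scaler.transform(X), y)
    return DecodingModel(
        beta=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        mu=scaler.mean_.copy(),
        sigma=scaler.scale_.copy(),
        channel_names=list(tm.channel_names),
        meta={"n_trials": int(len(y)), "C": SVM_C, "kernel": "linear"},
    )


def predict_sleep(model: DecodingModel, tm: TrialMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Motor/rest votes for the valid sleep trials.

    Returns ``(votes, epoch_ids)`` over valid trials only; a vote is
    True (motor) iff the decision value is positive.
    """
    tm = tm.valid_subset()
    if tm.n_trials == 0:
        return np.array([], dtype=bool), np.array([], dtype=int)
    d = model.decision_values(tm.features)
    return d > 0, tm.epoch_id.copy()


def beta_by_area(model: DecodingModel, labels: list[str]) -> pd.DataFrame:
    """Per-area maximum of min-max-rescaled |beta|.

    With a single channel (or all |beta| equal) the rescaled value is 1
    by convention. Every channel must carry a label.
    """
    if len(labels) != len(model.beta):
        raise ValueError("one label per model feature required")
    if any(not l for l in labels):
        raise ValueError("every channel must be labeled")
    absb = np.abs(model.beta)
    span = absb.max() - absb.min()
    rescaled = np.ones_like(absb) if span == 0 else (absb - absb.min()) / span
    df = pd.DataFrame({"area": labels, "rescaled_abs_beta": rescaled})
    return (
        df.groupby("area", sort=True)["rescaled_abs_beta"]
        .max()
        .reset_index()
        .sort_values("rescaled_abs_beta", ascending=False)
        .reset_index(drop=True)
    )


def save_model(model: DecodingModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "beta": model.beta.tolist(),
                "bias": model.bias,
                "mu": model.mu.tolist(),
                "sigma": model.sigma.tolist(),
                "channel_names": model.channel_names,
                "meta": model.meta,
            }
        )
    )


def load_model(path: str | Path) -> DecodingModel:
    d = json.loads(Path(path).read_text())
    return DecodingModel(
        np.array(d["beta"]),
        float(d["bias"]),
        np.array(d["mu"]),
        np.array(d["sigma"]),
        d["channel_names"],
        d.get("meta", {}),
    )
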