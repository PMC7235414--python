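"""End-to-end orchestration: synthetic session -> preprocessing ->
electrode labeling -> gamma envelope -> trials -> decoder -> reactivation
statistics, with explicit seeding and a machine-readable report.

One top-level seed fans out to the stage seeds (synthesis, class
balancing, cross-validation) by fixed offsets, so identical
configurations yield byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import decoder, ela, features, gammaenv, preprocess, stats
from .containers import Recording, TrialMatrix
from .synthdata import SynthBundle, SynthConfig, generate_session

logger = logging.getLogger("gammareplay")

SEED_OFFSET_BALANCE = 10_000
SEED_OFFSET_CV = 20_000


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    modes: tuple = ("all", "network")
    bad_channels: tuple = ()
    ied_threshold: float = preprocess.IED_RATE_THRESHOLD
    artifact_threshold: float = features.ARTIFACT_THRESHOLD
    alpha: float = stats.ALPHA_REACTIVATION
    include_retest: bool = True
    compute_spectra: bool = False

    def __post_init__(self) -> None:
        if self.ied_threshold <= 0 or self.artifact_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        self.synth = (
            self.synth
            if isinstance(self.synth, SynthConfig)
            else SynthConfig(**dict(self.synth))
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        return cls(synth=synth, **raw)

    @property
    def seed_balance(self) -> int:
        return self.seed + SEED_OFFSET_BALANCE

    @property
    def seed_cv(self) -> int:
        return self.seed + SEED_OFFSET_CV


def _subset_trials(tm: TrialMatrix, col_idx: np.ndarray, names: list) -> TrialMatrix:
    return TrialMatrix(
        tm.features[:, col_idx],
        tm.labels,
        tm.epoch_id,
        tm.valid,
        tm.session,
        names,
    )


def run_subject(cfg: RunConfig, bundle: SynthBundle | None = None) -> dict:
    """Run the full analysis for one (synthetic) subject.

    Returns a JSON-serializable report with, per channel-selection mode,
    the decoding accuracy, the per-subject reactivation row (median
    pre/post, z, p, r, significance), the reactivation index, and the
    per-area weight summary, plus preprocessing exclusions, behavioral
    performance and hypnogram descriptives.
    """
    synth_cfg = cfg.synth
    if bundle is None:
        synth_cfg = SynthConfig(**{**asdict(synth_cfg), "seed": cfg.seed})
        bundle = generate_session(synth_cfg)

    # --- preprocessing -------------------------------------------------
    channels = bundle.channels
    if cfg.bad_channels:
        channels = channels.loc[~channels["name"].isin(cfg.bad_channels)]
        channels = channels.reset_index(drop=True)
    clean = {tag: preprocess.demean_notch(rec) for tag, rec in bundle.recordings.items()}
    reref = {}
    reref_channels = None
    for tag, rec in clean.items():
        # restrict to the retained contacts before re-referencing
        rows = [rec.channel_names.index(n) for n in channels["name"]]
        sub = Recording(rec.data[rows], rec.fs, tag, list(channels["name"]))
        r, reref_channels = preprocess.rereference(sub, channels)
        reref[tag] = r
    rates = preprocess.pooled_ied_rates(reref)

    # ELA labels on the bipolar midpoints, before network selection
    labeled = ela.label_channels(reref_channels, bundle.label_volume)
    retained, report_pre = preprocess.select_channels(
        labeled, rates, bad_list=[], threshold=cfg.ied_threshold, network_filter=False
    )
    keep_idx = np.array(
        [list(labeled["name"]).index(n) for n in retained["name"]], dtype=int
    )
    retained_recs = {
        tag: Recording(rec.data[keep_idx], rec.fs, tag, list(retained["name"]))
        for tag, rec in reref.items()
    }

    # --- envelope and trials ------------------------------------------
    envs = gammaenv.compute_envelopes(retained_recs, rest_key="rest")
    ev = bundle.events
    motor_sessions = ["task"] + (["retest"] if cfg.include_retest else [])
    motor_tms = []
    for ses in motor_sessions:
        presses = ev.loc[
            (ev["session"] == ses) & (ev["type"] == "press") & (ev["correct"]),
            "sample",
        ].to_numpy()
        trials = features.epoch(envs[ses], "motor", press_samples=presses)
        motor_tms.append(
            features.reject_and_featurize(
                envs[ses], trials, "motor", cfg.artifact_threshold
            )
        )
    motor_tm = features.concatenate(motor_tms, session="motor")
    rest_trials = features.epoch(envs["rest"], "rest")
    rest_tm = features.reject_and_featurize(
        envs["rest"], rest_trials, "rest", cfg.artifact_threshold
    )
    sleep_tms = {}
    for period in ("sleepPre", "sleepPost"):
        trials = features.epoch(
            envs[period], "sleep", hypnogram=bundle.hypnograms[period]
        )
        sleep_tms[period] = features.reject_and_featurize(
            envs[period], trials, "unlabeled", cfg.artifact_threshold
        )

    # --- per-mode decoding and statistics -----------------------------
    report: dict = {
        "config": {"seed": cfg.seed, "synth_seed": synth_cfg.seed},
        "preprocess": {
            "n_channels_initial": int(len(bundle.channels)),
            "n_channels_rereferenced": int(len(labeled)),
            "n_channels_retained": int(len(retained)),
            "excluded_ied_channels": report_pre.excluded_ied_channels,
            "excluded_bad_channels": list(cfg.bad_channels),
            "reference_scheme": report_pre.reference_scheme,
        },
        "rejection_pct": {
            "task": 100.0 * motor_tm.rejection_fraction,
            "rest": 100.0 * rest_tm.rejection_fraction,
            "sleepPre": 100.0 * sleep_tms["sleepPre"].rejection_fraction,
            "sleepPost": 100.0 * sleep_tms["sleepPost"].rejection_fraction,
        },
        "modes": {},
    }

    all_names = list(retained["name"])
    labels_by_name = dict(zip(retained["name"], retained["label"]))
    for mode in cfg.modes:
        if mode == "all":
            names = all_names
        elif mode == "network":
            names = [
                n
                for n in all_names
                if labels_by_name[n] in preprocess.MOTOR_NETWORK_LABELS
            ]
            if not names:
                raise ValueError("no channels inside the motor-learning network")
        else:
            raise ValueError(f"unknown channel-selection mode {mode!r}")
        col_idx = np.array([all_names.index(n) for n in names], dtype=int)

        m_tm = _subset_trials(motor_tm, col_idx, names)
        r_tm = _subset_trials(rest_tm, col_idx, names)
        balanced = features.balance_classes(m_tm, r_tm, cfg.seed_balance)
        cv = decoder.crossvalidate(balanced, k=5, seed=cfg.seed_cv)
        model = decoder.train_full(balanced)

        series = {}
        for period in ("sleepPre", "sleepPost"):
            s_tm = _subset_trials(sleep_tms[period], col_idx, names)
            votes, epoch_ids = decoder.predict_sleep(model, s_tm)
            series[period] = stats.vote_proportions(votes, epoch_ids, period)
        test = stats.compare_periods(
            series["sleepPre"], series["sleepPost"], alpha=cfg.alpha
        )
        area_table = decoder.beta_by_area(model, [labels_by_name[n] for n in names])
        report["modes"][mode] = {
            "n_channels": len(names),
            "decoding_accuracy": cv.decoding_accuracy,
            "fold_accuracies": [float(a) for a in cv.fold_accuracies],
            "median_pre": series["sleepPre"].median,
            "median_post": series["sleepPost"].median,
            "n_epochs_pre": int(series["sleepPre"].n_epochs),
            "n_epochs_post": int(series["sleepPost"].n_epochs),
            "z": test.z,
            "p": test.p,
            "r": test.r,
            "significant": test.significant,
            "reactivation_index": stats.reactivation_index(
                series["sleepPre"], series["sleepPost"]
            ),
            "beta_by_area": {
                row["area"]: float(row["rescaled_abs_beta"])
                for _, row in area_table.iterrows()
            },
        }

    # --- behavior and descriptives ------------------------------------
    perf = stats.performance_summary(bundle.tapping_log)
    report["performance"] = {
        "improvement_pct": perf.improvement_pct,
        "performance_index": perf.performance_index,
        "excluded_pct": perf.excluded_pct,
        "n_accepted": perf.n_accepted,
        "block_means": perf.block_means,
    }
    report["hypnograms"] = {
        period: stats.hypnogram_summary(stages)
        for period, stages in bundle.hypnograms.items()
    }
    if cfg.compute_spectra:
        beta_full = None
        if "all" in report["modes"]:
            # recompute the full-channel beta for the channel split
            balanced_all = features.balance_classes(
                motor_tm, rest_tm, cfg.seed_balance
            )
            beta_full = decoder.train_full(balanced_all).beta
        spectra = stats.spectrum_qc(
            {t: retained_recs[t] for t in ("rest", "task", "sleepPre", "sleepPost")},
            beta=beta_full,
        )
        report["spectra"] = {
            k: (
                {kk: vv.tolist() for kk, vv in v.items()}
                if isinstance(v, dict)
                else v.tolist()
            )
            for k, v in spectra.items()
        }
    return report


def run_pipeline(cfg: RunConfig, out_path: str | Path | None = None) -> dict:
    """Run one subject end to end and optionally write the JSON report."""
    report = run_subject(cfg)
    if out_path is not None:
        Path(out_path).write_text(report_to_json(report))
        logger.info("report written to %s", out_path)
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1)


def run_cohort(
    base_synth: SynthConfig,
    n_subjects: int,
    seed: int = 0,
    modes: tuple = ("all",),
    **run_kwargs,
) -> dict:
    """Run several subjects and add the group-level statistics.

    Subjects differ only by seed (seed + subject index). Returns
    per-subject reports plus, per mode, the paired t-test on median
    vote proportions and the correlations of the reactivation index
    with the performance index and with the (synthetic) elapsed time
    between sleep periods.
    """
    rng = np.random.default_rng(seed + 777)
    reports = []
    elapsed = []
    for s in range(n_subjects):
        scfg = SynthConfig(**{**asdict(base_synth), "seed": seed + s})
        cfg = RunConfig(synth=scfg, seed=seed + s, modes=modes, **run_kwargs)
        reports.append(run_subject(cfg))
        base_min = (
            base_synth.rest_duration / 60.0 + base_synth.task_blocks * 1.0
        )
        elapsed.append(base_min + rng.uniform(5.0, 30.0))
    out: dict = {"subjects": reports, "group": {}}
    for mode in modes:
        med_pre = np.array([r["modes"][mode]["median_pre"] for r in reports])
        med_post = np.array([r["modes"][mode]["median_post"] for r in reports])
        idx = np.array([r["modes"][mode]["reactivation_index"] for r in reports])
        perf = np.array([r["performance"]["performance_index"] for r in reports])
        group = {"paired_t": stats.group_level(med_pre, med_post)}
        if n_subjects >= 3 and np.std(idx) > 0 and np.std(perf) > 0:
            group["correlations"] = stats.reactivation_correlation(
                idx, perf, np.array(elapsed)
            )
        group["n_significant"] = int(
            sum(r["modes"][mode]["significant"] for r in reports)
        )
        out["group"][mode] = group
    return out
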