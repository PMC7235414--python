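"""Reactivation statistics, behavioral performance, and spectral QC.

The reactivation readout is the per-30-s-NREM-epoch proportion of sleep
trials voted "motor". Within a subject, the pre- vs post-learning
distributions of these proportions are compared with a left-tailed
Wilcoxon rank-sum test (alternative: proportions are larger after
learning; the z statistic is negative under the alternative), with the
effect size r = z / sqrt(n). For small samples (total <= 12) the p
value is the exact permutation tail mass; otherwise a tie- and
continuity-corrected normal approximation is used. Group level:
two-tailed paired t on the per-subject medians; the reactivation index
(median difference post-pre times the number of post epochs) is
correlated with the behavioral performance index and, as a control,
with the elapsed time between the sleep periods.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    NREM_STAGES,
    PerformanceSummary,
    Recording,
    TestResult,
    VoteSeries,
)

logger = logging.getLogger("gammareplay")

ALPHA_REACTIVATION = 0.025
EXACT_MAX_N = 12


# --------------------------------------------------------------------------
# vote series
# --------------------------------------------------------------------------


def vote_proportions(
    votes: np.ndarray, epoch_ids: np.ndarray, period: str
) -> VoteSeries:
    """Per-NREM-epoch proportion of motor votes.

    Denominators are the accepted (valid) trials of each epoch; epochs
    with zero accepted trials are excluded and logged.
    """
    votes = np.asarray(votes, dtype=bool)
    epoch_ids = np.asarray(epoch_ids, dtype=int)
    if votes.size == 0:
        raise ValueError(f"no NREM sleep trials in period {period!r}")
    ids = np.unique(epoch_ids)
    props, counts, kept = [], [], []
    for ep in ids:
        sel = epoch_ids == ep
        n = int(sel.sum())
        if n == 0:
            logger.warning("period %s epoch %d has no accepted trials", period, ep)
            continue
        kept.append(ep)
        counts.append(n)
        props.append(votes[sel].mean())
    return VoteSeries(period, np.array(kept), np.array(props), np.array(counts))


# --------------------------------------------------------------------------
# rank-sum comparison
# --------------------------------------------------------------------------


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_left_p(pre: np.ndarray, post: np.ndarray) -> float:
    """Exact permutation left-tail mass P(W_pre <= w_obs).

    W is the midrank sum of the pre group over the pooled sample;
    enumerated over all C(n, n_pre) group assignments (ties handled by
    midranks). Feasible for the small-sample regime where it is used.
    """
    pooled = np.concatenate([pre, post])
    ranks = _midranks(pooled)
    n, k = len(pooled), len(pre)
    w_obs = ranks[:k].sum()
    hits = 0
    for idx in combinations(range(n), k):
        if ranks[list(idx)].sum() <= w_obs + 1e-12:
            hits += 1
    return hits / comb(n, k)


def _normal_z(pre: np.ndarray, post: np.ndarray) -> float:
    """Tie- and continuity-corrected normal z for the pre rank sum."""
    pooled = np.concatenate([pre, post])
    n1, n2 = len(pre), len(post)
    n = n1 + n2
    ranks = _midranks(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    diff = w - mu
    # continuity correction toward the null, sign-symmetric
    if diff > 0.5:
        diff -= 0.5
    elif diff < -0.5:
        diff += 0.5
    else:
        diff = 0.0
    return float(diff / np.sqrt(var))


def compare_periods(
    pre: VoteSeries, post: VoteSeries, alpha: float = ALPHA_REACTIVATION
) -> TestResult:
    """Left-tailed rank-sum comparison of the two sleep periods.

    Alternative: motor-vote proportions are larger in the post period,
    in which case the pre ranks are low and z is negative. p is exact
    (permutation enumeration) for total n <= 12, else the normal
    approximation with tie and continuity corrections. r = z / sqrt(n).
    """
    a = np.asarray(pre.proportions, dtype=float)
    b = np.asarray(post.proportions, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both periods need at least one epoch")
    n = len(a) + len(b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("all vote proportions identical; rank-sum degenerate")
        z = 0.0
        p = 1.0
        return TestResult(z, p, 0.0, n, significant=False, degenerate=True)
    z = _normal_z(a, b)
    if n <= EXACT_MAX_N:
        p = _exact_left_p(a, b)
    else:
        p = float(sps.norm.cdf(z))
    r = z / np.sqrt(n)
    return TestResult(z, p, r, n, significant=bool(p < alpha))


# --------------------------------------------------------------------------
# group-level tests and correlations
# --------------------------------------------------------------------------


def group_level(medians_pre: np.ndarray, medians_post: np.ndarray) -> dict:
    """Two-tailed paired t-test on per-subject median vote proportions."""
    a = np.asarray(medians_pre, dtype=float)
    b = np.asarray(medians_post, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 paired subjects")
    d = a - b
    degenerate = bool(np.std(d, ddof=1) == 0)
    if degenerate:
        if np.all(d == 0):
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(d.mean()) * np.inf)
            p = 0.0
        logger.warning("zero-variance paired differences; t-test degenerate")
    else:
        t, p = sps.ttest_rel(a, b)
        t, p = float(t), float(p)
    return {"t": t, "df": len(a) - 1, "p": p, "degenerate": degenerate}


def reactivation_index(pre: VoteSeries, post: VoteSeries) -> float:
    """(median post - median pre) * number of post-sleep NREM epochs."""
    return (post.median - pre.median) * post.n_epochs


def performance_index_from_blocks(block_means: dict) -> float:
    return block_means["9:10"] - block_means["12:13"]


def reactivation_correlation(
    indices: np.ndarray,
    performance_indices: np.ndarray,
    elapsed_minutes: np.ndarray | None = None,
) -> dict:
    """Pearson correlations of the reactivation index across subjects.

    Against (a) the behavioral performance index and, when provided,
    (b) the time elapsed between the two sleep periods (control).
    """
    x = np.asarray(indices, dtype=float)
    y = np.asarray(performance_indices, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 subjects for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlated variable")
    r_perf, p_perf = sps.pearsonr(x, y)
    out = {"performance": {"r": float(r_perf), "p": float(p_perf)}}
    if elapsed_minutes is not None:
        t = np.asarray(elapsed_minutes, dtype=float)
        if np.std(t) == 0:
            raise ValueError("zero variance in elapsed time")
        r_t, p_t = sps.pearsonr(x, t)
        out["elapsed_time"] = {"r": float(r_t), "p": float(p_t)}
    return out


# --------------------------------------------------------------------------
# behavioral performance
# --------------------------------------------------------------------------

BLOCK_CONTRASTS = {"2:3": (2, 3), "9:10": (9, 10), "12:13": (12, 13)}


def performance_summary(log: pd.DataFrame) -> PerformanceSummary:
    """Per-subject tapping summary with outlier exclusion and contrasts.

    Repetitions strictly slower than pooled mean + 3 SD (over all
    correct repetitions) are excluded; accepted durations are divided by
    their overall mean (baseline normalization, mean 1 by construction).
    Block means for 2:3 (early learning), 9:10 (late learning) and
    12:13 (retest) give improvement % = 100*(m23-m910)/m23 and the
    performance index m910 - m1213.
    """
    correct = log.loc[log["correct"]].copy()
    if correct.empty:
        raise ValueError("no correct repetitions in the log")
    dur = correct["duration"].to_numpy(dtype=float)
    mean, sd = dur.mean(), dur.std(ddof=1) if len(dur) > 1 else 0.0
    keep = dur <= mean + 3 * sd
    accepted = correct.loc[keep].copy()
    excluded_pct = 100.0 * (1.0 - keep.mean())
    baseline = accepted["duration"].mean()
    accepted["normalized"] = accepted["duration"] / baseline
    block_means = {}
    for name, blocks in BLOCK_CONTRASTS.items():
        sel = accepted.loc[accepted["block"].isin(blocks), "normalized"]
        if sel.empty:
            raise ValueError(f"no accepted repetitions in contrast blocks {name}")
        block_means[name] = float(sel.mean())
    m23, m910 = block_means["2:3"], block_means["9:10"]
    improvement = 100.0 * (m23 - m910) / m23
    return PerformanceSummary(
        normalized=accepted,
        excluded_pct=float(excluded_pct),
        n_accepted=int(keep.sum()),
        baseline_mean=float(baseline),
        block_means=block_means,
        improvement_pct=float(improvement),
        performance_index=float(performance_index_from_blocks(block_means)),
    )


def group_performance_anova(summaries: list[PerformanceSummary]) -> dict:
    """Repeated-measures ANOVA (Greenhouse-Geisser) over the three
    block contrasts across subjects, plus post-hoc paired t-tests."""
    import pingouin as pg

    rows = []
    for s_id, summ in enumerate(summaries):
        for name, m in summ.block_means.items():
            rows.append({"subject": s_id, "contrast": name, "mean_duration": m})
    df = pd.DataFrame(rows)
    aov = pg.rm_anova(
        data=df, dv="mean_duration", within="contrast", subject="subject",
        correction=True,
    )
    row = aov.iloc[0]
    p_gg = row["p_GG_corr"] if "p_GG_corr" in aov.columns and np.isfinite(
        row.get("p_GG_corr", np.nan)
    ) else row["p_unc"]
    posthoc = {}
    names = list(BLOCK_CONTRASTS)
    wide = df.pivot(index="subject", columns="contrast", values="mean_duration")
    for a, b in combinations(names, 2):
        t, p = sps.ttest_rel(wide[a], wide[b])
        posthoc[f"{a} vs {b}"] = {"t": float(t), "p": float(p)}
    return {
        "F": float(row["F"]),
        "p_gg": float(p_gg),
        "eps_gg": float(row.get("eps", np.nan)),
        "posthoc": posthoc,
    }


# --------------------------------------------------------------------------
# spectral QC and hypnogram descriptives
# --------------------------------------------------------------------------


def spectrum_qc(
    recordings: dict,
    hypnograms: dict | None = None,
    beta: np.ndarray | None = None,
    fmin: float = 0.5,
    fmax: float = 25.0,
    fstep: float = 0.5,
    segment_sec: float = 30.0,
) -> dict:
    """Multitaper (DPSS) mean log-power spectra per condition.

    Each recording is cut into 30-s segments (sleep: its 30-s epochs;
    task/rest: consecutive 30-s windows); the per-segment multitaper PSD
    is averaged over segments and channels, regridded to ``fstep`` bins
    and log10-transformed. When ``beta`` is given, spectra for the
    top-5 and bottom-5 |beta| channel subsets are included. Segments
    shorter than 2 s are excluded with a warning.
    """
    from mne.time_frequency import psd_array_multitaper

    grid = np.arange(fmin, fmax + fstep / 2.0, fstep)
    out: dict = {"freqs": grid}
    for tag, rec in recordings.items():
        seg_len = int(round(segment_sec * rec.fs))
        segments = []
        for start in range(0, rec.n_samples - seg_len + 1, seg_len):
            segments.append(rec.data[:, start : start + seg_len])
        if not segments and rec.n_samples >= int(2 * rec.fs):
            segments = [rec.data]
        if not segments:
            logger.warning("session %s too short for spectral QC; skipped", tag)
            continue
        arr = np.stack(segments)  # segments x channels x samples
        psd, freqs = psd_array_multitaper(
            arr, rec.fs, fmin=fmin, fmax=fmax, verbose="error"
        )
        mean_psd = psd.mean(axis=0)  # channels x freqs

        def on_grid(p2d: np.ndarray) -> np.ndarray:
            avg = p2d.mean(axis=0)
            return np.interp(grid, freqs, avg)

        entry = {"all": np.log10(on_grid(mean_psd))}
        if beta is not None and len(beta) == rec.n_channels and rec.n_channels >= 5:
            order = np.argsort(np.abs(beta))
            entry["bottom5"] = np.log10(on_grid(mean_psd[order[:5]]))
            entry["top5"] = np.log10(on_grid(mean_psd[order[-5:]]))
        out[tag] = entry
    return out


def hypnogram_summary(stages: list, include_n1: bool = False) -> dict:
    """Sleep-period time and NREM minutes from a 30-s-epoch hypnogram.

    SPT spans the first through last sleep (non-wake) epoch; NREM
    minutes count N2/N3 epochs (N1 optionally included).
    """
    stages = list(stages)
    sleep_idx = [i for i, s in enumerate(stages) if s != "W"]
    if not sleep_idx:
        raise ValueError("hypnogram contains no sleep epochs")
    first, last = sleep_idx[0], sleep_idx[-1]
    spt_min = (last - first + 1) * 0.5
    nrem_set = set(NREM_STAGES) | ({"N1"} if include_n1 else set())
    nrem_min = sum(1 for s in stages if s in nrem_set) * 0.5
    return {
        "spt_min": spt_min,
        "nrem_min": nrem_min,
        "pct_nrem_of_spt": 100.0 * nrem_min / spt_min,
        "n_epochs": len(stages),
    }
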