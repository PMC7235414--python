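"""Reactivation statistics: rank-sum against an exact permutation oracle,
effect sizes, behavioral summaries, correlations, spectra and hypnogram
descriptives."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gammareplay import (
    compare_periods,
    group_level,
    hypnogram_summary,
    performance_summary,
    reactivation_correlation,
    reactivation_index,
    spectrum_qc,
    vote_proportions,
)
from gammareplay.containers import Recording, VoteSeries
from gammareplay.stats import group_performance_anova


def vs(values, period="sleepPre"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return VoteSeries(period, np.arange(n), values, np.full(n, 199))


def oracle_left_p(pre, post):
    """Independent enumeration oracle via the Mann-Whitney U statistic.

    U = #{(i,j): pre_i < post_j} + 0.5 #{ties}; small U means pre ranks
    low (post larger). Tail mass P(U <= u_obs) over all C(n, n_pre)
    assignments of the pooled values to the pre group.
    """
    pooled = np.concatenate([pre, post])
    n, k = len(pooled), len(pre)

    def u_stat(pre_vals, post_vals):
        u = 0.0
        for a in pre_vals:
            for b in post_vals:
                if a < b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(pre, post)
    hits = 0
    idx_all = set(range(n))
    for pre_idx in combinations(range(n), k):
        rest = sorted(idx_all - set(pre_idx))
        if u_stat(pooled[list(pre_idx)], pooled[rest]) >= u_obs - 1e-12:
            hits += 1
    return hits / comb(n, k)


class TestComparePeriods:
    def test_most_extreme_ordering_exact_p(self):
        res = compare_periods(vs([0.1, 0.2]), vs([0.8, 0.9], "sleepPost"))
        assert res.p == pytest.approx(1.0 / 6.0, abs=1e-12)
        assert res.z < 0

    def test_matches_enumeration_for_small_samples(self, rng):
        for trial in range(40):
            n1 = rng.integers(1, 11)
            n2 = rng.integers(1, 13 - n1)
            # discrete support induces ties
            pre = rng.integers(0, 5, size=n1) / 4.0
            post = rng.integers(0, 5, size=n2) / 4.0
            if len(set(np.r_[pre, post])) == 1:
                continue
            res = compare_periods(vs(pre), vs(post, "sleepPost"))
            assert res.p == pytest.approx(oracle_left_p(pre, post), abs=1e-9)

    def test_identical_multisets_z_near_zero(self):
        vals = [0.1, 0.3, 0.5, 0.2]
        res = compare_periods(vs(vals), vs(vals, "sleepPost"))
        assert abs(res.z) < 1e-12
        assert 0.4 < res.p < 0.8

    def test_swapping_periods_flips_z(self, rng):
        pre = rng.random(15)
        post = rng.random(18) + 0.2
        a = compare_periods(vs(pre), vs(post, "sleepPost"))
        b = compare_periods(vs(post), vs(pre, "sleepPost"))
        assert a.z == pytest.approx(-b.z, abs=1e-12)

    def test_constant_data_degenerate(self):
        res = compare_periods(vs([0.2, 0.2]), vs([0.2, 0.2, 0.2], "sleepPost"))
        assert res.degenerate and res.z == 0.0 and res.p == 1.0

    @given(
        st.lists(st.integers(0, 10), min_size=2, max_size=30),
        st.lists(st.integers(0, 10), min_size=2, max_size=30),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_effect_size_identity(self, a, b):
        pre, post = np.array(a) / 10.0, np.array(b) / 10.0
        res = compare_periods(vs(pre), vs(post, "sleepPost"))
        assert res.r == pytest.approx(res.z / np.sqrt(len(a) + len(b)), abs=1e-12)
        assert 0.0 <= res.p <= 1.0

    def test_z_negative_when_post_larger(self, rng):
        pre = rng.random(30) * 0.2
        post = rng.random(30) * 0.2 + 0.4
        res = compare_periods(vs(pre), vs(post, "sleepPost"))
        assert res.z < -3 and res.p < 0.025 and res.significant


class TestVoteProportions:
    def test_zero_and_partial_counts(self):
        votes = np.array([False] * 199 + [True] * 100 + [False] * 99)
        epochs = np.array([0] * 199 + [1] * 199)
        series = vote_proportions(votes, epochs, "sleepPre")
        assert series.proportions[0] == 0.0
        assert series.proportions[1] == pytest.approx(100 / 199)
        assert series.n_accepted.tolist() == [199, 199]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            vote_proportions(np.array([]), np.array([]), "sleepPre")


class TestGroupLevel:
    def test_identical_medians(self):
        res = group_level([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["degenerate"]

    def test_constant_nonzero_differences_flagged(self):
        res = group_level([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res["degenerate"] and res["p"] == 0.0

    def test_closed_form_three_pairs(self):
        pre = np.array([0.2, 0.4, 0.3])
        post = np.array([0.5, 0.5, 0.6])
        d = pre - post
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        res = group_level(pre, post)
        assert res["t"] == pytest.approx(t_manual)
        assert res["df"] == 2

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_level([0.1], [0.2])


class TestReactivationIndex:
    def test_quoted_arithmetic(self):
        pre = vs([0.1] * 5)
        post = VoteSeries("sleepPost", np.arange(60), np.full(60, 0.24), np.full(60, 199))
        # delta median 0.14 x 60 post epochs
        assert reactivation_index(pre, post) == pytest.approx(8.4)

    def test_perfectly_linear_correlation(self):
        idx = np.array([1.0, 2.0, 3.0, 4.0])
        out = reactivation_correlation(idx, 2.0 * idx + 1.0)
        assert out["performance"]["r"] == pytest.approx(1.0)

    def test_hand_computed_pearson(self, rng):
        x = rng.random(5)
        y = rng.random(5)
        r_manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        out = reactivation_correlation(x, y, elapsed_minutes=rng.random(5) * 60)
        assert out["performance"]["r"] == pytest.approx(r_manual)
        assert "elapsed_time" in out

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            reactivation_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


def make_log(block_durations: dict, reps=8):
    rows = []
    for block, dur in block_durations.items():
        for rep in range(reps):
            rows.append({"block": block, "repetition": rep, "duration": dur, "correct": True})
    return pd.DataFrame(rows)


class TestPerformanceSummary:
    def test_flat_durations(self):
        log = make_log({b: 2.0 for b in range(1, 14)})
        summ = performance_summary(log)
        assert summ.excluded_pct == 0.0
        assert summ.improvement_pct == pytest.approx(0.0)
        assert summ.performance_index == pytest.approx(0.0)
        assert summ.normalized["normalized"].mean() == pytest.approx(1.0)

    def test_outlier_rule_arithmetic(self):
        # durations {1,1,1,1,100}: mean 20.8, SD ~44.3 -> threshold ~153.7
        dur = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        thresh = dur.mean() + 3 * dur.std(ddof=1)
        assert 100.0 <= thresh  # the extreme value is retained by the rule
        log = pd.DataFrame(
            {"block": [2, 3, 9, 10, 12, 13], "repetition": range(6),
             "duration": [1.0, 1.0, 1.0, 1.0, 100.0, 1.0], "correct": True}
        )
        pooled = log["duration"]
        assert 100.0 <= pooled.mean() + 3 * pooled.std(ddof=1)
        summ = performance_summary(log)
        assert summ.excluded_pct == 0.0
        assert summ.n_accepted == 6

    def test_exclusion_fires_above_threshold(self):
        base = {b: 2.0 for b in range(1, 14)}
        log = make_log(base, reps=20)
        noise = np.random.default_rng(0).normal(0, 0.05, size=len(log))
        log["duration"] = log["duration"] + noise
        log.loc[0, "duration"] = 50.0  # gross outlier
        summ = performance_summary(log)
        assert summ.excluded_pct > 0.0

    def test_printed_block_means_improvement(self):
        log = make_log({1: 1.30, 2: 1.125, 3: 1.125, 4: 1.05, 5: 1.0, 6: 0.98,
                        7: 0.96, 8: 0.94, 9: 0.922, 10: 0.922, 11: 0.9,
                        12: 0.892, 13: 0.892})
        summ = performance_summary(log)
        assert round(summ.improvement_pct, 2) == 18.04

    def test_missing_contrast_block_error(self):
        log = make_log({1: 2.0, 2: 2.0, 3: 2.0, 9: 2.0, 10: 2.0})  # no retest
        with pytest.raises(ValueError, match="12:13"):
            performance_summary(log)


def test_group_anova_smoke(rng):
    from gammareplay import SynthConfig, generate_tapping_log

    summaries = []
    for seed in range(5):
        log = generate_tapping_log(SynthConfig(seed=seed))
        summaries.append(performance_summary(log))
    res = group_performance_anova(summaries)
    assert np.isfinite(res["F"]) and 0.0 <= res["p_gg"] <= 1.0
    assert "2:3 vs 9:10" in res["posthoc"]


class TestSpectrumQC:
    def test_white_noise_flat_and_tone_peak(self, rng):
        fs = 250.0
        white = Recording(rng.standard_normal((2, int(60 * fs))), fs, "rest", ["a", "b"])
        t = np.arange(int(60 * fs)) / fs
        tone = Recording(
            (np.sin(2 * np.pi * 10.0 * t) + 0.01 * rng.standard_normal(len(t)))[None, :],
        fs, "task", ["a"])
        out = spectrum_qc({"rest": white, "task": tone}, segment_sec=30.0)
        flat = out["rest"]["all"]
        assert flat.max() - flat.min() < 0.5  # log10 units
        freqs = out["freqs"]
        peak = freqs[np.argmax(out["task"]["all"])]
        assert peak == pytest.approx(10.0, abs=0.5)

    def test_sleep_exceeds_task_below_4hz(self, fast_bundle):
        out = spectrum_qc(
            {
                "task": fast_bundle.recordings["task"],
                "sleepPre": fast_bundle.recordings["sleepPre"],
            }
        )
        sel = out["freqs"] < 4.0
        assert np.all(out["sleepPre"]["all"][sel] > out["task"]["all"][sel])


class TestHypnogramSummary:
    def test_contiguous_sleep(self):
        out = hypnogram_summary(["N2"] * 76)
        assert out["spt_min"] == 38.0

    def test_mixed_stages_counts(self):
        out = hypnogram_summary(["W", "N2", "N2", "W", "N2"])
        assert out["spt_min"] == 2.0
        assert out["nrem_min"] == 1.5

    def test_all_wake_error(self):
        with pytest.raises(ValueError):
            hypnogram_summary(["W", "W"])

    def test_n1_optional(self):
        out = hypnogram_summary(["N1", "N2"], include_n1=True)
        assert out["nrem_min"] == 1.0
        assert hypnogram_summary(["N1", "N2"])["nrem_min"] == 0.5
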