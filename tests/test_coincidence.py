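"""Rasters, coincidence counting, channel classification and traces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohfo import coincidence as coin
from cohfo import sim


def events_frame(rows):
    """rows: iterable of (channel, peak_time)."""
    return pd.DataFrame([{"subject": "S01", "channel": c, "peak_time": t}
                         for c, t in rows])


def brute_force_cohfo_counts(matrix, halfwidth=5):
    """Exhaustive O(C^2 B^2) pair scan: the coincidence oracle."""
    m = np.asarray(matrix)
    n_ch, n_bins = m.shape
    flagged = np.zeros_like(m, dtype=bool)
    for i in range(n_ch):
        for t in range(n_bins):
            if not m[i, t]:
                continue
            for j in range(n_ch):
                if j == i:
                    continue
                for u in range(max(0, t - halfwidth),
                               min(n_bins, t + halfwidth + 1)):
                    if m[j, u]:
                        flagged[i, t] = True
    return flagged.sum(axis=0)


class TestBuildRaster:
    def test_half_open_bin_arithmetic(self):
        ev = events_frame([("A1", 10.005)])
        rasters = coin.build_raster(ev, [10.0], ["A1", "A2"])
        assert rasters[0].matrix[0, 150] == 1
        assert rasters[0].matrix.sum() == 1

    def test_no_events_all_zero(self):
        ev = events_frame([])
        ev = pd.DataFrame(columns=["subject", "channel", "peak_time"])
        rasters = coin.build_raster(ev, [10.0], ["A1"])
        assert not rasters[0].matrix.any()

    def test_two_events_one_bin_binarized(self):
        ev = events_frame([("A1", 10.001), ("A1", 10.003)])
        rasters = coin.build_raster(ev, [10.0], ["A1"])
        assert rasters[0].matrix[0, 150] == 1

    def test_truncated_trials_excluded(self):
        ev = events_frame([("A1", 1.0)])
        rasters = coin.build_raster(ev, [1.0, 50.0], ["A1"], duration=52.0)
        assert len(rasters) == 1
        assert rasters[0].align_time == 50.0

    def test_empty_align_times(self):
        assert coin.build_raster(events_frame([("A1", 1.0)]), [], ["A1"]) == []


class TestCountCohfo:
    def test_same_bin_pair(self):
        m = np.zeros((2, 300), dtype=int)
        m[0, 100] = m[1, 100] = 1
        counts = coin.count_cohfo(m)
        assert counts[100] == 2
        assert counts.sum() == 2

    def test_six_bins_apart_not_coincident(self):
        m = np.zeros((2, 300), dtype=int)
        m[0, 100] = m[1, 106] = 1
        assert not coin.count_cohfo(m).any()

    def test_five_bins_apart_coincident(self):
        m = np.zeros((2, 300), dtype=int)
        m[0, 100] = m[1, 105] = 1
        counts = coin.count_cohfo(m)
        assert counts[100] == 1 and counts[105] == 1

    def test_single_channel_all_zero(self):
        m = np.ones((1, 50), dtype=int)
        assert not coin.count_cohfo(m).any()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(12, 60), st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle(self, n_ch, n_bins, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((n_ch, n_bins)) < 0.1).astype(int)
        np.testing.assert_array_equal(coin.count_cohfo(m),
                                      brute_force_cohfo_counts(m))

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = (rng.random((6, 80)) < 0.1).astype(int)
        perm = rng.permutation(6)
        np.testing.assert_array_equal(coin.count_cohfo(m),
                                      coin.count_cohfo(m[perm]))


class TestPairwiseCorrelation:
    def test_identical_rows(self):
        rng = np.random.default_rng(1)
        row = (rng.random(100) < 0.2).astype(float)
        r = coin.pairwise_correlation(np.vstack([row, row]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_complement_rows(self):
        rng = np.random.default_rng(2)
        row = (rng.random(100) < 0.5).astype(float)
        r = coin.pairwise_correlation(np.vstack([row, 1 - row]))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_sparse_null(self):
        rng = np.random.default_rng(3)
        m = (rng.random((10, 3000)) < 0.05).astype(float)
        r = coin.pairwise_correlation(m)
        off = r[np.triu_indices(10, 1)]
        assert (np.abs(off) < 0.1).mean() >= 0.99

    def test_zero_variance_channel_flagged(self):
        m = np.vstack([np.zeros(50), np.random.default_rng(4).random(50)])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = coin.pairwise_correlation(m)
        assert r[0, 1] == 0.0 and r[0, 0] == 1.0


class TestClassifyAndSort:
    @staticmethod
    def corr_from_scores(scores):
        n = len(scores)
        r = np.eye(n)
        for i, s in enumerate(scores):
            j = (i + 1) % n
            r[i, j] = max(r[i, j], s)
            r[j, i] = r[i, j]
        return r

    def test_threshold_rule(self):
        r = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.6], [0.2, 0.6, 1.0]])
        order, cls, scores = coin.classify_and_sort(r, ["a", "b", "c"], 0.5)
        np.testing.assert_array_equal(scores, [0.9, 0.9, 0.6])
        assert list(cls) == [True, True, True]
        order2, cls2, _ = coin.classify_and_sort(r, ["a", "b", "c"], 0.7)
        assert list(cls2) == [True, True, False]

    def test_tie_break_by_label(self):
        r = np.full((3, 3), 0.4)
        np.fill_diagonal(r, 1.0)
        order, _, _ = coin.classify_and_sort(r, ["c", "a", "b"], 0.5)
        assert [["c", "a", "b"][i] for i in order] == ["a", "b", "c"]

    def test_descending_scores(self):
        r = np.array([[1.0, 0.2, 0.9], [0.2, 1.0, 0.6], [0.9, 0.6, 1.0]])
        order, _, scores = coin.classify_and_sort(r, ["a", "b", "c"], 0.5)
        assert list(scores[order]) == sorted(scores, reverse=True)


class TestCohfoProbability:
    def test_normalization_contract(self):
        rng = np.random.default_rng(5)
        prob, per_sec, flags = coin.cohfo_probability(
            {"S01": rng.poisson(2.0, size=(7, 300)).astype(float)})
        assert prob.sum() == pytest.approx(1.0, abs=1e-9)
        assert not flags

    def test_uniform_counts(self):
        prob, per_sec, _ = coin.cohfo_probability({"S01": np.ones((4, 300))})
        np.testing.assert_allclose(prob, 1.0 / 300)
        np.testing.assert_allclose(per_sec, 100.0)  # 1/bin * 100 per second

    def test_scale_invariance_of_probability(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(1.0, size=(5, 60)).astype(float)
        p1, _, _ = coin.cohfo_probability({"S01": counts})
        p2, _, _ = coin.cohfo_probability({"S01": 2.0 * counts})
        np.testing.assert_allclose(p1, p2)

    def test_per_second_is_rate_over_binwidth(self):
        counts = np.zeros((1, 300))
        counts[0, 10] = 3.0
        _, per_sec, _ = coin.cohfo_probability({"S01": counts})
        assert per_sec[10] == pytest.approx(300.0)  # 3 per bin * 100

    def test_all_zero_flagged(self):
        prob, _, flags = coin.cohfo_probability({"S01": np.zeros((2, 10))})
        assert flags and not prob.any()


def simulate_events(seed, **profile_kw):
    profile = sim.RateProfile(baseline_rate=1.2, **profile_kw)
    groups = [sim.CoincidenceGroupSpec(members=tuple(range(0, 6)),
                                       jitter_sd=0.002,
                                       participation_prob=0.95)]
    cfg = sim.SimConfig(n_subjects=2, n_channels=10, n_lists=3, fs=1000.0,
                        seed=seed, recall_prob=0.4,
                        burst_freq_range=(80.0, 200.0),
                        coincidence_groups=groups, rate_profile=profile)
    _, task, truth, _ = sim.simulate_dataset(cfg, synthesize_signal=False)
    names = sim.channel_names(cfg.n_channels)
    events = pd.DataFrame({
        "subject": truth.subject,
        "channel": [names[int(c)] for c in truth.channel],
        "peak_time": truth.center_time,
    })
    return events, task, cfg


class TestSessionTraces:
    def test_identical_strata_identical_traces(self):
        """Two strata resolving to the same align times give identical
        traces (here: every word recalled, so WORD == WORD_RECALLED)."""
        events, task, cfg = simulate_events(seed=30)
        task = task.copy()
        task.loc[task.trial_type == "WORD", "recalled"] = True
        out = coin.session_traces(events, task,
                                  strata=("WORD", "WORD_RECALLED"),
                                  duration=cfg.duration)
        t = out.table
        for cls in ("correlated", "non-correlated"):
            a = t[(t.condition == "WORD") & (t.channel_class == cls)]
            b = t[(t.condition == "WORD_RECALLED") & (t.channel_class == cls)]
            np.testing.assert_allclose(a.probability.to_numpy(),
                                       b.probability.to_numpy())

    def test_planted_recall_peak_recovered(self):
        from cohfo import experiments
        res = experiments.profile_recovery(seed=31)
        assert abs(res["peak_offset_bins"]) <= 5
        assert res["dip_detected"]

    def test_contrast_subsequent_memory_effect(self):
        """Higher encode gain for recalled words shows up in the recalled
        trace during word display."""
        events, task, cfg = simulate_events(seed=32)
        # plant the effect: extra events during display of recalled words
        extra = []
        words = task[(task.trial_type == "WORD") & task.recalled]
        rng = np.random.default_rng(0)
        for r in words.itertuples():
            for ch in ("A1", "A2", "A3", "A4"):
                extra.append({"subject": r.subject, "channel": ch,
                              "peak_time": r.onset
                              + rng.uniform(0.0, r.duration)})
        events2 = pd.concat([events, pd.DataFrame(extra)], ignore_index=True)
        out = coin.contrast_traces(events2, task, "recalled-vs-forgotten",
                                   duration=cfg.duration)
        t = out.table
        display = (t.bin_center_s >= 0.0) & (t.bin_center_s < 1.5)
        rec = t[(t.condition == "WORD_RECALLED")
                & (t.channel_class == "correlated") & display]
        forg = t[(t.condition == "WORD_FORGOTTEN")
                 & (t.channel_class == "correlated") & display]
        assert rec.per_second_rate.mean() > forg.per_second_rate.mean()

    def test_cue_locked_planted_peak(self):
        """Bursts planted at cue + 0.2 s produce a trace peak there."""
        cfg = sim.SimConfig(n_subjects=1, n_channels=6, n_lists=2, fs=1000.0,
                            seed=33, burst_freq_range=(80.0, 200.0))
        task = sim.generate_task_schedule(cfg, task="pal",
                                          rng=np.random.default_rng(33))
        task.insert(0, "subject", "S01")
        cues = task[task.trial_type == "CUE"]
        rng = np.random.default_rng(1)
        rows = []
        for r in cues.itertuples():
            for ch in ("A1", "A2", "A3", "A4"):
                rows.append({"subject": "S01", "channel": ch,
                             "peak_time": r.onset + 0.2
                             + rng.normal(0.0, 0.002)})
        # sparse background so correlation classes are defined
        for ch in ("A1", "A2", "A3", "A4", "A5", "A6"):
            for t0 in rng.uniform(0, cfg.duration, 10):
                rows.append({"subject": "S01", "channel": ch, "peak_time": t0})
        events = pd.DataFrame(rows)
        out = coin.contrast_traces(events, task,
                                   "cue-locked-vs-vocalization-locked",
                                   duration=cfg.duration)
        t = out.table
        cue = t[(t.condition == "CUE") & (t.channel_class == "correlated")]
        peak_center = cue.bin_center_s.to_numpy()[
            cue.probability.to_numpy().argmax()]
        assert abs(peak_center - 0.2) <= 0.05

    def test_unknown_contrast_rejected(self):
        events, task, _ = simulate_events(seed=34)
        with pytest.raises(ValueError, match="unknown contrast"):
            coin.contrast_traces(events, task, "nope")
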