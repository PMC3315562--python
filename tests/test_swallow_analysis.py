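"""Swallow segmentation, CSS/NFP/NFN scoring and DFA."""

import numpy as np
import pytest

import splinedetrend as sd
from splinedetrend.swallow_analysis import (
    before_after_study,
    dfa_alpha,
    score_segmentation,
    segment_swallows,
)


class TestSegmentSwallows:
    def test_all_zero_signal_yields_no_events(self):
        assert segment_swallows(np.zeros(5000), 1000.0) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_false_alarm_rate_on_white_noise(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40_000)
        events = segment_swallows(x, 1000.0, threshold_k=6.0)
        assert len(events) <= 1

    def test_detects_true_events_without_trend(self):
        cfg = sd.SyntheticConfig(
            duration_s=40.0, snr_db=20.0,
            trend_amp_range={"ap": (0.0, 0.0), "si": (0.0, 0.0)})
        rec, truth = sd.gen_recording(cfg, np.random.default_rng(3))
        found = segment_swallows(rec.ap, cfg.f_s)
        score = score_segmentation(truth.events, found)
        assert score.css >= 4

    def test_intervals_disjoint_and_sorted(self, short_recording):
        cfg, rec, _ = short_recording
        events = segment_swallows(rec.si, cfg.f_s)
        for (a0, b0), (a1, b1) in zip(events, events[1:]):
            assert b0 <= a1
        assert all(a < b for a, b in events)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_swallows(np.zeros(50), 1000.0, window_s=1.0)


class TestScoreSegmentation:
    def test_exact_match(self):
        ev = [(0.0, 1.0), (2.0, 3.0)]
        s = score_segmentation(ev, ev)
        assert (s.tns, s.css, s.nfp, s.nfn) == (2, 2, 0, 0)

    def test_empty_detection(self):
        s = score_segmentation([(0.0, 1.0), (2.0, 3.0)], [])
        assert (s.css, s.nfn, s.nfp) == (0, 2, 0)

    def test_ninety_percent_rule_excludes_85_percent_capture(self):
        s = score_segmentation([(0.0, 1.0)], [(0.15, 1.0)])
        assert (s.css, s.nfn) == (0, 1)

    def test_ninety_percent_rule_accepts_95_percent_capture(self):
        s = score_segmentation([(0.0, 1.0)], [(0.05, 1.0)])
        assert (s.css, s.nfn) == (1, 0)

    def test_non_overlapping_detection_is_false_positive(self):
        s = score_segmentation([(0.0, 1.0)], [(0.0, 1.0), (5.0, 6.0)])
        assert (s.css, s.nfp) == (1, 1)

    def test_fragmented_cover_counts_jointly(self):
        s = score_segmentation([(0.0, 1.0)], [(0.0, 0.5), (0.52, 1.0)])
        assert s.css == 1

    def test_count_conservation_on_random_layouts(self, rng):
        for _ in range(20):
            k = rng.integers(0, 6)
            starts = np.sort(rng.uniform(0, 30, k))
            true_ev = [(s, s + rng.uniform(0.2, 1.0)) for s in starts[::2]]
            det_ev = [(s + rng.uniform(-0.1, 0.1), s + rng.uniform(0.3, 1.2))
                      for s in starts[1::2]]
            det_ev = [e for i, e in enumerate(det_ev)
                      if i == 0 or e[0] > det_ev[i - 1][1]]
            s = score_segmentation(true_ev, det_ev)
            assert s.css + s.nfn == s.tns

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            score_segmentation([(0.0, 2.0), (1.0, 3.0)], [])


class TestDfa:
    def test_white_noise_benchmark(self):
        x = np.random.default_rng(7).normal(size=20_000)
        assert dfa_alpha(x).alpha == pytest.approx(0.5, abs=0.06)

    def test_random_walk_benchmark(self):
        x = np.cumsum(np.random.default_rng(8).normal(size=20_000))
        assert dfa_alpha(x).alpha == pytest.approx(1.5, abs=0.12)

    def test_fluctuation_positive_and_monotone_scales(self, rng):
        res = dfa_alpha(rng.normal(size=5000))
        assert np.all(res.fluctuation > 0)
        assert np.all(np.diff(res.scales) > 0)

    def test_scale_constraints_enforced(self, rng):
        x = rng.normal(size=1000)
        with pytest.raises(ValueError):
            dfa_alpha(x, scales=[2, 50])       # below detrend_order + 2
        with pytest.raises(ValueError):
            dfa_alpha(x, scales=[10, 500])     # above length / 4


@pytest.fixture(scope="module")
def strong_trend_batch():
    cfg = sd.SyntheticConfig(
        duration_s=40.0, snr_db=10.0,
        trend_amp_range={"ap": (0.0, 2.0), "si": (0.0, 2.0)})
    return [sd.gen_recording(cfg, np.random.default_rng(500 + i))
            for i in range(8)]


class TestBeforeAfterStudy:
    def test_detrending_reduces_segmentation_errors(self, strong_trend_batch):
        _, summary = before_after_study(strong_trend_batch)
        assert summary["after"]["nfn"] <= summary["before"]["nfn"]
        assert summary["after"]["nfp"] <= summary["before"]["nfp"]
        assert summary["after"]["css"] >= summary["before"]["css"]

    def test_detrending_reduces_persistence(self, strong_trend_batch):
        _, summary = before_after_study(strong_trend_batch)
        for axis in ("ap", "si"):
            assert (summary["after"]["mean_alpha"][axis]
                    < summary["before"]["mean_alpha"][axis])

    def test_trendless_batch_segmentation_neutral(self):
        """Without a trend, detrending leaves segmentation statistically
        unchanged (alpha still shifts slightly: removal of the low band is
        a high-pass operation even on trendless noise)."""
        from splinedetrend.evaluation import mann_whitney
        cfg = sd.SyntheticConfig(
            duration_s=20.0, snr_db=10.0,
            trend_amp_range={"ap": (0.0, 0.0), "si": (0.0, 0.0)})
        batch = [sd.gen_recording(cfg, np.random.default_rng(900 + i))
                 for i in range(6)]
        table, summary = before_after_study(batch)
        errs = {stage: (table[table.stage == stage].nfp
                        + table[table.stage == stage].nfn).to_numpy(float)
                for stage in ("before", "after")}
        assert mann_whitney(errs["before"], errs["after"]) > 0.05
        assert summary["before"]["css"] == summary["after"]["css"]
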