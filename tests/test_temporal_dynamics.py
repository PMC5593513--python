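"""Epoch selection, concatenation/truncation bookkeeping, and the sliding
windows whose arithmetic the study design fixes (600/100/50 -> 11 windows)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepfc import synthetic_data as sd
from sleepfc.connectivity_index import ci_from_run
from sleepfc.containers import SpatialPattern
from sleepfc.synthetic_data import Hypnogram
from sleepfc.temporal_dynamics import (
    concatenate_and_truncate,
    longest_segment,
    n_windows,
    select_epochs,
    sliding_ci,
    sliding_roi_fc,
    window_robustness,
)

from conftest import make_run, toy_run


def hyp(*bouts):
    labels = []
    for stage, n in bouts:
        labels.extend([stage] * n)
    return Hypnogram(np.array(labels, dtype=object))


class TestSelectEpochs:
    def test_all_n2_single_epoch(self):
        es = select_epochs(hyp(("N2", 300)), "N2")
        assert es.intervals == [(0, 300)]

    def test_strictly_greater_than_min_len(self):
        es = select_epochs(hyp(("N2", 50), ("wake", 5), ("N2", 51)), "N2",
                           min_len=50)
        assert es.intervals == [(55, 106)]

    def test_artifact_breaks_segments(self):
        es = select_epochs(
            hyp(("N2", 60), ("artifact", 1), ("N2", 60)), "N2", min_len=50)
        assert es.intervals == [(0, 60), (61, 121)]
        # even when artifact is requested it cannot join segments
        es2 = select_epochs(
            hyp(("N2", 60), ("artifact", 1), ("N2", 60)), {"N2", "artifact"},
            min_len=50)
        assert es2.intervals == [(0, 60), (61, 121)]

    def test_planted_alternating_plan_recovered_exactly(self):
        plan = [("wake", 60), ("N2", 60)] * 3
        hypnogram = sd.simulate_hypnogram(360, plan, seed=0, jitter=0.0)
        es = select_epochs(hypnogram, "N2", min_len=50)
        assert es.intervals == [(60, 120), (180, 240), (300, 360)]

    def test_nothing_qualifying_is_empty_and_flagged(self):
        with pytest.warns(RuntimeWarning, match="no epochs"):
            es = select_epochs(hyp(("wake", 100)), "N2")
        assert len(es) == 0 and es.n_volumes == 0

    def test_epoch_union_and_complement_cover_hypnogram(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["wake", "N2", "SWS", "artifact"], size=400)
        hypnogram = Hypnogram(labels)
        es = select_epochs(hypnogram, "N2", min_len=0)
        covered = np.zeros(400, dtype=bool)
        for s, e in es.intervals:
            assert np.all(labels[s:e] == "N2")
            covered[s:e] = True
        assert not np.any(labels[covered] != "N2")
        # maximality: neighbors of each epoch are not N2
        for s, e in es.intervals:
            if s > 0:
                assert labels[s - 1] != "N2"
            if e < 400:
                assert labels[e] != "N2"


class TestLongestSegment:
    def test_tie_broken_by_earliest_start(self):
        h = hyp(("N2", 40), ("wake", 1), ("N2", 90), ("wake", 1), ("N2", 90))
        assert longest_segment(h, "N2") == (41, 131)

    def test_single_bout(self):
        assert longest_segment(hyp(("wake", 5), ("N2", 10)), "N2") == (5, 15)

    def test_none_qualifying(self):
        assert longest_segment(hyp(("wake", 5)), "N2") is None

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(9)
        for seed in range(20):
            labels = np.random.default_rng(seed).choice(
                ["wake", "N2"], size=120)
            h = Hypnogram(labels)
            got = longest_segment(h, "N2")
            best = None
            for s in range(120):
                for e in range(s + 1, 121):
                    if np.all(labels[s:e] == "N2"):
                        if best is None or (e - s) > (best[1] - best[0]):
                            best = (s, e)
            assert got == best


class TestConcatenateAndTruncate:
    @staticmethod
    def runs(t_msl, t_ctl):
        out = {}
        for cond, t in (("MSL", t_msl), ("CTL", t_ctl)):
            data = np.arange(t, dtype=float)[None, :].repeat(4, axis=0)
            out[cond] = toy_run(data, condition=cond)
        return out

    def test_cap_at_600(self):
        runs = self.runs(700, 700)
        es = {c: select_epochs(hyp(("N2", 700)), "N2") for c in runs}
        out = concatenate_and_truncate(runs, es, cap=600)
        assert out["MSL"].n_volumes == 600 and out["CTL"].n_volumes == 600

    def test_min_rule_across_conditions(self):
        runs = self.runs(650, 500)
        es = {c: select_epochs(hyp(("N2", runs[c].n_volumes)), "N2")
              for c in runs}
        out = concatenate_and_truncate(runs, es, cap=600)
        assert out["MSL"].n_volumes == 500 and out["CTL"].n_volumes == 500

    def test_concatenation_preserves_within_epoch_order(self):
        runs = self.runs(300, 300)
        bouts = hyp(("wake", 20), ("N2", 80), ("wake", 40), ("N2", 160))
        es = {c: select_epochs(bouts, "N2") for c in runs}
        out = concatenate_and_truncate(runs, es, cap=600)
        expected = np.concatenate([np.arange(20, 100), np.arange(140, 300)])
        assert np.allclose(out["MSL"].data[0, 0, 0], expected)


class TestWindows:
    @given(t=st.integers(1, 2000), w=st.integers(1, 2000), s=st.integers(1, 300))
    @settings(deadline=None, max_examples=100)
    def test_n_windows_formula(self, t, w, s):
        if t < w:
            with pytest.raises(ValueError):
                n_windows(t, w, s)
        else:
            n = n_windows(t, w, s)
            assert n == (t - w) // s + 1
            # every window fits; one more step would not
            assert (n - 1) * s + w <= t
            assert n * s + w > t

    def test_study_design_arithmetic(self):
        assert n_windows(600, 100, 50) == 11

    def test_full_length_window_equals_full_series_ci(self, small_run,
                                                      pattern_pair):
        _, co = pattern_pair
        traj = sliding_ci(small_run, co, window=small_run.n_volumes, step=1)
        assert traj.n_windows == 1
        assert traj.values[0] == pytest.approx(ci_from_run(small_run, co).ci,
                                               rel=1e-12)

    def test_stationary_series_windows_near_full_ci(self, small_run,
                                                    pattern_pair):
        _, co = pattern_pair
        traj = sliding_ci(small_run, co, window=50, step=25)
        full = ci_from_run(small_run, co).ci
        assert np.mean(traj.values) == pytest.approx(full, rel=0.25)


class TestSlidingRoiFC:
    def test_targets_identical_to_roi_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=120)
        data = np.tile(series, (6, 1))
        run = toy_run(data)
        roi = np.zeros((1, 1, 6), dtype=bool)
        roi[0, 0, :2] = True
        pattern_mask = np.ones((1, 1, 6), dtype=bool)
        traj = sliding_roi_fc(run, roi, pattern_mask, window=40, step=20)
        assert np.allclose(traj.values, 1.0)

    def test_independent_targets_near_zero(self):
        rng = np.random.default_rng(1)
        n_targets, w = 30, 100
        data = rng.normal(size=(n_targets + 2, w))
        run = toy_run(data)
        roi = np.zeros((1, 1, n_targets + 2), dtype=bool)
        roi[0, 0, :2] = True
        pattern_mask = np.ones((1, 1, n_targets + 2), dtype=bool)
        traj = sliding_roi_fc(run, roi, pattern_mask, window=w, step=w)
        assert abs(traj.values[0]) < 3.0 / np.sqrt(w)

    def test_matches_bruteforce_mean_correlation(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(5, 60))
        run = toy_run(data)
        roi = np.zeros((1, 1, 5), dtype=bool)
        roi[0, 0, 0] = True
        pattern_mask = np.ones((1, 1, 5), dtype=bool)
        traj = sliding_roi_fc(run, roi, pattern_mask, window=30, step=30)
        for i, s in enumerate((0, 30)):
            rs = []
            for v in range(1, 5):
                rs.append(np.corrcoef(data[0, s:s + 30], data[v, s:s + 30])[0, 1])
            assert traj.values[i] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_no_targets_after_exclusion_rejected(self):
        run = toy_run(np.random.default_rng(3).normal(size=(4, 50)))
        roi = np.ones((1, 1, 4), dtype=bool)
        with pytest.raises(ValueError, match="target"):
            sliding_roi_fc(run, roi, roi, window=25, step=25)


class TestWindowRobustness:
    def test_time_reversal_swaps_first_and_last(self, pattern_pair):
        la, co = pattern_pair
        run = make_run({"consolidated": np.linspace(0.2, 1.0, 200)}, seed=31,
                       T=200)
        rev = run.with_data(run.data[..., ::-1].copy())
        fwd = window_robustness(run, co, sizes=[50, 100])
        bwd = window_robustness(rev, co, sizes=[50, 100])
        assert np.allclose(fwd["first_ci"], bwd["last_ci"], rtol=1e-10)
        assert np.allclose(fwd["last_ci"], bwd["first_ci"], rtol=1e-10)

    def test_oversized_windows_skipped_with_warning(self, small_run,
                                                    pattern_pair):
        _, co = pattern_pair
        with pytest.warns(UserWarning, match="skipped"):
            tab = window_robustness(small_run, co, sizes=[100, 9999])
        assert tab["size"].tolist() == [100]

    def test_ramping_amplitude_raises_late_ci(self, pattern_pair):
        la, co = pattern_pair
        run = make_run({"consolidated": np.linspace(0.2, 1.4, 600)}, seed=33,
                       T=600)
        tab = window_robustness(run, co, sizes=range(50, 301, 50))
        assert (tab["last_ci"] > tab["first_ci"]).all()
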