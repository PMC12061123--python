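import numpy as np
import pytest
from scipy import stats

from affpriming import CONGRUENT, EpochSet, INCONGRUENT
from affpriming.channels import CHANNELS_32
from affpriming.erp import (ERPSet, RunningTestResult, participant_erps,
                            running_ttest, select_longest_window,
                            summarize_window, windowed_amplitude)

SFREQ = 250.0
TIMES = np.arange(0, 251) / SFREQ


def _epochs(data, labels):
    return EpochSet(data=data, times=np.arange(-25, 251) / SFREQ, sfreq=SFREQ,
                    ch_names=CHANNELS_32[:data.shape[1]], labels=np.asarray(labels))


def _erpset(cong, incong, ch_names=None):
    ch_names = ch_names or CHANNELS_32[:cong.shape[1]]
    return ERPSet(cong=cong, incong=incong, times=TIMES[:cong.shape[2]],
                  sfreq=SFREQ, ch_names=list(ch_names))


class TestParticipantERPs:
    def test_single_trial_erp_is_the_trial(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 3, 276))
        ep = _epochs(data, [CONGRUENT, INCONGRUENT])
        erps = participant_erps([ep])
        mask = ep.times >= 0
        assert np.array_equal(erps.cong[0], data[0][:, mask])
        assert np.array_equal(erps.incong[0], data[1][:, mask])

    def test_analysis_window_spans_first_second(self):
        ep = _epochs(np.zeros((2, 3, 276)), [CONGRUENT, INCONGRUENT])
        erps = participant_erps([ep])
        assert erps.times[0] == 0.0
        assert np.isclose(erps.times[-1], 1.0)

    def test_missing_condition_excludes_participant(self):
        good = _epochs(np.zeros((2, 3, 276)), [CONGRUENT, INCONGRUENT])
        bad = _epochs(np.zeros((2, 3, 276)), [CONGRUENT, CONGRUENT])
        erps = participant_erps([good, bad, good])
        assert erps.n_participants == 2
        assert erps.excluded[0]["participant"] == 1

    def test_sem_matches_brute_force(self):
        rng = np.random.default_rng(1)
        cong = rng.standard_normal((7, 4, 100))
        incong = rng.standard_normal((7, 4, 100))
        erps = _erpset(cong, incong)
        sem = erps.sem_diff()
        d = cong - incong
        ci, ti = 2, 50
        vals = d[:, ci, ti]
        assert np.isclose(sem[ci, ti], np.std(vals, ddof=1) / np.sqrt(7), atol=1e-12)

    def test_grand_diff_linearity(self):
        """Mean of differences equals difference of grand means."""
        rng = np.random.default_rng(2)
        cong = rng.standard_normal((6, 3, 60))
        incong = rng.standard_normal((6, 3, 60))
        erps = _erpset(cong, incong)
        assert np.allclose(erps.grand_diff(),
                           erps.grand(CONGRUENT) - erps.grand(INCONGRUENT),
                           atol=1e-12)


class TestRunningTTest:
    def test_identical_conditions_yield_null(self):
        x = np.random.default_rng(3).standard_normal((5, 2, 40))
        res = running_ttest(_erpset(x, x.copy()))
        assert np.all(res.t_trace == 0.0)
        assert np.all(res.p_trace == 1.0)
        assert res.corrected is False

    def test_point_matches_scipy_paired_ttest(self):
        rng = np.random.default_rng(4)
        cong = rng.standard_normal((9, 3, 30))
        incong = rng.standard_normal((9, 3, 30))
        res = running_ttest(_erpset(cong, incong))
        ci, ti = 1, 17
        ref = stats.ttest_rel(cong[:, ci, ti], incong[:, ci, ti])
        assert abs(res.t_trace[ci, ti] - ref.statistic) < 1e-10
        assert abs(res.p_trace[ci, ti] - ref.pvalue) < 1e-10

    def test_constant_nonzero_difference_is_undefined_not_zero(self):
        cong = np.zeros((5, 1, 10)) + 1.0
        incong = np.zeros((5, 1, 10))
        res = running_ttest(_erpset(cong, incong))
        assert np.isnan(res.p_trace).all()

    def test_cohens_d_is_paired(self):
        rng = np.random.default_rng(5)
        cong = rng.standard_normal((8, 2, 20))
        incong = rng.standard_normal((8, 2, 20))
        res = running_ttest(_erpset(cong, incong))
        d = (cong - incong)[:, 0, 5]
        assert np.isclose(res.d_trace[0, 5], d.mean() / d.std(ddof=1))

    def test_needs_three_participants(self):
        x = np.zeros((2, 1, 5))
        with pytest.raises(ValueError):
            running_ttest(_erpset(x, x))


def _result_from_p(p_trace, ch_names):
    p = np.asarray(p_trace, dtype=float)
    return RunningTestResult(t_trace=np.zeros_like(p), p_trace=p,
                             d_trace=np.zeros_like(p),
                             times=TIMES[:p.shape[1]], sfreq=SFREQ,
                             ch_names=list(ch_names), alpha=0.05, n=10)


class TestWindowSelection:
    def test_longest_run_wins_across_electrodes(self):
        p = np.full((2, 30), 0.5)
        p[0, 5:8] = 0.01       # run of 3 on electrode A
        p[1, 10:17] = 0.01     # run of 7 on electrode B
        sel = select_longest_window(_result_from_p(p, ["A", "B"]))
        assert sel.electrode == "B"
        assert np.isclose(sel.length_ms, 7 / SFREQ * 1000)
        assert np.isclose(sel.window_ms[0], TIMES[10] * 1000)
        assert np.isclose(sel.window_ms[1], TIMES[16] * 1000)

    def test_no_subalpha_points_gives_empty_selection(self):
        sel = select_longest_window(_result_from_p(np.full((3, 20), 0.5),
                                                   ["A", "B", "C"]))
        assert sel.empty

    def test_tie_breaks_on_earlier_onset_then_order(self):
        p = np.full((2, 30), 0.5)
        p[1, 4:9] = 0.01
        p[0, 10:15] = 0.01
        sel = select_longest_window(_result_from_p(p, ["A", "B"]))
        assert sel.electrode == "B"          # same length, earlier onset

    def test_nan_breaks_runs(self):
        p = np.full((1, 20), 0.01)
        p[0, 10] = np.nan
        sel = select_longest_window(_result_from_p(p, ["A"]))
        assert np.isclose(sel.length_ms, 10 / SFREQ * 1000)

    def test_min_p_time_inside_window(self):
        p = np.full((1, 30), 0.5)
        p[0, 5:15] = np.linspace(0.04, 0.001, 10)
        sel = select_longest_window(_result_from_p(p, ["A"]))
        assert sel.window_ms[0] <= sel.min_p_time_ms <= sel.window_ms[1]
        assert np.isclose(sel.min_p, 0.001)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.06, 1, size=(4, 50))   # no sub-alpha noise runs
        p[2, 12:20] = 0.01                       # unique longest run on C
        p[0, 30:34] = 0.01
        names = ["A", "B", "C", "D"]
        sel = select_longest_window(_result_from_p(p, names))
        perm = [2, 0, 3, 1]
        sel_p = select_longest_window(_result_from_p(p[perm],
                                                     [names[i] for i in perm]))
        assert sel_p.electrode == sel.electrode
        assert sel_p.window_ms == sel.window_ms


class TestSummarizeWindow:
    def _selected(self, p):
        res = _result_from_p(p, ["A", "B"])
        return res, select_longest_window(res)

    def test_constant_p_passes_through(self):
        p = np.full((2, 60), 0.5)
        p[0, 20:40] = 0.01
        res, sel = self._selected(p)
        assert summarize_window(res, sel)["A"] == pytest.approx(0.01)

    def test_cap_applies_exactly(self):
        p = np.full((2, 60), 0.5)
        p[0, 20:40] = 0.01
        res, sel = self._selected(p)
        assert summarize_window(res, sel)["B"] == 0.05

    def test_median_matches_brute_force(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 0.2, size=(2, 80))
        p[0, 30:50] = rng.uniform(0, 0.04, size=20)
        res, sel = self._selected(p)
        out = summarize_window(res, sel)
        t_star = sel.min_p_time_ms / 1000.0
        neighbourhood = [i for i, t in enumerate(res.times)
                         if abs(t - t_star) <= 0.0100001]
        for ci, ch in enumerate(res.ch_names):
            expected = min(float(np.median(p[ci, neighbourhood])), 0.05)
            assert out[ch] == pytest.approx(expected)

    def test_empty_selection_rejected(self):
        res = _result_from_p(np.full((2, 20), 0.5), ["A", "B"])
        with pytest.raises(ValueError):
            summarize_window(res, select_longest_window(res))


class TestWindowedAmplitude:
    def test_constant_difference_returns_it_everywhere(self):
        cong = np.full((6, 2, 100), 0.32)
        incong = np.zeros((6, 2, 100))
        erps = _erpset(cong, incong)
        for window in [(0.0, 0.1), (0.1, 0.3), (0.0, 0.39)]:
            out = windowed_amplitude(erps, erps.ch_names[0], window)
            assert out["mean"] == pytest.approx(0.32)
            assert np.allclose(out["per_participant"], 0.32)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(8)
        cong = rng.standard_normal((5, 3, 120))
        incong = rng.standard_normal((5, 3, 120))
        erps = _erpset(cong, incong)
        out = windowed_amplitude(erps, erps.ch_names[2], (0.1, 0.3))
        idx = [i for i, t in enumerate(erps.times)
               if round(0.1 * SFREQ) <= round(t * SFREQ) < round(0.3 * SFREQ)]
        d = (cong - incong)[:, 2, idx]
        assert np.allclose(out["per_participant"], d.mean(axis=1))
        assert out["sd"] == pytest.approx(d.mean(axis=1).std(ddof=1))

    def test_unknown_electrode_rejected(self):
        erps = _erpset(np.zeros((5, 2, 50)), np.zeros((5, 2, 50)))
        with pytest.raises(KeyError):
            windowed_amplitude(erps, "QQ7", (0.0, 0.1))

    def test_window_outside_span_rejected(self):
        erps = _erpset(np.zeros((5, 2, 50)), np.zeros((5, 2, 50)))
        with pytest.raises(ValueError):
            windowed_amplitude(erps, erps.ch_names[0], (0.1, 0.9))
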