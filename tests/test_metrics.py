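import numpy as np
import pytest

from conftest import make_trace
from oracles import brute_hr_delta_slope, brute_plm_runs
from plmad.metrics import (
    PLMRun,
    aggregate_hr,
    detect_r_peaks,
    find_plm_runs,
    hr_response,
    night_ratio,
    periodicity_index,
    plm_indices,
)
from plmad.model import Hypnogram, LMEvent


def lms_at(onsets, dur=1.0, **kw):
    return [LMEvent(t, t + dur, **kw) for t in onsets]


class TestFindPLMRuns:
    def test_five_regular_movements_one_run(self):
        runs = find_plm_runs(lms_at([0, 30, 60, 90, 120]))
        assert len(runs) == 1
        assert len(runs[0]) == 5
        assert runs[0].imis_s == [30, 30, 30, 30]

    def test_three_movements_no_run(self):
        assert find_plm_runs(lms_at([0, 30, 60])) == []

    def test_short_imi_breaks_run_in_strict_mode(self):
        # IMI of 3 s breaks at the second LM; the chain restarts there
        runs = find_plm_runs(lms_at([0, 3, 30, 60, 90, 120]), short_imi="break")
        assert len(runs) == 1
        assert runs[0].lm_ids == [1, 2, 3, 4, 5]
        assert runs[0].imis_s == [27, 30, 30, 30]

    def test_short_imi_ignored_in_wasm_mode(self):
        # the intervening movement at 33 s is skipped; the run continues
        runs = find_plm_runs(lms_at([0, 30, 33, 60, 90, 120]), short_imi="ignore")
        assert len(runs) == 1
        assert runs[0].lm_ids == [0, 1, 3, 4, 5]

    def test_long_imi_terminates_run(self):
        runs = find_plm_runs(lms_at([0, 30, 60, 90, 300, 330, 360, 390]))
        assert len(runs) == 2
        assert runs[0].lm_ids == [0, 1, 2, 3]
        assert runs[1].lm_ids == [4, 5, 6, 7]

    def test_run_id_written_to_events(self):
        events = lms_at([0, 30, 60, 90, 500])
        find_plm_runs(events)
        assert [e.run_id for e in events] == [0, 0, 0, 0, None]

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 60))
            onsets = np.sort(rng.uniform(0, 3600, n))
            onsets = np.unique(onsets)
            events = lms_at(onsets)
            got = [r.lm_ids for r in find_plm_runs(events)]
            assert got == brute_plm_runs(list(onsets))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            find_plm_runs(lms_at([30, 0, 60, 90]))


class TestPLMIndices:
    def test_simple_rate(self):
        hyp = Hypnogram(stages=["S2"] * 720)  # 6 h sleep
        onsets = [100 + 30 * i for i in range(60)]
        events = lms_at(onsets)
        runs = find_plm_runs(events)
        plms_h, plmw_h, lm_count, plm_count = plm_indices(runs, events, hyp)
        assert plms_h == pytest.approx(10.0)
        assert plmw_h is None  # no wake epochs at all
        assert lm_count == 60 and plm_count == 60

    def test_no_runs_zero_indices(self):
        hyp = Hypnogram(stages=["S2"] * 120 + ["W"] * 120)
        events = lms_at([10.0, 500.0])
        plms_h, plmw_h, lm_count, plm_count = plm_indices([], events, hyp)
        assert plms_h == 0.0 and plmw_h == 0.0
        assert lm_count == 2 and plm_count == 0

    def test_run_straddling_wake_epoch_splits_numerators(self):
        # epochs: 0-120 s sleep, 120-150 s wake, 150-300 s sleep
        hyp = Hypnogram(stages=["S2"] * 4 + ["W"] + ["S2"] * 5)
        onsets = [10, 50, 90, 125, 160]  # 4 in sleep epochs, 1 in the wake epoch
        events = lms_at(onsets)
        runs = find_plm_runs(events)
        assert len(runs) == 1 and len(runs[0]) == 5  # continues across wake
        plms_h, plmw_h, _, _ = plm_indices(runs, events, hyp)
        tst_h = 270 / 3600
        wake_h = 30 / 3600
        assert plms_h == pytest.approx(4 / tst_h)
        assert plmw_h == pytest.approx(1 / wake_h)


class TestPeriodicityIndex:
    def test_all_qualifying_long_sequence(self):
        assert periodicity_index(lms_at([30 * i for i in range(10)])) == 1.0

    def test_alternating_imis_no_qualifying_sequence(self):
        onsets = [0]
        for i in range(6):
            onsets.append(onsets[-1] + (30 if i % 2 == 0 else 200))
        assert periodicity_index(lms_at(onsets)) == 0.0

    def test_single_lm_undefined(self):
        assert periodicity_index(lms_at([10.0])) is None

    def test_short_imis_do_not_qualify(self):
        # IMIs of 7 s are within PLM bounds but below the 10 s periodicity floor
        assert periodicity_index(lms_at([7 * i for i in range(8)])) == 0.0

    def test_mixed_fraction(self):
        # IMIs: 30,30,30 (qualifying seq of 3) then 200, then 30,30 (only 2)
        onsets = [0, 30, 60, 90, 290, 320, 350]
        pi = periodicity_index(lms_at(onsets))
        assert pi == pytest.approx(3 / 6)

    def test_state_filter(self):
        hyp = Hypnogram(stages=["S2"] * 4 + ["W"] * 16)
        onsets = [0, 30, 60, 90, 120, 150, 180]  # 4 in sleep, 3 in wake
        events = lms_at(onsets)
        pi_sleep = periodicity_index(events, "sleep", hyp)
        pi_wake = periodicity_index(events, "wake", hyp)
        assert pi_sleep == 1.0
        assert pi_wake == 0.0  # only 2 qualifying IMIs in wake, below min_seq


class TestNightRatio:
    def test_two_to_one(self):
        onsets = list(np.linspace(0, 999, 10)) + list(np.linspace(1001, 1999, 5))
        assert night_ratio(onsets, 2000.0) == pytest.approx(2.0)

    def test_zero_half_undefined(self):
        assert night_ratio([1500, 1600, 1700, 1800, 1900], 2000.0) is None
        assert night_ratio([], 2000.0) is None

    def test_symmetric(self):
        onsets = [100 * i for i in range(7)] + [1100 + 100 * i for i in range(7)]
        assert night_ratio(onsets, 2000.0) == pytest.approx(1.0)


def synth_ecg(rr_s, fs=250.0, amp=600.0):
    """ECG trace from an explicit RR sequence (first peak at 0.5 s)."""
    times = 0.5 + np.concatenate([[0.0], np.cumsum(rr_s)])
    n = int((times[-1] + 1.0) * fs)
    x = np.zeros(n)
    t = np.arange(-0.05, 0.05, 1 / fs)
    tpl = (1 - (t / 0.012) ** 2) * np.exp(-0.5 * (t / 0.012) ** 2)
    for rt in times:
        c = int(round(rt * fs))
        i0 = c - len(tpl) // 2
        if 0 <= i0 and i0 + len(tpl) <= n:
            x[i0 : i0 + len(tpl)] += tpl * amp
    return make_trace(x, fs=fs, label="ECG"), times


class TestDetectRPeaks:
    def test_60bpm_one_minute(self):
        ecg, truth = synth_ecg(np.ones(59))
        peaks = detect_r_peaks(ecg)
        assert abs(len(peaks) - 60) <= 1
        rr = np.diff(peaks)
        assert np.all(np.abs(rr - 1.0) <= 0.02)

    def test_zero_signal_empty(self):
        assert detect_r_peaks(make_trace(np.zeros(1000), fs=250.0)).size == 0

    def test_skipped_beat_gives_double_rr(self):
        rr = np.ones(40)
        rr[20] = 2.0  # one dropped beat
        ecg, _ = synth_ecg(rr)
        peaks = detect_r_peaks(ecg)
        gaps = np.diff(peaks)
        assert np.sum(np.abs(gaps - 2.0) < 0.05) == 1
        assert np.all((np.abs(gaps - 1.0) < 0.05) | (np.abs(gaps - 2.0) < 0.05))

    def test_peak_time_accuracy(self):
        ecg, truth = synth_ecg(np.ones(30))
        peaks = detect_r_peaks(ecg)
        for p in peaks:
            assert np.min(np.abs(truth - p)) < 0.03


class TestHRResponse:
    def test_constant_hr_zero_delta_and_slope(self):
        r = np.arange(0, 60, 1.0)  # 60 bpm
        resp = hr_response(r, plm_onset=30.2)
        assert resp is not None
        assert resp.delta == 0.0
        assert resp.slope == 0.0

    def test_baseline_cycle_normalized_to_zero(self):
        rng = np.random.default_rng(3)
        rr = 1.0 + 0.1 * rng.standard_normal(40)
        r = np.concatenate([[0.0], np.cumsum(rr)])
        onset = r[21] + 0.3
        resp = hr_response(r, onset)
        assert resp.pre_hr[-1] == 0.0  # the baseline is its own reference

    def test_constructed_delta_and_slope(self):
        # pre min -2 bpm and post max +8 bpm, 5 cycles apart: delta 10, slope 2
        hr = np.full(25, 60.0)
        hr[11] = 58.0  # pre minimum (baseline cycle index 12)
        hr[16] = 68.0  # post maximum
        rr = 60.0 / hr
        r = np.concatenate([[0.0], np.cumsum(rr)])
        onset = r[13] + 0.1  # baseline cycle = 12
        resp = hr_response(r, onset)
        assert resp.delta == pytest.approx(10.0)
        assert resp.slope == pytest.approx(2.0)

    def test_insufficient_cycles_skipped(self):
        r = np.arange(0, 12, 1.0)
        assert hr_response(r, plm_onset=5.0) is None

    def test_matches_direct_arithmetic_on_random_sequences(self, rng):
        for _ in range(50):
            rr = rng.uniform(0.6, 1.4, 60)
            r = np.concatenate([[0.0], np.cumsum(rr)])
            onset = rng.uniform(r[15], r[45])
            got = hr_response(r, onset)
            expected = brute_hr_delta_slope(r, onset)
            if expected is None:
                assert got is None
            else:
                assert got.delta == pytest.approx(expected[0])
                assert got.slope == pytest.approx(expected[1])

    def test_aggregate_reports_skips(self):
        r = np.arange(0, 100, 1.0)
        delta, slope, skipped = aggregate_hr(r, [2.0, 50.0])
        assert skipped == 1
        assert delta == 0.0 and slope == 0.0


class TestPLMRunType:
    def test_imi_consistency_enforced(self):
        with pytest.raises(ValueError):
            PLMRun(lm_ids=[0, 1, 2, 3], imis_s=[30.0])
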