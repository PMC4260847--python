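import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import as_roles, make_trace
from oracles import brute_moving_mean, simulate_state_machine
from plmad.detect import (
    DetectorRules,
    auc_screen,
    bridge_and_filter,
    detect_candidates,
    detect_lm,
    rms_envelope,
)
from plmad.model import Hypnogram, Recording, SignalTrace
from plmad.synth import SynthSpec, Train, generate
from plmad.thresholds import thresholds

RULES = DetectorRules()


def flat_profile(n, fs=100.0, alpha=8.0):
    """Constant thresholds: alpha, beta=alpha/4, psi=5/8 alpha."""
    return thresholds(np.zeros(n), U=alpha, L=alpha / 4, fs=fs)


class TestRMSEnvelope:
    def test_constant(self):
        y = rms_envelope(make_trace(np.full(500, -3.0)))
        np.testing.assert_allclose(y, 3.0)

    def test_zero(self):
        y = rms_envelope(make_trace(np.zeros(500)))
        np.testing.assert_array_equal(y, 0.0)

    def test_sine_rms(self):
        # many cycles per 0.15 s window: RMS -> 1/sqrt(2)
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 500 * t)
        y = rms_envelope(make_trace(x, fs=fs))
        np.testing.assert_allclose(y[2000:-2000], 1 / np.sqrt(2), rtol=1e-3)

    def test_trailing_alignment(self):
        x = np.zeros(100)
        x[50] = 10.0
        centered = rms_envelope(make_trace(x), align="centered")
        trailing = rms_envelope(make_trace(x), align="trailing")
        assert np.argmax(centered > 0) < 50 <= np.argmax(trailing > 0)


class TestDetectCandidates:
    def test_subthreshold_envelope_no_candidates(self):
        y = np.full(1000, 4.0)
        assert detect_candidates(y, flat_profile(1000), RULES) == []

    def test_hand_traced_single_burst(self):
        # 0 for 5 s, 12 uV for 2 s, 0 after (alpha=8, beta=2, psi=5)
        fs = 100.0
        y = np.zeros(1000)
        y[500:700] = 12.0
        out = detect_candidates(y, flat_profile(1000, fs), RULES)
        assert len(out) == 1
        on, off, flags = out[0]
        assert on == pytest.approx(5.0)
        assert off == pytest.approx(7.0)
        assert not flags

    def test_open_ended_candidate_flagged(self):
        fs = 100.0
        y = np.zeros(1000)
        y[900:] = 12.0  # exceeds alpha, never falls below beta again
        out = detect_candidates(y, flat_profile(1000, fs), RULES)
        assert len(out) == 1
        on, off, flags = out[0]
        assert "open_ended" in flags
        assert off == pytest.approx(10.0)

    def test_boundary_equality_does_not_trigger(self):
        # exactly alpha is not an onset (strict >)
        y = np.full(1000, 8.0)
        assert detect_candidates(y, flat_profile(1000), RULES) == []

    def test_at_beta_is_not_below(self):
        # y drops exactly to beta: event cannot close, stays open to end
        fs = 100.0
        y = np.full(1000, 2.0)
        y[100:200] = 12.0
        out = detect_candidates(y, flat_profile(1000, fs), RULES)
        assert len(out) == 1
        assert "open_ended" in out[0][2]

    def test_no_detection_in_disabled_region(self):
        fs = 100.0
        n = 2000
        y = np.zeros(n)
        y[500:600] = 12.0
        eta = np.zeros(n)
        eta[400:700] = 60.0  # detector off around the burst
        prof = thresholds(eta, fs=fs)
        out = detect_candidates(y, prof, RULES)
        assert out == []

    def test_matches_oracle_on_random_envelopes(self, rng):
        fs = 100.0
        k_fall = 5
        for _ in range(25):
            n = 5000
            y = np.abs(
                brute_moving_mean(rng.normal(0, 6, n), 9) * 4
            )  # smooth positive envelope
            eta = np.clip(brute_moving_mean(rng.normal(2, 30, n), 401), 0, None)
            prof = thresholds(eta, fs=fs)
            got = detect_candidates(y, prof, RULES)
            expected = simulate_state_machine(
                y, prof.alpha, prof.beta, prof.psi, prof.enabled, k_fall
            )
            exp = [
                (on / fs, off / fs, frozenset({"open_ended"}) if oe else frozenset())
                for on, off, oe in expected
            ]
            assert got == exp


class TestBridgeAndFilter:
    def test_bridge_then_keep(self):
        out = bridge_and_filter(
            [(0.0, 0.6, frozenset()), (0.68, 1.3, frozenset())], RULES
        )
        kept = [iv for iv in out if not (iv[2] & {"too_short", "too_long"})]
        assert kept == [(0.0, 1.3, frozenset({"bridged"}))]

    def test_isolated_short_rejected(self):
        out = bridge_and_filter([(0.0, 0.5, frozenset())], RULES)
        assert len(out) == 1
        assert "too_short" in out[0][2]

    def test_merge_then_reject_order_sensitivity(self):
        # gap 1.5 <= 2.0 merges to [0, 13) which is then > 10 s: rejected
        out = bridge_and_filter(
            [(0.0, 6.0, frozenset()), (7.5, 13.0, frozenset())], RULES
        )
        assert len(out) == 1
        on, off, flags = out[0]
        assert (on, off) == (0.0, 13.0)
        assert {"merged", "too_long"} <= flags

    def test_bridge_before_duration_filter(self):
        # two 0.4 s chunks 0.05 s apart: individually too short, bridged ok
        out = bridge_and_filter(
            [(0.0, 0.4, frozenset()), (0.45, 0.85, frozenset())], RULES
        )
        assert len(out) == 1
        assert out[0][:2] == (0.0, 0.85)
        assert "too_short" not in out[0][2]

    def test_short_chunks_do_not_participate_in_merge(self):
        # the 0.2 s fragment is rejected before merging, so the two long
        # movements 3 s apart stay separate
        out = bridge_and_filter(
            [
                (0.0, 1.0, frozenset()),
                (2.0, 2.2, frozenset()),
                (4.0, 5.0, frozenset()),
            ],
            RULES,
        )
        kept = [iv for iv in out if not (iv[2] & {"too_short", "too_long"})]
        assert [iv[:2] for iv in kept] == [(0.0, 1.0), (4.0, 5.0)]

    def test_idempotent_on_retained_output(self):
        ivs = [
            (0.0, 0.6, frozenset()),
            (0.68, 1.3, frozenset()),
            (5.0, 6.4, frozenset()),
            (12.0, 12.3, frozenset()),
            (30.0, 31.0, frozenset()),
            (32.5, 33.5, frozenset()),
        ]
        first = bridge_and_filter(ivs, RULES)
        retained = [iv for iv in first if not (iv[2] & {"too_short", "too_long"})]
        second = bridge_and_filter(retained, RULES)
        assert second == retained

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 500, allow_nan=False),
                st.floats(0.05, 12.0, allow_nan=False),
            ),
            max_size=20,
        )
    )
    def test_idempotence_property(self, raw):
        ivs = sorted((on, on + dur, frozenset()) for on, dur in raw)
        # make non-overlapping
        clean = []
        for on, off, fl in ivs:
            if clean and on < clean[-1][1]:
                continue
            clean.append((on, off, fl))
        first = bridge_and_filter(clean, RULES)
        retained = [iv for iv in first if not (iv[2] & {"too_short", "too_long"})]
        assert bridge_and_filter(retained, RULES) == retained

    def test_retained_durations_within_limits(self, rng):
        ivs = []
        t = 0.0
        for _ in range(100):
            t += rng.uniform(0.01, 5.0)
            dur = rng.uniform(0.05, 12.0)
            ivs.append((t, t + dur, frozenset()))
            t += dur
        out = bridge_and_filter(ivs, RULES)
        for on, off, flags in out:
            if not (flags & {"too_short", "too_long"}):
                assert RULES.min_dur_s <= off - on <= RULES.max_dur_s


class TestAUCScreen:
    def test_stable_movement_kept(self):
        fs = 100.0
        x = make_trace(np.full(300, 10.0), fs=fs)
        prof = flat_profile(300, fs)  # alpha = 8 -> limit 4
        out = auc_screen(x, [(0.5, 2.5, frozenset())], prof, RULES)
        assert len(out) == 1
        assert "auc_rejected" not in out[0][2]
        assert out[0][3] == pytest.approx(10.0)

    def test_myoclonic_spike_rejected(self):
        # 0.8 s interval, 20 uV for 0.05 s, zero elsewhere:
        # trapezoidal area 1.0 uV*s -> normalized 1.25 < 4
        fs = 100.0
        x = np.zeros(200)
        x[100:105] = 20.0
        prof = flat_profile(200, fs)
        out = auc_screen(make_trace(x, fs=fs), [(0.6, 1.4, frozenset())], prof, RULES)
        assert out[0][3] == pytest.approx(1.25)
        assert "auc_rejected" in out[0][2]

    def test_empty_interval_list(self):
        x = make_trace(np.zeros(100))
        assert auc_screen(x, [], flat_profile(100), RULES) == []

    def test_inverted_mode_keeps_myoclonus(self):
        fs = 100.0
        x = np.zeros(200)
        x[100:105] = 20.0
        rules = DetectorRules(auc_invert=True)
        out = auc_screen(
            make_trace(x, fs=fs), [(0.6, 1.4, frozenset())], flat_profile(200, fs), rules
        )
        assert "auc_rejected" not in out[0][2]

    def test_zero_length_interval_errors(self):
        x = make_trace(np.zeros(100))
        with pytest.raises(ValueError, match="covers"):
            auc_screen(x, [(0.5, 0.5, frozenset())], flat_profile(100), RULES)


class TestDetectLM:
    def test_all_zero_recording(self):
        rec = Recording(
            traces={"leg": SignalTrace(np.zeros(60_000), 100.0, "leg")},
            duration_s=600.0,
        )
        hyp = Hypnogram(stages=["S2"] * 20)
        assert detect_lm(rec, hyp) == []

    def test_planted_bursts_recovered(self, train_fixture):
        spec, res = train_fixture
        rec = as_roles(res.recording)
        hyp = res.hypnogram
        events = [e for e in detect_lm(rec, hyp) if e.retained]
        truth = res.ground_truth.lm_intervals
        assert len(events) == len(truth)
        for ev, (on, off) in zip(events, truth):
            assert abs(ev.onset_s - on) <= 0.25

    def test_retained_durations_in_range(self, train_fixture):
        _, res = train_fixture
        events = detect_lm(as_roles(res.recording), res.hypnogram)
        for ev in events:
            if ev.retained:
                assert 0.75 <= ev.duration_s <= 10.0

    def test_shutoff_in_noisy_middle_third(self):
        # baseline ramps above the 50 uV shutoff in the middle third:
        # bursts planted there must not be detected
        spec = SynthSpec(
            duration_h=0.25,
            fs_hz=100.0,
            seed=11,
            baseline_uv=((0.0, 1.0), (300.0, 80.0), (600.0, 1.0)),
            bursts=[
                __import__("plmad.synth", fromlist=["Burst"]).Burst(o, 1.5, 120.0)
                for o in (100.0, 400.0, 450.0, 700.0)
            ],
            include_ecg_channel=False,
        )
        res = generate(spec)
        events = [
            e for e in detect_lm(as_roles(res.recording, with_ecg=False), res.hypnogram)
            if e.retained
        ]
        onsets = [e.onset_s for e in events]
        assert not any(320 < t < 580 for t in onsets)
        assert any(abs(t - 100) < 1 for t in onsets)
        assert any(abs(t - 700) < 1 for t in onsets)

    def test_stage_labels_from_hypnogram(self, train_fixture):
        _, res = train_fixture
        events = detect_lm(as_roles(res.recording), res.hypnogram)
        for ev in events:
            assert ev.state == res.hypnogram.stage_at(ev.onset_s)

    def test_deterministic(self, train_fixture):
        _, res = train_fixture
        rec = as_roles(res.recording)
        a = detect_lm(rec, res.hypnogram)
        b = detect_lm(rec, res.hypnogram)
        assert [(e.onset_s, e.offset_s, tuple(sorted(e.flags))) for e in a] == [
            (e.onset_s, e.offset_s, tuple(sorted(e.flags))) for e in b
        ]

    def test_short_recording_warns(self):
        rec = Recording(
            traces={"leg": SignalTrace(np.zeros(10_000), 100.0, "leg")},
            duration_s=100.0,
        )
        hyp = Hypnogram(stages=["S2"] * 4)
        with pytest.warns(UserWarning, match="< 2 h"):
            detect_lm(rec, hyp)
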