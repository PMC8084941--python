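import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flybehave import (
    LoomResponseThresholds,
    LoomingProtocol,
    LoomingSchedule,
    delta_jumps,
    delta_speed,
    event_delta_speeds,
    generate_schedule,
    loom_profile,
    loom_theta,
    select_valid_events,
    theta_cap_time_s,
    triggered_profile,
)
from flybehave.errors import InsufficientDataError, ParameterError

FPS = 60.0


def _schedule(onsets):
    return LoomingSchedule(np.asarray(onsets, float))


class TestLoomTheta:
    def test_tau_equals_ratio_gives_90_degrees(self):
        assert loom_theta(0.040, 0.040) == pytest.approx(90.0, abs=1e-12)

    def test_onset_angle_half_second_out(self):
        assert loom_theta(0.500, 0.040) == pytest.approx(9.148, abs=1e-3)

    def test_cap_reached_at_78_degrees(self):
        tau_star = 0.500 - theta_cap_time_s()
        assert loom_theta(tau_star, 0.040) == pytest.approx(78.0, abs=1e-9)
        assert tau_star == pytest.approx(0.0494, abs=1e-4)

    def test_domain_error_for_nonpositive_tau(self):
        with pytest.raises(ParameterError):
            loom_theta(0.0)

    @given(tau=st.floats(1e-3, 10.0), ratio=st.floats(1e-3, 1.0))
    def test_scale_invariance(self, tau, ratio):
        # doubling l/v at fixed tau equals halving tau at fixed l/v
        assert loom_theta(tau, 2 * ratio) == pytest.approx(
            loom_theta(tau / 2, ratio), rel=1e-12
        )

    def test_strictly_decreasing_in_tau(self):
        taus = np.linspace(0.01, 5.0, 500)
        theta = loom_theta(taus)
        assert np.all(np.diff(theta) < 0)
        assert loom_theta(1e6) < 1e-2  # -> 0 as tau -> inf


class TestLoomProfile:
    def test_first_sample_is_onset_angle(self):
        _, theta = loom_profile()
        assert theta[0] == pytest.approx(9.148, abs=1e-3)

    def test_expansion_lasts_about_450_ms(self):
        t, theta = loom_profile(sample_rate_hz=10000.0)
        reach = t[np.argmax(theta >= 78.0 - 1e-9)]
        assert reach == pytest.approx(0.4506, abs=5e-4)

    def test_hold_phase_about_50_ms(self):
        t, theta = loom_profile(sample_rate_hz=10000.0)
        hold = np.sum(theta >= 78.0 - 1e-9) / 10000.0
        assert hold == pytest.approx(0.0494, abs=5e-4)

    def test_non_decreasing_and_capped(self):
        _, theta = loom_profile(sample_rate_hz=240.0)
        assert np.all(np.diff(theta) >= 0)
        assert theta.max() <= 78.0 + 1e-12
        assert theta[-1] == pytest.approx(78.0)

    def test_bad_sample_rate(self):
        with pytest.raises(ParameterError):
            loom_profile(sample_rate_hz=0.0)


class TestSchedule:
    def test_default_protocol_properties(self):
        sched = generate_schedule(LoomingProtocol(), seed=42)
        assert len(sched) == 7
        gaps = np.diff(sched.onsets_s) - 0.5
        assert np.all(gaps >= 10.0) and np.all(gaps <= 20.0)
        assert sched.onsets_s[0] >= 120.0
        assert sched.offsets_s[-1] <= 420.0

    def test_zero_looms_empty_schedule(self):
        proto = LoomingProtocol(n_looms=0)
        assert len(generate_schedule(proto, seed=0)) == 0

    def test_feasibility_arithmetic(self):
        # minimum span 6*10 + 7*0.5 = 63.5 s fits in 300 s
        proto = LoomingProtocol()
        span = (proto.n_looms - 1) * proto.isi_min_s + proto.n_looms * proto.loom_duration_s
        assert span == pytest.approx(63.5)
        with pytest.raises(ParameterError):
            LoomingProtocol(stimulation_s=60.0)

    def test_many_seeds_never_violate_invariants(self):
        proto = LoomingProtocol()
        for seed in range(200):
            generate_schedule(proto, seed).validate(proto)


class TestEventSelection:
    def test_constant_walking_keeps_all(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130, 150, 170, 190, 210, 230, 250])
        assert len(select_valid_events(speed, FPS, sched)) == 7

    def test_paused_pre_bin_excluded(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130.0, 160.0])
        speed[int(129.5 * FPS):int(130 * FPS)] = 0.0
        keep = select_valid_events(speed, FPS, sched)
        np.testing.assert_array_equal(keep, [1])

    def test_above_band_pre_bin_excluded(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130.0, 160.0])
        speed[int(159.5 * FPS):int(160 * FPS)] = 80.0
        keep = select_valid_events(speed, FPS, sched)
        np.testing.assert_array_equal(keep, [0])

    def test_brute_force_equivalence(self, rng):
        thr = LoomResponseThresholds()
        proto = LoomingProtocol()
        for trial in range(30):
            speed = rng.uniform(0, 90, int(420 * FPS))
            sched = generate_schedule(proto, seed=trial)
            got = set(select_valid_events(speed, FPS, sched, thr).tolist())
            expected = set()
            for i in range(len(sched)):
                pre = speed[int(round((sched.onsets_s[i] - 0.5) * FPS)):
                            int(round(sched.onsets_s[i] * FPS))]
                late = speed[int(round((sched.offsets_s[i] + 2.0) * FPS)):
                             int(round((sched.offsets_s[i] + 2.5) * FPS))]
                ok = True
                for b in (pre, late):
                    frac = np.mean((b > 4.0) & (b < 75.0))
                    ok &= frac >= 0.5
                if ok:
                    expected.add(i)
            assert got == expected


class TestTriggeredProfile:
    def test_constant_trace_flat(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130, 150, 170, 190, 210, 230, 250])
        prof = triggered_profile(speed, FPS, sched)
        np.testing.assert_allclose(prof["mean"], 10.0)
        np.testing.assert_allclose(prof["sem"], 0.0)

    def test_jump_frame_excluded_from_average(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130.0, 160.0])
        k = int(130.5 * FPS)
        speed[k] = 100.0
        prof = triggered_profile(speed, FPS, sched)
        np.testing.assert_allclose(prof["mean"], 10.0)  # spike dropped, not averaged
        t_spike = 0.5
        idx = np.argmin(np.abs(prof["t_s"] - t_spike))
        assert prof["n"][idx] == 1  # only the other event contributes there

    def test_no_valid_events_signalled(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130.0])
        with pytest.raises(InsufficientDataError):
            triggered_profile(speed, FPS, sched, events=np.empty(0, int))


class TestDeltas:
    def test_constant_trace_zero_delta(self):
        speed = np.full(int(420 * FPS), 10.0)
        assert delta_speed(speed, FPS, 130.0, 130.5) == pytest.approx(0.0)

    def test_pre_10_post_25_gives_15(self):
        speed = np.full(int(420 * FPS), 10.0)
        speed[int(130.5 * FPS):int(131.0 * FPS)] = 25.0
        assert delta_speed(speed, FPS, 130.0, 130.5) == pytest.approx(15.0)

    def test_bins_out_of_range_signalled(self):
        with pytest.raises(InsufficientDataError):
            delta_speed(np.full(100, 10.0), FPS, 0.2, 0.7)

    def test_no_jumps_anywhere(self):
        speed = np.full(int(420 * FPS), 10.0)
        out = delta_jumps(speed, FPS)
        assert out == {"baseline": 0, "stimulation": 0, "delta": 0}

    def test_two_baseline_five_stim(self):
        speed = np.full(int(420 * FPS), 10.0)
        for t in (10, 50):  # baseline jumps
            speed[int(t * FPS)] = 100.0
        for t in (130, 150, 200, 250, 300):  # stimulation jumps
            speed[int(t * FPS)] = 100.0
        out = delta_jumps(speed, FPS)
        assert out == {"baseline": 2, "stimulation": 5, "delta": 3}

    def test_event_delta_speeds_vectorizes(self):
        speed = np.full(int(420 * FPS), 10.0)
        sched = _schedule([130.0, 160.0])
        np.testing.assert_allclose(
            event_delta_speeds(speed, FPS, sched), [0.0, 0.0]
        )
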