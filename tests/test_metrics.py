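import numpy as np
import pytest

from rehabgame.engine import (
    Direction,
    GameConfig,
    GameEvent,
    ObjectKind,
    catch_test,
    run_session,
)
from rehabgame.metrics import (
    MetricsConfig,
    ResponseTrace,
    detect_onset,
    overlay_frame,
    segment_responses,
    session_summary,
    success_rate,
    trace_kinematics,
    variability,
)
from rehabgame.players import preset

FR = 120.0


def make_trace(disp, direction=Direction.rightward, amplitude=10.0, caught=False):
    disp = np.asarray(disp, dtype=float)
    return ResponseTrace(
        event_id=0,
        direction=direction,
        t=np.arange(len(disp)) / FR,
        displacement=disp,
        caught=caught,
        required_amplitude=amplitude,
    )


def onset_oracle(trace, thr, hold):
    """Exhaustive scan over all candidate onset samples."""
    t, disp = trace.t, np.abs(trace.displacement)
    for i in range(len(t)):
        if t[i] + hold > t[-1] + 1e-9:
            return None  # hold window no longer fits
        window = [j for j in range(i, len(t)) if t[j] <= t[i] + hold + 1e-9]
        if all(disp[j] >= thr for j in window):
            return t[i]
    return None


def random_trace(rng):
    n = rng.integers(30, 241)
    kind = rng.integers(0, 3)
    t = np.arange(n) / FR
    if kind == 0:  # noise only
        disp = rng.normal(0.0, rng.uniform(0.2, 1.5), size=n)
    elif kind == 1:  # delayed smooth ramp + noise
        onset = rng.uniform(0.1, 1.2)
        amp = rng.uniform(3.0, 40.0)
        disp = amp / (1 + np.exp(-(t - onset) * rng.uniform(5, 30)))
        disp += rng.normal(0.0, 0.5, size=n)
    else:  # step with dropouts
        disp = np.where(t > rng.uniform(0.0, 1.5), rng.uniform(2.0, 10.0), 0.0)
        drop = rng.random(n) < 0.05
        disp[drop] = 0.0
    return make_trace(disp)


class TestSegmentation:
    def test_30_event_log_gives_30_traces(self):
        log = run_session(GameConfig(seed=2), preset("able_bodied", seed=2), seed=2)
        assert len(segment_responses(log)) == 30

    def test_empty_log(self):
        with pytest.warns(UserWarning):
            log = run_session(
                GameConfig(session_duration_s=1.0, seed=0), preset("able_bodied")
            )
        assert segment_responses(log) == []

    def test_hand_built_windows(self, three_event_log):
        traces = segment_responses(three_event_log)
        assert len(traces) == 3
        tr0, tr1, tr2 = traces
        n = 241  # 2 s at 120 Hz, inclusive window
        assert all(len(tr.t) == n for tr in traces)
        # event 0: paddle 50 -> 30 at t=0.5, leftward so displacement +20
        expected0 = np.where(np.arange(n) / FR < 0.5, 0.0, 20.0)
        np.testing.assert_allclose(tr0.displacement, expected0)
        assert tr0.required_amplitude == pytest.approx(20.0)
        # event 1: paddle 30 -> 70 at rel t=0.5, rightward so +40
        expected1 = np.where(np.arange(n) / FR < 0.5, 0.0, 40.0)
        np.testing.assert_allclose(tr1.displacement, expected1)
        # event 2: paddle 70 -> 20, leftward so +50
        expected2 = np.where(np.arange(n) / FR < 0.5, 0.0, 50.0)
        np.testing.assert_allclose(tr2.displacement, expected2)
        assert [tr.t[0] for tr in traces] == [0.0, 0.0, 0.0]
        assert all(tr.displacement[0] == 0.0 for tr in traces)

    def test_missing_frames_named_error(self, three_event_log):
        log = three_event_log
        keep = np.ones(len(log.t), dtype=bool)
        keep[300:310] = False  # inside event 1's window
        log.t = log.t[keep]
        log.paddle_x = log.paddle_x[keep]
        with pytest.raises(ValueError, match="event 1"):
            segment_responses(log)

    def test_distractors_excluded(self):
        cfg = GameConfig(distractors_enabled=True, seed=3)
        log = run_session(cfg, preset("able_bodied", seed=3), seed=3)
        traces = segment_responses(log)
        assert len(traces) == 30
        target_ids = {e.event_id for e in log.target_events}
        assert {tr.event_id for tr in traces} == target_ids


class TestOnset:
    def test_flat_trace(self):
        assert detect_onset(make_trace(np.zeros(241))) is None

    def test_ideal_step(self):
        t = np.arange(241) / FR
        disp = np.where(t >= 0.4, 10.0, 0.0)
        assert detect_onset(make_trace(disp), 2.0, 0.05) == pytest.approx(0.4)

    def test_rejects_bad_thresholds(self):
        with pytest.raises(ValueError):
            detect_onset(make_trace(np.zeros(10)), 0.0, 0.05)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            tr = random_trace(rng)
            got = detect_onset(tr, 2.0, 0.05)
            want = onset_oracle(tr, 2.0, 0.05)
            assert got == want, f"mismatch: {got} vs {want}"


class TestSuccessRate:
    def test_all_caught(self):
        traces = [
            make_trace(np.zeros(50), d, caught=True)
            for d in (Direction.leftward, Direction.rightward)
            for _ in range(3)
        ]
        assert success_rate(traces) == (100.0, 100.0, 100.0)

    def test_half_caught_each_side(self):
        traces = []
        for d in (Direction.leftward, Direction.rightward):
            traces += [make_trace(np.zeros(50), d, caught=(i < 3)) for i in range(6)]
        assert success_rate(traces) == (50.0, 50.0, 50.0)

    def test_unweighted_direction_average(self):
        traces = [make_trace(np.zeros(50), Direction.leftward, caught=(i < 2)) for i in range(5)]
        traces += [make_trace(np.zeros(50), Direction.rightward, caught=(i < 3)) for i in range(5)]
        left, right, avg = success_rate(traces)
        assert (left, right) == (40.0, 60.0)
        assert avg == 50.0

    def test_single_direction_falls_back_with_warning(self):
        traces = [make_trace(np.zeros(50), Direction.leftward, caught=True)]
        with pytest.warns(UserWarning):
            left, right, avg = success_rate(traces)
        assert right is None
        assert avg == left == 100.0

    def test_sr_agrees_with_engine_catch_flags(self):
        log = run_session(GameConfig(seed=7), preset("stroke_moderate", seed=7), seed=7)
        traces = segment_responses(log)
        # independent path: recompute catches from raw frames
        for e in log.target_events:
            i = int(np.searchsorted(log.t, e.t_disappear - 1e-6))
            expected = catch_test(
                log.paddle_x[i],
                log.game_config.paddle_width_pct,
                e.x_spawn,
                log.game_config.target_width_pct,
            )
            assert log.catches[e.event_id] == expected
        n_caught = sum(tr.caught for tr in traces)
        assert n_caught == sum(log.catches.values())


class TestKinematics:
    def test_clean_reach_no_overshoot(self):
        t = np.arange(241) / FR
        s = np.clip(t / 0.5, 0, 1)
        disp = 10.0 * s**3 * (10 - 15 * s + 6 * s**2)
        kin = trace_kinematics(make_trace(disp, amplitude=10.0))
        assert kin.overshoot_count == 0
        assert kin.final_error_pct == pytest.approx(0.0, abs=1e-9)
        assert kin.peak_amplitude_pct == pytest.approx(10.0)

    def test_overshoot_and_return_counts_once(self):
        t = np.arange(241) / FR
        s = np.clip(t / 0.5, 0, 1)
        disp = 12.0 * s**3 * (10 - 15 * s + 6 * s**2)  # to 120%
        disp[t > 1.0] = 10.0  # settle back on target
        kin = trace_kinematics(make_trace(disp, amplitude=10.0))
        assert kin.overshoot_count == 1

    def test_absent_onset_gives_none(self):
        assert trace_kinematics(make_trace(np.zeros(241))) is None

    def test_stroke_presets_overshoot_more_than_able(self):
        means = {}
        for name in ("able_bodied", "stroke_moderate"):
            vals = []
            for s in range(8):
                log = run_session(GameConfig(seed=s), preset(name, seed=s), seed=s)
                vals.append(session_summary(log).overshoot_count_mean)
            means[name] = np.mean(vals)
        assert means["stroke_moderate"] > means["able_bodied"]


class TestVariability:
    def test_identical_traces(self):
        traces = [make_trace(np.linspace(0, 10, 100)) for _ in range(4)]
        assert variability(traces, Direction.rightward) == pytest.approx(0.0)

    def test_two_constant_traces_closed_form(self):
        # sample SD of {0, 10} is 7.071... at every time point
        traces = [
            make_trace(np.full(100, 0.0), amplitude=100.0),
            make_trace(np.full(100, 10.0), amplitude=100.0),
        ]
        assert variability(traces, Direction.rightward) == pytest.approx(
            np.sqrt(50.0), rel=1e-9
        )

    def test_requires_two_traces(self):
        assert variability([make_trace(np.zeros(50))], Direction.rightward) is None

    def test_able_less_variable_than_severe(self):
        means = {}
        for name in ("able_bodied", "stroke_severe"):
            vals = []
            for s in range(10):
                log = run_session(GameConfig(seed=s), preset(name, seed=s), seed=s)
                vals.append(session_summary(log).variability_pct)
            means[name] = np.mean(vals)
        assert means["able_bodied"] < means["stroke_severe"]


class TestSessionSummary:
    def test_hand_computed_fixture(self, three_event_log):
        m = session_summary(three_event_log)
        assert m.sr_avg == 0.0  # no catch flags set in the fixture
        assert m.mot_left_mean_s == pytest.approx(0.5)
        assert m.mot_right_mean_s == pytest.approx(0.5)
        assert m.mot_avg_s == pytest.approx(0.5)
        assert m.response_time_ms == pytest.approx(500.0)
        assert m.peak_amplitude_mean_pct == pytest.approx((20 + 40 + 50) / 3)
        assert m.overshoot_count_mean == 0.0
        assert (m.n_events_left, m.n_events_right) == (2, 1)
        assert m.n_onsets == 3

    def test_ideal_player_session(self, game_config, ideal_player):
        m = session_summary(run_session(game_config, ideal_player))
        assert m.sr_avg == 100.0
        # zero latency: onset is the threshold-crossing of a fast reach
        assert m.mot_avg_s < 0.1

    def test_empty_session(self):
        with pytest.warns(UserWarning):
            log = run_session(
                GameConfig(session_duration_s=1.0, seed=0), preset("able_bodied")
            )
        m = session_summary(log)
        assert m.sr_avg is None
        assert m.mot_avg_s is None
        assert (m.n_events_left, m.n_events_right) == (0, 0)

    def test_invariant_to_added_distractors(self):
        log = run_session(GameConfig(seed=9), preset("stroke_mild", seed=9), seed=9)
        before = session_summary(log).to_dict()
        next_id = max(e.event_id for e in log.events) + 1
        log.events = log.events + [
            GameEvent(next_id, ObjectKind.distractor, 0.0, 2.0, 42.0)
        ]
        log.distractor_contacts[next_id] = True
        after = session_summary(log).to_dict()
        assert before == after


class TestOverlay:
    def test_overlay_shape_and_columns(self, three_event_log):
        df = overlay_frame(segment_responses(three_event_log))
        assert list(df.columns) == ["event_id", "direction", "caught", "t_s", "displacement_pct"]
        assert len(df) == 3 * 241

    def test_empty(self):
        assert overlay_frame([]).empty
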