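"""The supervision loop: slope fit, verdicts, retry semantics, switch-off."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from sumdkit import (
    SupervisionConfig,
    TerminationReason,
    checkpoint_schedule,
    fit_slope,
    judge_step,
    run_sumd,
)
from sumdkit.fixtures import make_scripted_engine


class TestFitSlope:
    def test_unit_descent_series(self):
        slope = fit_slope([120, 240, 360, 480, 600], [10, 9, 8, 7, 6])
        assert slope == pytest.approx(-1 / 120, abs=1e-15)

    def test_constant_series_slope_zero(self):
        assert fit_slope([1, 2, 3], [4.4, 4.4, 4.4]) == 0.0

    @given(
        seed=st.integers(0, 200),
    )
    def test_matches_least_squares_minimization(self, seed):
        """OLS closed form agrees with a numeric SSE minimizer to 1e-10."""
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 600, size=5))
        while np.any(np.diff(t) <= 0):
            t = np.sort(rng.uniform(0, 600, size=5))
        d = rng.uniform(0, 40, size=5)

        def sse(p):
            a, b = p
            return float(((d - (a * t + b)) ** 2).sum())

        res = minimize(sse, x0=[0.0, d.mean()], method="Nelder-Mead",
                       options={"xatol": 1e-13, "fatol": 1e-16, "maxiter": 20000})
        assert fit_slope(t, d) == pytest.approx(res.x[0], abs=1e-8)
        # and against the normal-equations form written out independently
        tbar, dbar = t.mean(), d.mean()
        assert fit_slope(t, d) == pytest.approx(
            ((t - tbar) * (d - dbar)).sum() / ((t - tbar) ** 2).sum(), abs=1e-10
        )

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            fit_slope([5, 5, 5], [1, 2, 3])


class TestJudgeStep:
    @pytest.mark.parametrize(
        "slope, verdict",
        [(-0.01, True), (0.01, False), (0.0, False), (-1e-15, True)],
    )
    def test_strictly_negative_is_productive(self, slope, verdict):
        assert judge_step(slope) is verdict

    def test_nan_slope_is_an_error(self):
        with pytest.raises(ValueError):
            judge_step(float("nan"))


class TestCheckpointSchedule:
    def test_default_schedule(self):
        cfg = SupervisionConfig()
        assert checkpoint_schedule(cfg) == pytest.approx([120, 240, 360, 480, 600])

    def test_two_checkpoints(self):
        cfg = SupervisionConfig(n_checkpoints=2)
        assert checkpoint_schedule(cfg) == pytest.approx([300, 600])

    @pytest.mark.parametrize("n", [2, 3, 5, 7])
    def test_last_offset_is_window_end(self, n):
        cfg = SupervisionConfig(n_checkpoints=n, step_duration_ps=600.0)
        sched = checkpoint_schedule(cfg)
        assert len(sched) == n
        assert sched[-1] == pytest.approx(600.0)


def _cfg(**kw):
    defaults = dict(step_duration_ps=600.0, n_checkpoints=5, switchoff_distance=5.0,
                    post_switchoff_steps=3, max_consecutive_failures=5, max_total_steps=100)
    defaults.update(kw)
    return SupervisionConfig(**defaults)


class TestRunSumdScripted:
    def test_monotone_descent_never_rejects(self):
        script = [10.0, 9.0, 8.0, 7.0, 6.0, 4.0] + [4.0] * 10
        engine, top, lig, site = make_scripted_engine(script, start_distance=11.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        assert all(r.productive for r in run.step_log)
        assert engine.n_velocity_resamples == 0
        assert run.switchoff_step is not None
        unsupervised = [r for r in run.step_log if not r.supervised]
        assert len(unsupervised) == 3  # post_switchoff_steps
        assert run.terminated_reason is TerminationReason.COMPLETED

    def test_never_approaching_script_hits_failure_limit(self):
        engine, top, lig, site = make_scripted_engine([10.0, 11.0], start_distance=10.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        assert run.terminated_reason is TerminationReason.FAILURE_LIMIT
        assert sum(not r.productive for r in run.step_log) == 5
        assert run.retained_trajectory is None
        # every rejection reassigned velocities
        assert engine.n_velocity_resamples == 5

    def test_rejection_restores_window_start(self):
        # 12 then 11: first window 10→12 rejected; retry starts from 10 again
        engine, top, lig, site = make_scripted_engine([12.0, 9.0, 4.0, 4.0, 4.0, 4.0],
                                                      start_distance=10.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        rejected = run.step_log[0]
        retry = run.step_log[1]
        assert not rejected.productive
        assert retry.productive
        # retry's first checkpoint interpolates from the restored distance 10
        assert retry.checkpoint_distances[0] == pytest.approx(10.0 + (9.0 - 10.0) / 5)

    def test_checkpoint_distances_follow_linear_interpolation(self):
        script = [8.0, 6.0, 4.0] + [4.0] * 5
        engine, top, lig, site = make_scripted_engine(script, start_distance=10.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        expected_first = [10.0 + (8.0 - 10.0) * k / 5 for k in range(1, 6)]
        assert run.step_log[0].checkpoint_distances == pytest.approx(expected_first, abs=1e-9)
        expected_second = [8.0 + (6.0 - 8.0) * k / 5 for k in range(1, 6)]
        assert run.step_log[1].checkpoint_distances == pytest.approx(expected_second, abs=1e-9)

    def test_switchoff_is_irreversible_and_counts_post_steps(self):
        script = [10.0, 4.5] + [6.0, 7.0, 8.0, 9.0]  # distance climbs after switch-off
        engine, top, lig, site = make_scripted_engine(script, start_distance=11.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        switch = run.switchoff_step
        assert switch is not None
        post = [r for r in run.step_log if not r.supervised]
        assert len(post) == 3
        assert all(r.productive for r in post)  # retained regardless of slope
        # no supervised record after the switch-off window
        seen_switch = False
        for r in run.step_log:
            if seen_switch:
                assert not r.supervised
            if r.supervised and r.productive and r.end_distance < 5.0:
                seen_switch = True

    def test_step_limit_termination(self):
        engine, top, lig, site = make_scripted_engine([9.0, 8.0], start_distance=10.0)
        cfg = _cfg(max_total_steps=4, switchoff_distance=0.5, max_consecutive_failures=50)
        run = run_sumd(engine, lig, site, top, cfg)
        assert run.terminated_reason is TerminationReason.STEP_LIMIT
        assert run.n_propagated_windows == 4

    def test_no_frame_from_rejected_attempts(self):
        script = [12.0, 9.0, 4.0] + [4.0] * 5
        engine, top, lig, site = make_scripted_engine(script, start_distance=10.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        # frame provenance only names retained steps, in order
        assert run.frame_provenance == sorted(run.frame_provenance)
        retained_steps = {r.step_index for r in run.step_log if r.productive}
        assert set(run.frame_provenance) <= retained_steps
        # rejected window ended at 12 Å; no retained frame shows that distance
        from sumdkit import com_distance

        for f in run.retained_trajectory.frames:
            assert com_distance(f, lig, site, top) < 11.0

    def test_audit_log_matches_retained_frames(self):
        """Replaying the retained trajectory reproduces logged checkpoint distances."""
        from sumdkit import com_distance

        script = [9.0, 7.0, 4.0] + [4.0] * 5
        engine, top, lig, site = make_scripted_engine(script, start_distance=10.0)
        run = run_sumd(engine, lig, site, top, _cfg())
        frames_by_time = {round(f.time, 6): f for f in run.retained_trajectory.frames}
        for rec in run.step_log:
            if not rec.productive:
                continue
            for t, d in zip(rec.checkpoint_times, rec.checkpoint_distances):
                frame = frames_by_time[round(t, 6)]
                assert com_distance(frame, lig, site, top) == pytest.approx(d, abs=1e-6)
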