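"""Design enumeration and trajectory kinematics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

import gravityprior as gp
from gravityprior.stimulus_design import (
    BALL_MASS,
    DRAG_COEFF,
    G_EARTH,
    OCCLUSION_WINDOWS,
)


class TestBuildDesign:
    def test_default_totals(self):
        d = gp.build_design()
        assert len(d) == 1344
        per_block = d.groupby("block").size()
        assert per_block.loc[[1, 2, 3]].tolist() == [320, 320, 320]
        assert per_block.loc[4] == 384

    def test_single_repetition_totals(self):
        d = gp.build_design(1, 1)
        assert len(d) == 136  # 3*40 + 16
        assert (d[d.block < 4].groupby("block").size() == 40).all()

    def test_block4_gravities(self):
        d = gp.build_design()
        assert set(d[d.block == 4]["gravity_multiple"]) == {1.0, -1.0}

    @pytest.mark.parametrize("reps", [(0, 1), (1, 0), (-3, 8)])
    def test_nonpositive_repetitions_rejected(self, reps):
        with pytest.raises(ValueError):
            gp.build_design(*reps)

    def test_shuffle_is_seeded_permutation(self):
        d = gp.build_design(1, 1)
        s1 = gp.shuffle_design(d, 7)
        s2 = gp.shuffle_design(d, 7)
        assert s1.equals(s2)
        assert not s1.equals(d)
        assert len(s1.merge(d)) == len(d)


class TestBallistic:
    def test_symmetric_parabola(self):
        cond = gp.StimulusCondition(1.0, 4.905, 3.0, "Long")
        state = gp.ballistic_state(cond, 1.0)
        assert state.y == pytest.approx(0.0, abs=1e-12)
        assert state.vy == pytest.approx(-4.905)
        assert gp.flight_time(cond) == pytest.approx(1.0)

    def test_initial_condition(self):
        cond = gp.StimulusCondition(1.15, 6.0, 4.0, "Short")
        state = gp.ballistic_state(cond, 0.0)
        assert (state.x, state.y, state.vy) == (0.0, 0.0, 6.0)

    def test_against_ode_integration(self):
        cond = gp.StimulusCondition(0.7, 6.0, 3.0, "Long")
        g = cond.g_magnitude
        sol = solve_ivp(
            lambda t, s: [s[2], s[3], 0.0, -g],
            (0, 0.5), [0, 0, 3.0, 6.0], rtol=1e-10, atol=1e-12,
        )
        state = gp.ballistic_state(cond, 0.5)
        assert state.x == pytest.approx(sol.y[0, -1], abs=1e-7)
        assert state.y == pytest.approx(sol.y[1, -1], abs=1e-7)

    @given(st.floats(0.05, 0.95))
    def test_height_symmetric_about_apex(self, frac):
        cond = gp.StimulusCondition(1.3, 4.5, 3.0, "Long")
        T = gp.flight_time(cond)
        y1 = gp.ballistic_state(cond, frac * T).y
        y2 = gp.ballistic_state(cond, (1 - frac) * T).y
        assert y1 == pytest.approx(y2, abs=1e-10)
        assert gp.ballistic_state(cond, 0.5 * T).y >= y1

    def test_negative_time_rejected(self):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, "Long")
        with pytest.raises(ValueError):
            gp.ballistic_state(cond, -0.1)


class TestDrag:
    def test_matches_ode_integration(self):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, "Long")
        g, k = cond.g_magnitude, DRAG_COEFF / BALL_MASS
        sol = solve_ivp(
            lambda t, s: [s[2], s[3], -k * s[2], -g - k * s[3]],
            (0, 0.7), [0, 0, 3.0, 4.5], rtol=1e-11, atol=1e-13,
        )
        state = gp.drag_state(cond, 0.7)
        assert state.x == pytest.approx(sol.y[0, -1], abs=1e-8)
        assert state.y == pytest.approx(sol.y[1, -1], abs=1e-8)
        assert state.vy == pytest.approx(sol.y[3, -1], abs=1e-8)

    @pytest.mark.parametrize("t", [0.1, 0.45, 0.9])
    def test_drag_free_limit(self, t):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, "Long")
        weak = gp.drag_state(cond, t, drag_coeff=1e-8)
        free = gp.ballistic_state(cond, t)
        assert weak.y == pytest.approx(free.y, abs=1e-6)
        assert weak.x == pytest.approx(free.x, abs=1e-6)

    def test_initial_condition(self):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, "Long")
        state = gp.drag_state(cond, 0.0)
        assert (state.x, state.y) == (0.0, 0.0)

    def test_drag_shortens_flight(self):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, "Long")
        assert gp.flight_time(cond, "drag") < gp.flight_time(cond, "ballistic")

    def test_flight_time_differences_small_on_grid(self):
        # a few ms to ~0.02 s over the stimulus grid
        for g in (0.7, 1.0, 1.3):
            for vyi in (4.5, 6.0):
                cond = gp.StimulusCondition(g, vyi, 3.0, "Long")
                tb = gp.flight_time(cond, "ballistic")
                td = gp.flight_time(cond, "drag")
                assert abs(td - tb) < 0.05 * tb


class TestFlightTime:
    @pytest.mark.parametrize(
        "gmul,vyi,expected",
        [(1.0, 4.905, 1.0), (0.7, 6.0, 2 * 6.0 / (0.7 * G_EARTH))],
    )
    def test_ballistic_closed_form(self, gmul, vyi, expected):
        cond = gp.StimulusCondition(gmul, vyi, 3.0, "Long")
        assert gp.flight_time(cond) == pytest.approx(expected, rel=1e-12)

    def test_inverted_gravity_mirrors_1g(self):
        up = gp.StimulusCondition(-1.0, 4.5, 3.0, "Long")
        down = gp.StimulusCondition(1.0, 4.5, 3.0, "Long")
        assert gp.flight_time(up) == gp.flight_time(down)

    def test_full_grid_matches_2v_over_g(self):
        for _, row in gp.build_design(1, 1).iterrows():
            cond = gp.StimulusCondition(
                row.gravity_multiple, row.vyi, row.vxi, row.occlusion_class
            )
            assert gp.flight_time(cond) == pytest.approx(
                2 * row.vyi / cond.g_magnitude, rel=1e-14
            )


class TestMakeTrial:
    def test_apex_disappearance(self):
        cond = gp.StimulusCondition(1.0, 4.905, 3.0, "Long")
        trial = gp.make_trial(cond, 0.5)
        assert trial.vy_at_disappear == pytest.approx(0.0, abs=1e-12)
        assert trial.dy_at_disappear == pytest.approx(4.905**2 / (2 * G_EARTH))
        assert trial.alpha_at_disappear == pytest.approx(np.pi / 2)

    def test_short_occlusion_closed_form(self):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, "Short")
        trial = gp.make_trial(cond, 0.75)
        T = gp.flight_time(cond)
        expected_dy = 4.5 * 0.75 * T - 0.5 * G_EARTH * (0.75 * T) ** 2
        assert trial.dy_at_disappear == pytest.approx(expected_dy)
        assert trial.t_occluded == pytest.approx(0.25 * T)

    @pytest.mark.parametrize(
        "occ,frac", [("Long", 0.49), ("Long", 0.56), ("Short", 0.70), ("Short", 0.81)]
    )
    def test_fraction_outside_window_rejected(self, occ, frac):
        cond = gp.StimulusCondition(1.0, 4.5, 3.0, occ)
        with pytest.raises(ValueError):
            gp.make_trial(cond, frac)

    @given(
        gmul=st.sampled_from([0.7, 0.85, 1.0, 1.15, 1.3, -1.0]),
        vyi=st.sampled_from([4.5, 6.0]),
        occ=st.sampled_from(["Long", "Short"]),
        u=st.floats(0, 1),
    )
    def test_trialspec_invariants(self, gmul, vyi, occ, u):
        lo, hi = OCCLUSION_WINDOWS[occ]
        cond = gp.StimulusCondition(gmul, vyi, 3.0, occ)
        trial = gp.make_trial(cond, lo + u * (hi - lo))
        assert 0 < trial.t_disappear < trial.t_flight
        assert trial.t_occluded == trial.t_flight - trial.t_disappear
        assert trial.dy_at_disappear >= 0
        assert trial.vtan_at_disappear >= abs(trial.vy_at_disappear) - 1e-12
        assert trial.vy_at_disappear >= -1e-12  # disappears at or after the apex


class TestTrialTable:
    def test_matches_single_trial_path(self, midpoint_trials):
        row = midpoint_trials.iloc[17]
        cond = gp.StimulusCondition(
            row.gravity_multiple, row.vyi, row.vxi, row.occlusion_class
        )
        trial = gp.make_trial(cond, row.occlusion_fraction)
        assert row.dy == pytest.approx(trial.dy_at_disappear)
        assert row.vy == pytest.approx(trial.vy_at_disappear)
        assert row.vtan == pytest.approx(trial.vtan_at_disappear)
        assert row.t_occluded == pytest.approx(trial.t_occluded)

    def test_uniform_fractions_stay_in_window(self, small_design):
        t = gp.trial_table(small_design, fractions="uniform", seed=3)
        for occ, (lo, hi) in OCCLUSION_WINDOWS.items():
            frac = t.loc[t.occlusion_class == occ, "occlusion_fraction"]
            assert frac.between(lo, hi).all()

    def test_explicit_fractions_validated(self, small_design):
        frac = np.full(len(small_design), 0.6)
        with pytest.raises(ValueError):
            gp.trial_table(small_design, fractions=frac)
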