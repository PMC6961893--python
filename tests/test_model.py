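"""Unit and property tests for the verticality-estimator dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svvkit import model
from svvkit.model import (
    ModelParams,
    ModelState,
    apply_noise_attenuation,
    linearized_asymptote,
    retinal_slip,
    simulate,
    step,
    trial_protocol,
)

GIA = np.array([0.0, 0.0, 1.0])


class TestRetinalSlip:
    @pytest.mark.parametrize(
        "vis, omega, expected",
        [
            ((16, 0, 0), (0, 0, 0), (16, 0, 0)),
            ((5, 0, 0), (5, 0, 0), (0, 0, 0)),
            ((16, 0, 0), (10.3, 0, 0), (5.7, 0, 0)),
        ],
    )
    def test_componentwise_subtraction(self, vis, omega, expected):
        np.testing.assert_allclose(retinal_slip(vis, omega), expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            retinal_slip((np.nan, 0, 0), (0, 0, 0))

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=3),
        st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, vis, omega):
        out = retinal_slip(vis, omega)
        np.testing.assert_allclose(out, np.asarray(vis) - np.asarray(omega))


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(t_s=0.0)
        with pytest.raises(ValueError):
            ModelParams(ko=-0.1)

    @pytest.mark.parametrize(
        "noise, ko_expected, go_expected",
        [(0.0, 0.11, 0.16), (0.25, 0.0825, 0.12), (0.8, 0.022, 0.032)],
    )
    def test_noise_attenuation_scales_visual_gains_only(self, noise, ko_expected, go_expected):
        p = apply_noise_attenuation(ModelParams(), noise)
        assert p.ko == pytest.approx(ko_expected)
        assert p.go == pytest.approx(go_expected)
        assert (p.kv, p.gv, p.kf, p.t_vs, p.t_s) == (0.2, 0.43, 0.0, 15.0, 0.74)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_noise_attenuation_domain(self, bad):
        with pytest.raises(ValueError):
            apply_noise_attenuation(ModelParams(), bad)


class TestStep:
    def test_aligned_rest_state_is_fixed_point(self):
        state = ModelState(vs=np.zeros(3), g=GIA.copy())
        new = step(state, (np.zeros(3), np.zeros(3), GIA), ModelParams(), 1 / 30)
        np.testing.assert_allclose(new.vs, 0.0, atol=1e-15)
        np.testing.assert_allclose(new.g, GIA, atol=1e-15)

    def test_rejects_non_positive_dt(self):
        state = ModelState(vs=np.zeros(3), g=GIA.copy())
        with pytest.raises(ValueError):
            step(state, (np.zeros(3), np.zeros(3), GIA), ModelParams(), 0.0)

    def test_rotation_feedback_inert_at_zero_gain(self):
        # kf = 0 (the published value): a tilted G must evolve identically to
        # an integrator in which the GIA x G storage term is absent, which is
        # the closed-form linear storage solution when vision is the only input
        p = ModelParams()  # kf = 0
        tilted = np.array([0.0, np.sin(0.1), np.cos(0.1)])
        state = ModelState(vs=np.array([1.0, 0.0, 0.0]), g=tilted)
        dt = 1 / 30
        new = step(state, (np.array([16.0, 0, 0]), np.zeros(3), GIA), p, dt)
        # storage is a scalar linear ODE along x when kf = 0:
        # dvs/dt = ko/(1+go)*vis - lam*vs, lam = ko/(1+go) + 1/t_vs
        lam = p.ko / (1 + p.go) + 1 / p.t_vs
        drive = p.ko / (1 + p.go) * 16.0
        vs_exact = drive / lam + (1.0 - drive / lam) * np.exp(-lam * dt)
        assert new.vs[0] == pytest.approx(vs_exact, rel=1e-9)

    def test_step_halving_richardson(self):
        """One step vs two half-steps differ by O(dt^2) overall error order."""
        p = ModelParams()
        inp = (np.array([16.0, 0, 0]), np.zeros(3), GIA)
        state = ModelState(vs=np.zeros(3), g=GIA.copy())
        fine = state
        for _ in range(1 << 10):
            fine = step(fine, inp, p, 0.5 / (1 << 10))
        errs = []
        for k in (2, 4):
            dt = 0.5 / k
            s = state
            for _ in range(k):
                s = step(s, inp, p, dt)
            errs.append(np.linalg.norm(np.concatenate([s.vs - fine.vs, s.g - fine.g])))
        # RK4: halving dt should cut the error by about 2^4
        assert errs[1] < errs[0] / 8.0


class TestSimulate:
    def test_zero_visual_input_gives_zero_bias(self):
        res = simulate(trial_protocol(0.0), ModelParams())
        np.testing.assert_allclose(res.bias, 0.0, atol=1e-12)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            model.MotionInput(
                time=np.array([]), vis=np.zeros((0, 3)),
                v=np.zeros((0, 3)), gia=np.zeros((0, 3)),
            )

    def test_bias_starts_at_zero_and_trajectory_lengths_match(self):
        res = simulate(trial_protocol(16.0), ModelParams())
        assert res.bias[0] == 0.0
        n = len(res.time)
        assert res.g.shape == res.omega.shape == res.vs.shape == res.a_hat.shape == (n, 3)
        assert res.bias.shape == (n,)

    def test_asymptote_against_linearized_closed_form(self):
        p = ModelParams()
        res = simulate(trial_protocol(16.0), p)
        theta = linearized_asymptote(16.0, p)
        assert theta == pytest.approx(0.74 * 16 * (0.16 + 1.65) / 2.81, rel=1e-12)
        assert res.bias[-301] == pytest.approx(theta, rel=0.10)  # end of motion

    def test_step_halving_convergence_of_bias(self):
        p = ModelParams()
        res1 = simulate(trial_protocol(16.0, dt=1 / 30), p)
        res2 = simulate(trial_protocol(16.0, dt=1 / 60), p)
        assert np.max(np.abs(res2.bias[::2] - res1.bias)) < 0.01

    def test_gravity_norm_preserved(self):
        for v in (1, 16):
            for noise in (0.0, 0.8):
                p = apply_noise_attenuation(ModelParams(), noise)
                res = simulate(trial_protocol(v), p)
                np.testing.assert_allclose(np.linalg.norm(res.g, axis=1), 1.0, atol=1e-3)
                assert res.max_norm_drift < 1e-3

    def test_direction_symmetry(self):
        p = ModelParams()
        ccw = simulate(trial_protocol(8.0, "CCW"), p)
        cw = simulate(trial_protocol(8.0, "CW"), p)
        np.testing.assert_allclose(cw.bias, -ccw.bias, atol=1e-12)

    def test_bias_monotone_in_velocity(self):
        p = ModelParams()
        finals = [
            simulate(trial_protocol(v), p).bias[-301] for v in (1, 2, 4, 6, 8, 16)
        ]
        assert np.all(np.diff(finals) >= 0)

    def test_bias_monotone_decreasing_in_noise(self):
        finals = [
            simulate(trial_protocol(16.0), apply_noise_attenuation(ModelParams(), q)).bias[-301]
            for q in (0.0, 0.25, 0.5, 0.6, 0.7, 0.8)
        ]
        assert np.all(np.diff(finals) <= 0)

    def test_time_course_saturating(self):
        """During rotation the bias rises monotonically and is concave after
        the initial transient (the saturating approach to the asymptote)."""
        res = simulate(trial_protocol(16.0), ModelParams())
        motion = (res.time >= 12.0) & (res.time <= 40.0)
        b = res.bias[motion]
        assert np.all(np.diff(b) >= -1e-9)
        d2 = np.diff(b, 2)
        assert np.quantile(d2, 0.99) <= 1e-9


class TestBatch:
    def test_batch_matches_single_simulations(self):
        p = ModelParams()
        protos = [trial_protocol(v) for v in (2.0, 16.0)]
        pseq = [apply_noise_attenuation(p, q) for q in (0.0, 0.5)]
        batch = model.simulate_batch(protos, pseq)
        for pr, pp, res in zip(protos, pseq, batch):
            single = simulate(pr, pp)
            np.testing.assert_allclose(res.bias, single.bias, atol=1e-12)
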