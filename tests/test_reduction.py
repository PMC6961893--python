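"""Tests for rebasing, window means, folding and exponential fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svvkit.reduction import (
    direction_test,
    fit_exponential,
    fold_average,
    rebase,
    reduce_cohort,
    trial_window_means,
    window_mean,
)
from svvkit.synthetic import (
    BarTrace,
    DesignGrid,
    generate_cohort_trials,
    make_cohort,
    noiseless_condition_trace,
)


def _trace(angle, subject=1, direction="CCW", velocity=16.0, noise=0.0):
    t = np.arange(1500) / 30.0
    angle = np.broadcast_to(np.asarray(angle, dtype=float), t.shape).copy()
    return BarTrace(
        subject=subject, session=1, trial=1, velocity=velocity, noise=noise,
        direction=direction, time=t, angle=angle,
    )


class TestRebase:
    def test_constant_trace_becomes_zero(self):
        out = rebase(_trace(12.0))
        np.testing.assert_allclose(out.angle, 0.0, atol=1e-12)

    @given(st.floats(-50, 50))
    @settings(max_examples=25, derandomize=True)
    def test_shift_invariance(self, offset):
        rng = np.random.default_rng(0)
        base = _trace(rng.normal(0, 3, 1500))
        shifted = _trace(base.angle + offset)
        np.testing.assert_allclose(
            rebase(shifted).angle, rebase(base).angle, atol=1e-9
        )

    def test_rebased_window_is_zero_mean(self):
        rng = np.random.default_rng(1)
        out = rebase(_trace(rng.normal(0, 5, 1500)))
        w = (out.time >= 5.0) & (out.time <= 10.0)
        assert out.angle[w].mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_window_rejected(self):
        tr = _trace(1.0)
        tr.time = tr.time + 100.0
        with pytest.raises(ValueError):
            rebase(tr)


class TestWindowMean:
    def test_constant(self):
        assert window_mean(_trace(5.0)) == pytest.approx(5.0)
        assert window_mean(_trace(0.0)) == 0.0

    def test_pure_exponential_analytic_oracle(self):
        a, tau = 7.0, 11.4
        t = np.arange(1500) / 30.0
        y = np.where(t >= 10.0, a * (1 - np.exp(-(t - 10.0) / tau)), 0.0)
        # grid-exact expectation: mean over the closed 27-40 s sample window
        idx = np.arange(810, 1201)
        expected = np.mean(a * (1 - np.exp(-(idx / 30.0 - 10.0) / tau)))
        assert window_mean(_trace(y)) == pytest.approx(expected, abs=1e-12)
        # and within discretization error of the continuous-time integral
        cont = a * (1 - tau / 13.0 * (math.exp(-17 / tau) - math.exp(-30 / tau)))
        assert window_mean(_trace(y)) == pytest.approx(cont, abs=1e-3)


class TestFolding:
    def test_mirrored_pair_folds_to_ccw(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 2, 1500)
        ccw = _trace(y, direction="CCW")
        cw = _trace(-y, direction="CW")
        summary = fold_average([ccw, cw])
        np.testing.assert_allclose(summary.trace, rebase(ccw).angle, atol=1e-12)

    def test_all_ccw_is_identity_average(self):
        rng = np.random.default_rng(3)
        traces = [_trace(rng.normal(0, 2, 1500)) for _ in range(4)]
        summary = fold_average(traces)
        manual = np.mean([rebase(tr).angle for tr in traces], axis=0)
        np.testing.assert_allclose(summary.trace, manual, atol=1e-12)

    def test_averaging_reduces_variance(self):
        rng = np.random.default_rng(4)
        traces = []
        for k in range(8):
            d = "CW" if k < 4 else "CCW"
            sign = -1.0 if d == "CW" else 1.0
            traces.append(_trace(sign * 3.0 + rng.normal(0, 1, 1500), direction=d))
        summary = fold_average(traces)
        single_var = 1.0
        resid = summary.trace - 3.0
        assert resid.var() == pytest.approx(single_var / 8, rel=0.25)
        assert summary.n_trials == 8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_average([])


class TestDirectionTest:
    def test_identical_directions_not_significant(self):
        rows = []
        rng = np.random.default_rng(5)
        for s in range(1, 6):
            base = rng.normal(3, 1)
            for d in ("CW", "CCW"):
                rows.append(
                    {"subject": s, "session": 1, "trial": 1, "velocity": 16.0,
                     "noise": 0.0, "direction": d, "window_mean_deg": base}
                )
        import pandas as pd

        res = direction_test(pd.DataFrame(rows))
        assert len(res) == 1
        assert res.t.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not res.significant.any()

    def test_full_design_uses_bonferroni_threshold(self):
        cohort = make_cohort(4, rng=6, tracking_error_sd=1.0)
        traces = generate_cohort_trials(cohort, rng=7)
        res = direction_test(trial_window_means(traces))
        assert len(res) == 33
        assert res.threshold.iloc[0] == pytest.approx(0.05 / 33)


class TestExponentialFit:
    def test_recovers_noiseless_parameters(self):
        t = np.arange(1500) / 30.0
        a, b, c = 7.0, 1 / 11.4, 0.0
        y = np.where(t >= 10.0, a * (1 - np.exp(-b * (t - 10.0))) + c, 0.0)
        fit = fit_exponential(t, y)
        assert fit.success
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.tau == pytest.approx(11.4, rel=1e-6)

    def test_63_percent_identity(self):
        fit_tau = 9.0
        x = 1 / (1 / fit_tau)
        assert 1 - math.exp(-x / fit_tau) == pytest.approx(0.632, abs=1e-3)

    def test_flat_trace_flagged(self):
        t = np.arange(1500) / 30.0
        fit = fit_exponential(t, np.zeros_like(t))
        assert fit.success
        assert abs(fit.a) < 1e-6
        # rate is unconstrained on a flat trace; tau is None when b <= 0
        assert fit.tau is None or fit.tau > 0


class TestPipelineRecovery:
    def test_noise_free_recovery_is_exact(self, grid):
        """Window means of noiseless synthetic subjects equal the generating
        plateaus to numerical precision."""
        cohort = make_cohort(
            2, rng=8, tracking_error_sd=0.0, responsiveness_sd=0.0, intercept_sd=0.0
        )
        for v, p in [(16, 0.0), (1, 0.8), (6, 0.5)]:
            tr = noiseless_condition_trace(v, p)
            wm = window_mean(rebase(tr))
            assert wm == pytest.approx(cohort[0].plateaus[(v, p)], abs=1e-9)

    def test_reduce_cohort_structure(self):
        small = DesignGrid(sessions=1, reps_per_direction=1)
        cohort = make_cohort(2, rng=9)
        traces = generate_cohort_trials(cohort, rng=10, grid=small)
        red = reduce_cohort(traces)
        assert len(red["summaries"]) == 2 * 33
        assert (red["summaries"].n_trials == 2).all()
        assert len(red["grand_means"]) == 33
        assert set(red["grand_traces"]) == set(small.feasible_cells())
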