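"""Behavioral data reduction.

Each trial is rebased to its own 5-10 s pre-motion mean, the primary outcome
is the mean bar angle over the 27-40 s window (maximal, saturated response),
clockwise trials are sign-inverted ("folded") before averaging so that bias is
expressed in the direction of scene rotation, and the grand-mean time course
of the fastest zero-noise condition is summarized by a rising exponential
``Y = a*(1 - exp(-b*x)) + c`` whose 63%-rise time constant is ``1/b``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import ttest_rel

from .synthetic import BarTrace

__all__ = [
    "ConditionSummary",
    "ExpFit",
    "rebase",
    "window_mean",
    "trial_window_means",
    "direction_test",
    "fold_average",
    "fit_exponential",
    "reduce_cohort",
]

REBASE_WINDOW = (5.0, 10.0)
ANALYSIS_WINDOW = (27.0, 40.0)


@dataclass
class ConditionSummary:
    """Folded per-subject-per-condition mean trace and its window mean."""

    subject: int
    velocity: float
    noise: float
    time: np.ndarray
    trace: np.ndarray
    window_mean: float
    n_trials: int


@dataclass
class ExpFit:
    """Parameters of the saturating-exponential fit ``Y = a*(1-exp(-b*x)) + c``."""

    a: float
    b: float
    c: float
    tau: float | None
    sse: float
    success: bool
    message: str = ""


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    # closed interval on the 30 Hz grid (endpoint samples included)
    lo, hi = window
    eps = 1e-9
    return (time >= lo - eps) & (time <= hi + eps)


def rebase(trace: BarTrace) -> BarTrace:
    """Subtract the trial's 5-10 s mean from every sample."""
    mask = _window_mask(trace.time, REBASE_WINDOW)
    if not mask.any():
        raise ValueError("trace does not cover the 5-10 s rebase window")
    return _dc_replace(trace, angle=trace.angle - trace.angle[mask].mean())


def window_mean(trace: BarTrace, window: tuple[float, float] = ANALYSIS_WINDOW) -> float:
    """Mean bar angle over the (inclusive) analysis window, in degrees."""
    mask = _window_mask(trace.time, window)
    if not mask.any():
        raise ValueError(f"trace does not cover the {window} window")
    return float(trace.angle[mask].mean())


def trial_window_means(traces: list[BarTrace]) -> pd.DataFrame:
    """Per-trial rebased window means; the input to the direction test."""
    rows = []
    for tr in traces:
        rows.append(
            {
                "subject": tr.subject, "session": tr.session, "trial": tr.trial,
                "velocity": tr.velocity, "noise": tr.noise, "direction": tr.direction,
                "window_mean_deg": window_mean(rebase(tr)),
            }
        )
    return pd.DataFrame(rows)


def direction_test(per_trial: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-test of |window mean| between rotation directions, per condition.

    For each condition, each subject contributes the mean absolute window mean
    of their CW trials paired with that of their CCW trials; the significance
    threshold is Bonferroni-corrected across conditions (0.05/33 = 0.0015 for
    the full design).
    """
    per_subj = (
        per_trial.assign(abs_mean=lambda d: d["window_mean_deg"].abs())
        .groupby(["velocity", "noise", "subject", "direction"])["abs_mean"]
        .mean()
        .unstack("direction")
    )
    conditions = per_subj.index.droplevel("subject").unique()
    threshold = alpha / len(conditions)
    rows = []
    for v, p in conditions:
        pair = per_subj.loc[(v, p)].dropna()
        if len(pair) < 2:
            raise ValueError("direction test needs at least 2 paired subjects")
        if np.allclose(pair["CW"], pair["CCW"]):
            t, pval = 0.0, 1.0  # identical pairs: no direction effect
        else:
            t, pval = ttest_rel(pair["CW"], pair["CCW"])
        rows.append(
            {"velocity": v, "noise": p, "n": len(pair), "t": float(t),
             "p": float(pval), "threshold": threshold,
             "significant": bool(pval < threshold)}
        )
    return pd.DataFrame(rows)


def fold_average(traces: list[BarTrace]) -> ConditionSummary:
    """Rebase, invert clockwise trials, and average all trials pointwise.

    All traces must belong to one subject and condition.  With the full design
    eight trials are averaged (four inverted CW + four CCW).
    """
    if not traces:
        raise ValueError("no trials to fold")
    first = traces[0]
    stack = []
    for tr in traces:
        if (tr.subject, tr.velocity, tr.noise) != (first.subject, first.velocity, first.noise):
            raise ValueError("fold_average expects one subject-condition group")
        r = rebase(tr)
        stack.append(-r.angle if tr.direction == "CW" else r.angle)
    folded = np.mean(stack, axis=0)
    summary_trace = BarTrace(
        subject=first.subject, session=0, trial=0, velocity=first.velocity,
        noise=first.noise, direction="CCW", time=first.time, angle=folded,
    )
    return ConditionSummary(
        subject=first.subject, velocity=first.velocity, noise=first.noise,
        time=first.time, trace=folded,
        window_mean=window_mean(summary_trace), n_trials=len(traces),
    )


def _exp_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * (1.0 - np.exp(-b * x)) + c


def fit_exponential(
    time: np.ndarray,
    values: np.ndarray,
    motion_onset: float = 10.0,
    window: tuple[float, float] = (10.0, 40.0),
    n_jitters: int = 5,
) -> ExpFit:
    """Least-squares fit of the saturating exponential over the motion window.

    ``x`` is time since motion onset.  Initialization: ``a0`` from the final
    2 s of the window, ``b0 = 0.1 /s``, ``c0 = 0``, plus multiplicative
    multi-start jitters; the best sum-of-squares solution is kept.  The time
    constant ``tau = 1/b`` is the 63.2% rise time of this form and is reported
    only for ``b > 0``.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = _window_mask(time, window)
    if not mask.any():
        raise ValueError("trace does not cover the fit window")
    x = time[mask] - motion_onset
    y = values[mask]

    a0 = float(y[x >= x.max() - 2.0].mean())
    starts = [(a0, 0.1, 0.0)]
    jit = np.random.default_rng(0)
    for _ in range(n_jitters):
        starts.append(
            (
                a0 * jit.lognormal(0.0, 0.5) if a0 != 0.0 else jit.normal(0.0, 1.0),
                0.1 * jit.lognormal(0.0, 0.7),
                jit.normal(0.0, 1.0),
            )
        )

    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _exp_model(x, *p) - y, p0, method="lm",
                ftol=1e-12, xtol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if res.success and (best is None or sse < best[1] - 1e-10):
            best = (res.x, sse)
    if best is None:
        return ExpFit(np.nan, np.nan, np.nan, None, np.nan, False, "all starts failed")
    (a, b, c), sse = best
    tau = 1.0 / b if b > 0 else None
    msg = "" if tau is not None else "non-positive rate; time constant undefined"
    return ExpFit(float(a), float(b), float(c), tau, sse, True, msg)


def reduce_cohort(traces: list[BarTrace]) -> dict:
    """Run the full reduction on a cohort of trials.

    Returns a dict with ``summaries`` (per subject-condition window means),
    ``grand_means`` (across-subject means per condition), ``grand_traces``
    (across-subject folded mean trace per condition) and ``per_trial``
    (rebased per-trial window means for the direction test).
    """
    groups: dict[tuple[int, float, float], list[BarTrace]] = {}
    for tr in traces:
        groups.setdefault((tr.subject, tr.velocity, tr.noise), []).append(tr)
    summaries = [fold_average(g) for g in groups.values()]
    sum_df = pd.DataFrame(
        [
            {"subject": s.subject, "velocity": s.velocity, "noise": s.noise,
             "window_mean_deg": s.window_mean, "n_trials": s.n_trials}
            for s in summaries
        ]
    ).sort_values(["subject", "velocity", "noise"], ignore_index=True)

    grand_traces: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}
    cond_groups: dict[tuple[float, float], list[np.ndarray]] = {}
    time_ref = summaries[0].time
    for s in summaries:
        cond_groups.setdefault((s.velocity, s.noise), []).append(s.trace)
    for cond, arrs in cond_groups.items():
        grand_traces[cond] = (time_ref, np.mean(arrs, axis=0))
    grand_means = (
        sum_df.groupby(["velocity", "noise"], as_index=False)["window_mean_deg"]
        .mean()
        .rename(columns={"window_mean_deg": "grand_mean_deg"})
    )
    return {
        "summaries": sum_df,
        "grand_means": grand_means,
        "grand_traces": grand_traces,
        "per_trial": trial_window_means(traces),
    }
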