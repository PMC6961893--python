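"""Synthetic experimental design and behavioral data.

The raw human data of the verticality study are not available, so this module
generates cohorts with the statistical structure the analysis assumes: the
velocity x noise design grid with its three infeasible cells, 50-s bar-angle
trials sampled at 30 Hz (10 s static / 30 s rotation / 10 s static), a signed
exponential rise of the bar bias during rotation, band-limited residual
tracking noise, between-subject responsiveness spread, and a two-alternative
forced-choice (2AFC) velocity-comparison dataset whose point of subjective
equality (PSE) drifts linearly with noise level.

Condition plateaus come either from the study's published grand-mean table
(``preset="table1"``) or from simulations of the mechanistic model
(``preset="model"``).  Plateaus are window means over the 27-40 s analysis
window, so the generator's exponential amplitude is inflated by the analytic
rise fraction of that window (``amplitude_for_plateau``) to make the reduced
window mean match the preset value in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import model as _model
from .stimulus import BarNoiseSpec, generate_bar_noise

__all__ = [
    "DesignGrid",
    "SubjectProfile",
    "BarTrace",
    "PsychometricSpec",
    "TABLE1_WINDOW_MEANS",
    "build_schedule",
    "amplitude_for_plateau",
    "window_rise_fraction",
    "make_cohort",
    "generate_trial",
    "noiseless_condition_trace",
    "generate_cohort_trials",
    "generate_2afc_dataset",
    "model_preset_plateaus",
    "traces_to_frame",
    "frame_to_traces",
]

#: Published grand-mean bar angle (deg) over the 27-40 s window, per
#: (velocity deg/s, noise fraction) condition; the three infeasible
#: high-velocity/high-noise cells are absent.
TABLE1_WINDOW_MEANS: dict[tuple[float, float], float] = {
    (1, 0.8): 0.4, (1, 0.7): 0.9, (1, 0.6): 1.2, (1, 0.5): 1.3, (1, 0.25): 1.3, (1, 0.0): 1.1,
    (2, 0.8): 0.8, (2, 0.7): 1.3, (2, 0.6): 1.9, (2, 0.5): 2.0, (2, 0.25): 2.0, (2, 0.0): 1.6,
    (4, 0.8): 0.9, (4, 0.7): 1.8, (4, 0.6): 2.2, (4, 0.5): 2.8, (4, 0.25): 2.8, (4, 0.0): 3.1,
    (6, 0.8): 1.2, (6, 0.7): 2.2, (6, 0.6): 2.9, (6, 0.5): 2.8, (6, 0.25): 4.0, (6, 0.0): 3.9,
    (8, 0.7): 2.3, (8, 0.6): 3.4, (8, 0.5): 3.7, (8, 0.25): 3.7, (8, 0.0): 4.7,
    (16, 0.6): 3.4, (16, 0.5): 5.0, (16, 0.25): 5.9, (16, 0.0): 7.0,
}

#: Empirical 63%-rise time constant of the bias in the fastest zero-noise
#: condition (s); used as the generator's default rise time for all cells.
DEFAULT_RISE_TAU = 11.4


@dataclass(frozen=True)
class DesignGrid:
    """The velocity x noise x direction design of the main experiment."""

    velocities: tuple[float, ...] = (1, 2, 4, 6, 8, 16)
    noise_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.6, 0.7, 0.8)
    omitted: tuple[tuple[float, float], ...] = ((16, 0.8), (16, 0.7), (8, 0.8))
    directions: tuple[str, ...] = ("CW", "CCW")
    reps_per_direction: int = 4
    sessions: int = 4
    static_pre_s: float = 10.0
    motion_s: float = 30.0
    static_post_s: float = 10.0
    sample_rate: float = 30.0

    def feasible_cells(self) -> list[tuple[float, float]]:
        omitted = set(self.omitted)
        return [
            (v, p)
            for v in self.velocities
            for p in self.noise_levels
            if (v, p) not in omitted
        ]

    @property
    def duration_s(self) -> float:
        return self.static_pre_s + self.motion_s + self.static_post_s


@dataclass
class SubjectProfile:
    """Generative parameters of one synthetic subject.

    ``plateaus`` maps each feasible condition to its expected 27-40 s window
    mean (deg); ``responsiveness`` multiplies every plateau (between-subject
    spread); ``tracking_error_sd`` is the SD (deg) of the residual,
    imperfectly-corrected bar noise; ``intercept`` is a constant angular
    offset (deg) removed downstream by rebasing.
    """

    subject: int
    plateaus: dict[tuple[float, float], float]
    tau: float = DEFAULT_RISE_TAU
    responsiveness: float = 1.0
    tracking_error_sd: float = 2.0
    intercept: float = 0.0


@dataclass
class BarTrace:
    """One trial's 30 Hz bar-angle time series plus its design labels."""

    subject: int
    session: int
    trial: int
    velocity: float
    noise: float
    direction: str
    time: np.ndarray
    angle: np.ndarray


@dataclass(frozen=True)
class PsychometricSpec:
    """Generative psychometric model of the 2AFC velocity comparison.

    The probability of judging the comparison "faster" than the 6 deg/s
    zero-noise reference is a cumulative Gaussian of the comparison velocity
    about a subject- and noise-dependent PSE:
    ``PSE = pse_intercept + (pse_slope + b_subject) * noise``.
    """

    pse_intercept: float = 6.0
    pse_slope: float = -1.6
    sigma: float = 1.0
    lapse: float = 0.02
    subject_slope_sd: float = 0.5
    velocities: tuple[float, ...] = (3, 4, 5, 6, 7, 8, 9)
    noise_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6)
    reps: int = 16


def build_schedule(
    grid: DesignGrid, rng: np.random.Generator | int, subject: int = 1
) -> pd.DataFrame:
    """Pseudo-random trial schedule for one subject.

    Each session contains every feasible condition x direction the same number
    of times (once with the default grid: 66 trials/session), shuffled within
    session; four sessions give four repetitions per condition per direction,
    264 trials in total.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if grid.reps_per_direction % grid.sessions:
        raise ValueError("reps_per_direction must be divisible by sessions")
    per_session = grid.reps_per_direction // grid.sessions
    rows = []
    for session in range(1, grid.sessions + 1):
        cells = [
            (v, p, d)
            for (v, p) in grid.feasible_cells()
            for d in grid.directions
            for _ in range(per_session)
        ]
        order = rng.permutation(len(cells))
        for trial, k in enumerate(order, start=1):
            v, p, d = cells[k]
            rows.append(
                {"subject": subject, "session": session, "trial": trial,
                 "velocity": v, "noise": p, "direction": d}
            )
    return pd.DataFrame(rows)


def window_rise_fraction(
    tau: float,
    onset: float = 10.0,
    lo: float = 27.0,
    hi: float = 40.0,
    sample_rate: float = 30.0,
) -> float:
    """Mean of ``1 - exp(-(t-onset)/tau)`` over the closed [lo, hi] window.

    Evaluated on the recording grid (inclusive endpoints), matching the
    reduction's window mean exactly; the continuous-time counterpart is
    ``1 - tau/(hi-lo) * (exp(-(lo-onset)/tau) - exp(-(hi-onset)/tau))``.
    """
    if tau <= 0.0:
        raise ValueError("tau must be positive")
    i0 = int(round(lo * sample_rate))
    i1 = int(round(hi * sample_rate))
    t = np.arange(i0, i1 + 1) / sample_rate
    return float(np.mean(1.0 - np.exp(-(t - onset) / tau)))


def amplitude_for_plateau(plateau: float, tau: float = DEFAULT_RISE_TAU) -> float:
    """Exponential amplitude whose 27-40 s window mean equals ``plateau``."""
    return plateau / window_rise_fraction(tau)


def model_preset_plateaus(
    grid: DesignGrid | None = None, params: _model.ModelParams | None = None
) -> dict[tuple[float, float], float]:
    """Condition plateaus predicted by the mechanistic model (27-40 s means)."""
    grid = grid or DesignGrid()
    params = params or _model.ModelParams()
    cells = grid.feasible_cells()
    protocols = [
        _model.trial_protocol(
            v, "CCW", grid.static_pre_s, grid.motion_s, grid.static_post_s,
            dt=1.0 / grid.sample_rate,
        )
        for v, _ in cells
    ]
    pseq = [_model.apply_noise_attenuation(params, p) for _, p in cells]
    results = _model.simulate_batch(protocols, pseq)
    out = {}
    for (v, p), res in zip(cells, results):
        w = (res.time >= 27.0) & (res.time <= 40.0)
        out[(v, p)] = float(res.bias[w].mean())
    return out


def make_cohort(
    n_subjects: int = 10,
    rng: np.random.Generator | int = 0,
    preset: str = "table1",
    tau: float = DEFAULT_RISE_TAU,
    tracking_error_sd: float = 2.0,
    responsiveness_sd: float = 0.4,
    intercept_sd: float = 2.0,
    grid: DesignGrid | None = None,
) -> list[SubjectProfile]:
    """Build a cohort of subject profiles around a plateau preset.

    Responsiveness multipliers are shuffled Gaussian quantile midpoints
    (mean exactly 1, SD ``responsiveness_sd``): a stratified design that
    represents between-subject spread while keeping the cohort mean response
    calibrated to the preset.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if preset == "table1":
        plateaus = dict(TABLE1_WINDOW_MEANS)
    elif preset == "model":
        plateaus = model_preset_plateaus(grid)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    q = (np.arange(n_subjects) + 0.5) / n_subjects
    resp = 1.0 + responsiveness_sd * norm.ppf(q)
    resp = np.clip(rng.permutation(resp), 0.0, None)
    intercepts = rng.normal(0.0, intercept_sd, n_subjects)
    return [
        SubjectProfile(
            subject=i + 1,
            plateaus=plateaus,
            tau=tau,
            responsiveness=float(resp[i]),
            tracking_error_sd=tracking_error_sd,
            intercept=float(intercepts[i]),
        )
        for i in range(n_subjects)
    ]


def _bias_profile(t: np.ndarray, amplitude: float, tau: float, grid: DesignGrid) -> np.ndarray:
    """Unsigned rise-and-decay bias time course (deg)."""
    on = grid.static_pre_s
    off = grid.static_pre_s + grid.motion_s
    bias = np.zeros_like(t)
    rising = (t >= on) & (t < off)
    bias[rising] = amplitude * (1.0 - np.exp(-(t[rising] - on) / tau))
    b_off = amplitude * (1.0 - math.exp(-grid.motion_s / tau))
    after = t >= off
    bias[after] = b_off * np.exp(-(t[after] - off) / tau)
    return bias


def _tracking_residual(
    injected: np.ndarray, target_sd: float, sample_rate: float, tau_track: float = 1.0
) -> np.ndarray:
    """Residual of imperfect noise tracking: low-passed injected noise, rescaled."""
    if target_sd <= 0.0:
        return np.zeros_like(injected)
    alpha = math.exp(-1.0 / (sample_rate * tau_track))
    y = np.empty_like(injected)
    acc = injected[0]
    for i, xi in enumerate(injected):
        acc = alpha * acc + (1.0 - alpha) * xi
        y[i] = acc
    sd = y.std()
    return y * (target_sd / sd) if sd > 0 else y


def generate_trial(
    profile: SubjectProfile,
    velocity: float,
    noise: float,
    direction: str,
    rng: np.random.Generator,
    session: int = 1,
    trial: int = 1,
    bar_noise_spec: BarNoiseSpec | None = None,
    grid: DesignGrid | None = None,
    start_offset: float | None = None,
) -> BarTrace:
    """Generate one trial's bar-angle trace.

    The trace is the direction-signed sum of (a) the initial random bar offset
    (uniform on ±45°) settling with a 2-s exponential as the subject corrects
    it, (b) the exponential bias rise/decay with amplitude
    ``amplitude_for_plateau(plateau) * responsiveness``, and (c) residual
    un-corrected bar noise scaled to the profile's tracking-error SD; a
    constant subject intercept is added unsigned.
    """
    grid = grid or DesignGrid()
    spec = bar_noise_spec or BarNoiseSpec(sample_rate=grid.sample_rate)
    n = int(round(grid.duration_s * grid.sample_rate))
    t = np.arange(n) / grid.sample_rate
    amplitude = (
        amplitude_for_plateau(profile.plateaus[(velocity, noise)], profile.tau)
        * profile.responsiveness
    )
    bias = _bias_profile(t, amplitude, profile.tau, grid)
    if start_offset is None:
        start_offset = float(rng.uniform(-45.0, 45.0))
    settle = start_offset * np.exp(-t / 2.0)
    injected = generate_bar_noise(spec, grid.duration_s, rng)
    residual = _tracking_residual(injected, profile.tracking_error_sd, grid.sample_rate)
    sign = 1.0 if direction == "CCW" else -1.0
    angle = sign * (settle + bias + residual) + profile.intercept
    return BarTrace(
        subject=profile.subject, session=session, trial=trial,
        velocity=velocity, noise=noise, direction=direction, time=t, angle=angle,
    )


def noiseless_condition_trace(
    velocity: float,
    noise: float,
    preset: str = "table1",
    tau: float = DEFAULT_RISE_TAU,
    grid: DesignGrid | None = None,
) -> BarTrace:
    """Deterministic grand-mean bias trace for one condition (no noise terms)."""
    grid = grid or DesignGrid()
    if preset == "table1":
        plateau = TABLE1_WINDOW_MEANS[(velocity, noise)]
    elif preset == "model":
        plateau = model_preset_plateaus(grid)[(velocity, noise)]
    else:
        raise ValueError(f"unknown preset {preset!r}")
    n = int(round(grid.duration_s * grid.sample_rate))
    t = np.arange(n) / grid.sample_rate
    angle = _bias_profile(t, amplitude_for_plateau(plateau, tau), tau, grid)
    return BarTrace(
        subject=0, session=0, trial=0, velocity=velocity, noise=noise,
        direction="CCW", time=t, angle=angle,
    )


def generate_cohort_trials(
    profiles: list[SubjectProfile],
    rng: np.random.Generator | int = 0,
    grid: DesignGrid | None = None,
    bar_noise_spec: BarNoiseSpec | None = None,
) -> list[BarTrace]:
    """Full synthetic experiment: a randomized schedule per subject, one trace per trial."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = grid or DesignGrid()
    traces = []
    for profile in profiles:
        schedule = build_schedule(grid, rng, subject=profile.subject)
        for row in schedule.itertuples(index=False):
            traces.append(
                generate_trial(
                    profile, row.velocity, row.noise, row.direction, rng,
                    session=row.session, trial=row.trial,
                    bar_noise_spec=bar_noise_spec, grid=grid,
                )
            )
    return traces


def generate_2afc_dataset(
    n_subjects: int = 8,
    psychometric: PsychometricSpec | None = None,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Synthetic 2AFC velocity-comparison responses.

    Every (comparison velocity, noise) cell is presented ``reps`` times per
    subject (448 rows per subject with defaults) in randomized order, with the
    reference/comparison presentation order randomized per trial.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    spec = psychometric or PsychometricSpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for s in range(1, n_subjects + 1):
        b_s = rng.normal(0.0, spec.subject_slope_sd)
        cells = [
            (v, p)
            for v in spec.velocities
            for p in spec.noise_levels
            for _ in range(spec.reps)
        ]
        for k in rng.permutation(len(cells)):
            v, p = cells[k]
            pse = spec.pse_intercept + (spec.pse_slope + b_s) * p
            prob = spec.lapse / 2.0 + (1.0 - spec.lapse) * norm.cdf((v - pse) / spec.sigma)
            rows.append(
                {
                    "subject": s,
                    "velocity": v,
                    "noise": p,
                    "order": "cmp-first" if rng.random() < 0.5 else "ref-first",
                    "response": "faster" if rng.random() < prob else "slower",
                }
            )
    return pd.DataFrame(rows)


def traces_to_frame(traces: list[BarTrace]) -> pd.DataFrame:
    """Long-form tidy table: one row per sample."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "subject": tr.subject, "session": tr.session, "trial": tr.trial,
                    "velocity": tr.velocity, "noise": tr.noise,
                    "direction": tr.direction,
                    "time_s": tr.time, "angle_deg": tr.angle,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[BarTrace]:
    """Inverse of :func:`traces_to_frame`."""
    keys = ["subject", "session", "trial", "velocity", "noise", "direction"]
    traces = []
    for key, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("time_s")
        traces.append(
            BarTrace(
                subject=int(key[0]), session=int(key[1]), trial=int(key[2]),
                velocity=float(key[3]), noise=float(key[4]), direction=str(key[5]),
                time=sub["time_s"].to_numpy(), angle=sub["angle_deg"].to_numpy(),
            )
        )
    return traces
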