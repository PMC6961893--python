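"""Internal-model dynamics of visuo-vestibular verticality estimation.

The estimator combines retinal slip with semicircular-canal signals through a
leaky "velocity storage" integrator to infer head angular velocity, and
integrates that velocity to track the direction of gravity.  A somatogravic
feedback loop continuously pulls the internal gravity estimate back toward the
otolith-encoded gravito-inertial acceleration (GIA), so that during sustained
visual roll rotation the perceived vertical tilts toward an equilibrium rather
than drifting without bound.

State variables
---------------
``VS``   3-vector velocity-storage content, in deg/s.
``G``    3-vector internal estimate of the gravity direction (unit norm).

Dynamics (roll-plane protocol: seated, head fixed, visual rotation only)::

    rSL = Vis - Omega                                   (retinal slip)
    dVS/dt = ko*rSL + kv*V - VS/t_vs + kf*(GIA x G)     (velocity storage)
    Omega  = go*rSL + gv*V + VS                         (inferred head velocity)
    dG/dt  = G x Omega_rad - (G - GIA)/t_s              (gravity integration)

The direct visual pathway is algebraically self-referential (``Omega`` depends
on ``rSL`` which depends on ``Omega``); it is resolved exactly each step as
``Omega = (go*Vis + gv*V + VS) / (1 + go)``.  Gains act on deg/s signals; the
rotation of ``G`` uses ``Omega`` converted to rad/s because ``G`` is a
direction vector.  Integration is fixed-step classical Runge-Kutta (RK4) with
the inputs held constant over each step, and ``G`` is renormalized to unit
length after every step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "ModelState",
    "MotionInput",
    "SimulationResult",
    "retinal_slip",
    "infer_head_velocity",
    "apply_noise_attenuation",
    "step",
    "simulate",
    "simulate_batch",
    "trial_protocol",
    "linearized_asymptote",
]

_DEG = np.pi / 180.0
#: default recording / integration grid of the behavioral protocol
DEFAULT_DT = 1.0 / 30.0


@dataclass(frozen=True)
class ModelParams:
    """Gains and time constants of the verticality estimator.

    Parameters
    ----------
    ko : float
        Retinal-slip storage gain (1/s): visual drive into velocity storage.
    kv : float
        Vestibular (canal) storage gain (1/s).
    go : float
        Direct visual gain (dimensionless).
    gv : float
        Direct vestibular gain (dimensionless).
    kf : float
        Rotation-feedback gain on the GIA x G term of the storage integrator.
    t_vs : float
        Velocity-storage leak time constant (s).
    t_s : float
        Somatogravic time constant (s): leak of G toward GIA.
    """

    ko: float = 0.11
    kv: float = 0.2
    go: float = 0.16
    gv: float = 0.43
    kf: float = 0.0
    t_vs: float = 15.0
    t_s: float = 0.74

    def __post_init__(self) -> None:
        if not (self.t_vs > 0.0 and self.t_s > 0.0):
            raise ValueError("time constants t_vs and t_s must be positive")
        for name in ("ko", "kv", "go", "gv", "kf"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"gain {name} must be non-negative")


@dataclass
class ModelState:
    """Instantaneous estimator state: storage content, gravity estimate, time."""

    vs: np.ndarray
    g: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.vs = np.asarray(self.vs, dtype=float).reshape(3)
        self.g = np.asarray(self.g, dtype=float).reshape(3)


@dataclass
class MotionInput:
    """Sensory input series on a uniform time grid.

    ``vis`` is the angular velocity of the visual scene (deg/s), ``v`` the
    vestibular canal signal (deg/s) and ``gia`` the unit gravito-inertial
    acceleration direction, each with shape ``(n, 3)``.
    """

    time: np.ndarray
    vis: np.ndarray
    v: np.ndarray
    gia: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vis = np.asarray(self.vis, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.gia = np.asarray(self.gia, dtype=float)
        n = self.time.shape[0]
        if n == 0:
            raise ValueError("empty protocol")
        for name in ("vis", "v", "gia"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape (n, 3) on the shared grid")
        norms = np.linalg.norm(self.gia, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("gia must be unit magnitude at every sample")

    @property
    def dt(self) -> float:
        if self.time.shape[0] < 2:
            raise ValueError("protocol needs at least two samples")
        return float(self.time[1] - self.time[0])


@dataclass
class SimulationResult:
    """Trajectories of one simulated trial.

    ``bias`` is the signed roll-plane angle (deg) between the gravity estimate
    and the GIA, positive in the direction of positive (counter-clockwise)
    scene rotation about the naso-occipital x axis.  ``a_hat`` is the inferred
    linear acceleration, GIA - G.
    """

    time: np.ndarray
    g: np.ndarray
    omega: np.ndarray
    vs: np.ndarray
    a_hat: np.ndarray
    bias: np.ndarray
    max_norm_drift: float = 0.0


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite input")


def retinal_slip(vis: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Angular velocity of the scene relative to the retina: ``vis - omega``."""
    vis = np.asarray(vis, dtype=float)
    omega = np.asarray(omega, dtype=float)
    _check_finite(vis, omega)
    return vis - omega


def infer_head_velocity(vis, v, vs, params: ModelParams):
    """Resolve the direct-pathway algebra for the inferred head velocity.

    Omega = go*rSL + gv*V + VS with rSL = Vis - Omega gives
    Omega = (go*Vis + gv*V + VS) / (1 + go), exact at every instant.
    """
    return (params.go * np.asarray(vis) + params.gv * np.asarray(v) + np.asarray(vs)) / (
        1.0 + params.go
    )


def apply_noise_attenuation(params: ModelParams, noise_fraction: float) -> ModelParams:
    """Attenuate the visual gains by ``1 - noise_fraction``.

    Visual noise is modelled as down-weighting the visual pathway: both the
    storage gain ``ko`` and the direct gain ``go`` are multiplied by
    ``1 - noise_fraction``; vestibular gains are untouched.
    """
    if not (0.0 <= noise_fraction < 1.0):
        raise ValueError("noise_fraction must lie in [0, 1)")
    s = 1.0 - noise_fraction
    return replace(params, ko=params.ko * s, go=params.go * s)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # manual cross product: np.cross has high overhead on small batches
    return np.stack(
        (
            a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
            a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
            a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
        ),
        axis=-1,
    )


def _deriv(vs, g, vis, v, gia, ko, kv, go, gv, kf, t_vs, t_s):
    """Coupled derivatives; all array args broadcast over leading batch axes."""
    omega = (go * vis + gv * v + vs) / (1.0 + go)
    rsl = vis - omega
    dvs = ko * rsl + kv * v - vs / t_vs + kf * _cross(gia, g)
    dg = _cross(g, omega * _DEG) - (g - gia) / t_s
    return dvs, dg


def _rk4_step(vs, g, vis, v, gia, dt, p):
    k1v, k1g = _deriv(vs, g, vis, v, gia, *p)
    k2v, k2g = _deriv(vs + 0.5 * dt * k1v, g + 0.5 * dt * k1g, vis, v, gia, *p)
    k3v, k3g = _deriv(vs + 0.5 * dt * k2v, g + 0.5 * dt * k2g, vis, v, gia, *p)
    k4v, k4g = _deriv(vs + dt * k3v, g + dt * k3g, vis, v, gia, *p)
    vs_new = vs + (dt / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    g_new = g + (dt / 6.0) * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
    return vs_new, g_new


def _param_tuple(params: ModelParams):
    return (
        params.ko,
        params.kv,
        params.go,
        params.gv,
        params.kf,
        params.t_vs,
        params.t_s,
    )


def step(state: ModelState, input_sample, params: ModelParams, dt: float) -> ModelState:
    """Advance the estimator one RK4 step with the input held constant.

    ``input_sample`` is a ``(vis, v, gia)`` triple of 3-vectors.
    """
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    vis, v, gia = (np.asarray(x, dtype=float).reshape(3) for x in input_sample)
    _check_finite(vis, v, gia, state.vs, state.g)
    vs_new, g_new = _rk4_step(state.vs, state.g, vis, v, gia, dt, _param_tuple(params))
    norm = np.linalg.norm(g_new)
    if abs(norm - 1.0) > 0.05:
        raise RuntimeError("gravity-estimate norm diverged; reduce dt")
    return ModelState(vs=vs_new, g=g_new / norm, t=state.t + dt)


def _integrate(vis, v, gia, param_arrays, dt):
    """Batched RK4 integration.

    ``vis``, ``v``, ``gia``: arrays of shape ``(batch, n, 3)``; parameter
    entries are scalars or ``(batch, 1)`` arrays so that heterogeneous
    conditions integrate in one vectorized pass.  Returns the storage and
    gravity trajectories ``(batch, n, 3)`` and the maximum per-step norm
    drift of G before renormalization.
    """
    b, n, _ = vis.shape
    vs = np.zeros((b, 3))
    g = gia[:, 0, :].copy()
    vs_traj = np.empty((b, n, 3))
    g_traj = np.empty((b, n, 3))
    max_drift = 0.0
    for i in range(n):
        vs_traj[:, i, :] = vs
        g_traj[:, i, :] = g
        if i == n - 1:
            break
        vs, g = _rk4_step(vs, g, vis[:, i, :], v[:, i, :], gia[:, i, :], dt, param_arrays)
        norms = np.sqrt(np.sum(g * g, axis=-1, keepdims=True))
        drift = float(np.max(np.abs(norms - 1.0)))
        if drift > max_drift:
            max_drift = drift
        if max_drift > 0.05:
            raise RuntimeError("gravity-estimate norm diverged; reduce dt")
        g = g / norms
    return vs_traj, g_traj, max_drift


def _roll_bias_deg(g: np.ndarray) -> np.ndarray:
    """Signed angle of G's projection onto the y-z plane, from (0, 0, 1)."""
    return np.degrees(np.arctan2(g[..., 1], g[..., 2]))


def simulate_batch(protocols, params_seq, dt: float | None = None) -> list[SimulationResult]:
    """Simulate several conditions in one vectorized integration pass.

    All protocols must share one time grid; ``params_seq`` supplies one
    ``ModelParams`` per protocol (e.g. per-condition noise-attenuated gains).
    """
    protocols = list(protocols)
    params_seq = list(params_seq)
    if not protocols:
        raise ValueError("empty protocol")
    if len(protocols) != len(params_seq):
        raise ValueError("one ModelParams per protocol required")
    time = protocols[0].time
    for pr in protocols[1:]:
        if pr.time.shape != time.shape or not np.allclose(pr.time, time):
            raise ValueError("all protocols must share one time grid")
    if dt is None:
        dt = protocols[0].dt
    if not dt > 0.0:
        raise ValueError("dt must be positive")

    vis = np.stack([pr.vis for pr in protocols])
    v = np.stack([pr.v for pr in protocols])
    gia = np.stack([pr.gia for pr in protocols])
    cols = [np.array([[getattr(p, f)] for p in params_seq]) for f in (
        "ko", "kv", "go", "gv", "kf", "t_vs", "t_s")]
    vs_traj, g_traj, drift = _integrate(vis, v, gia, tuple(cols), dt)

    results = []
    for i, p in enumerate(params_seq):
        omega = (p.go * vis[i] + p.gv * v[i] + vs_traj[i]) / (1.0 + p.go)
        results.append(
            SimulationResult(
                time=time.copy(),
                g=g_traj[i],
                omega=omega,
                vs=vs_traj[i],
                a_hat=gia[i] - g_traj[i],
                bias=_roll_bias_deg(g_traj[i]),
                max_norm_drift=drift,
            )
        )
    return results


def simulate(protocol: MotionInput, params: ModelParams, dt: float | None = None) -> SimulationResult:
    """Simulate one full protocol from the aligned rest state.

    Initialization: ``G(0) = GIA(0)``, ``VS(0) = 0``, so ``bias(0) = 0``.
    """
    return simulate_batch([protocol], [params], dt=dt)[0]


def trial_protocol(
    velocity_deg_s: float,
    direction: str = "CCW",
    static_pre_s: float = 10.0,
    motion_s: float = 30.0,
    static_post_s: float = 10.0,
    dt: float = DEFAULT_DT,
) -> MotionInput:
    """Build the static/rotation/static visual-roll protocol of one trial.

    The scene rotates about the naso-occipital x axis; CCW is the positive
    rotation sense.  GIA is fixed at (0, 0, 1) (seated, head upright); the
    vestibular signal is zero throughout.
    """
    if direction not in ("CW", "CCW"):
        raise ValueError("direction must be 'CW' or 'CCW'")
    total = static_pre_s + motion_s + static_post_s
    n = int(round(total / dt))
    if n < 2:
        raise ValueError("protocol too short for the requested dt")
    t = np.arange(n) * dt
    sign = 1.0 if direction == "CCW" else -1.0
    vis = np.zeros((n, 3))
    in_motion = (t >= static_pre_s) & (t < static_pre_s + motion_s)
    vis[in_motion, 0] = sign * velocity_deg_s
    v = np.zeros((n, 3))
    gia = np.zeros((n, 3))
    gia[:, 2] = 1.0
    return MotionInput(time=t, vis=vis, v=v, gia=gia)


def linearized_asymptote(velocity_deg_s: float, params: ModelParams) -> float:
    """Small-angle closed form for the steady-state bias, in degrees.

    With no vestibular input and ``kf = 0`` the storage settles at
    ``VS = ko*t_vs*rSL`` and the inferred velocity at
    ``Omega = Vis*(go + ko*t_vs) / (1 + go + ko*t_vs)``; the gravity estimate
    then equilibrates where the somatogravic leak balances rotation, giving
    ``theta = t_s * Omega`` for small angles.
    """
    k = params.go + params.ko * params.t_vs
    return params.t_s * velocity_deg_s * k / (1.0 + k)
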