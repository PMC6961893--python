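"""Annulus dot-field stimulus with velocity-preserving rotational noise.

Noise is injected per dot and per frame: the nominal tangential jump vector of
each dot is rotated in the image plane by an independent angle drawn uniformly
from ±(180·p)° for noise fraction ``p``, then rescaled by the constant
``c(p) = (pi*p) / sin(pi*p)`` so that the expected net angular velocity of the
field is unchanged.  ``c`` is the reciprocal of the mean cosine of the jump
rotation and diverges as ``p -> 1`` (full noise carries no net motion), which
is why the experimental design caps the noise at 80%.

Also provides display-geometry helpers and the band-limited bar-position noise
injected into the verticality indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "AnnulusSpec",
    "NoiseSpec",
    "BarNoiseSpec",
    "DotField",
    "scale_constant",
    "n_dots",
    "visual_angle",
    "sample_dot_field",
    "advance_frame",
    "mean_field_velocity",
    "generate_bar_noise",
]


@dataclass(frozen=True)
class AnnulusSpec:
    """Physical geometry of the projected dot annulus (metres)."""

    inner_diameter: float = 0.48
    outer_diameter: float = 2.44
    dot_density: float = 1460.0
    dot_diameter: float = 0.012
    viewing_distance: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_diameter <= self.outer_diameter):
            raise ValueError("need 0 < inner_diameter <= outer_diameter")
        if self.dot_density < 0.0:
            raise ValueError("dot_density must be non-negative")
        if self.viewing_distance <= 0.0:
            raise ValueError("viewing_distance must be positive")

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0


@dataclass(frozen=True)
class NoiseSpec:
    """Noise fraction and nominal field rotation (deg/s, + = counter-clockwise)."""

    noise_fraction: float = 0.0
    field_velocity: float = 0.0
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_fraction <= 0.8):
            raise ValueError("noise_fraction must lie in [0, 0.8]")
        if self.frame_rate <= 0.0:
            raise ValueError("frame_rate must be positive")


@dataclass(frozen=True)
class BarNoiseSpec:
    """Band-limited noise added to the verticality bar's angular position."""

    bandwidth: tuple[float, float] = (0.0, 0.2)
    target_sd: float = 9.6
    range_limit: float = 35.9
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.target_sd <= 0.0:
            raise ValueError("target_sd must be positive")
        if self.range_limit <= self.target_sd:
            raise ValueError("range_limit must exceed target_sd")
        if not (0.0 <= self.bandwidth[0] < self.bandwidth[1] < self.sample_rate / 2.0):
            raise ValueError("bandwidth must be a valid interval below Nyquist")


@dataclass
class DotField:
    """Dot positions in polar coordinates about the annulus centre.

    After :func:`advance_frame`, ``last_jump_azimuth`` holds each dot's
    realized azimuthal increment (rad) and ``respawned`` marks dots that left
    the annulus and were re-seeded.
    """

    radius: np.ndarray
    azimuth: np.ndarray
    last_jump_azimuth: np.ndarray | None = None
    respawned: np.ndarray | None = None

    def __len__(self) -> int:
        return self.radius.shape[0]


def scale_constant(p: float) -> float:
    """Jump-magnitude rescaling that keeps the mean field velocity at nominal.

    For jump-direction noise uniform on ±(180·p)°, the expected tangential
    component of a unit jump is E[cos(theta)] = sin(pi*p)/(pi*p); the scale
    constant is its reciprocal, c = (pi*p)/sin(pi*p), with c(0) = 1 as the
    continuous limit.  Diverges as p -> 1.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("p must lie in [0, 1): the scale constant diverges at 100% noise")
    if p == 0.0:
        return 1.0
    return math.pi * p / math.sin(math.pi * p)


def n_dots(annulus: AnnulusSpec) -> int:
    """Dot count implied by the annulus area and dot density."""
    area = math.pi * (annulus.outer_radius**2 - annulus.inner_radius**2)
    return int(round(annulus.dot_density * area))


def visual_angle(extent: float, distance: float) -> float:
    """Visual angle (deg) subtended by ``extent`` viewed at ``distance``."""
    if distance <= 0.0:
        raise ValueError("distance must be positive")
    if extent < 0.0:
        raise ValueError("extent must be non-negative")
    return math.degrees(2.0 * math.atan(extent / (2.0 * distance)))


def _sample_annulus(annulus: AnnulusSpec, n: int, rng: np.random.Generator):
    """Uniform-in-area polar samples inside the annulus."""
    r = np.sqrt(rng.uniform(annulus.inner_radius**2, annulus.outer_radius**2, n))
    az = rng.uniform(-math.pi, math.pi, n)
    return r, az


def sample_dot_field(
    annulus: AnnulusSpec, rng: np.random.Generator, n: int | None = None
) -> DotField:
    """Seed a dot field uniformly over the annulus area."""
    if n is None:
        n = n_dots(annulus)
    r, az = _sample_annulus(annulus, n, rng)
    return DotField(radius=r, azimuth=az)


def _wrap(angle: np.ndarray) -> np.ndarray:
    return (angle + math.pi) % (2.0 * math.pi) - math.pi


def advance_frame(
    field: DotField,
    annulus: AnnulusSpec,
    noise: NoiseSpec,
    rng: np.random.Generator,
    rescale: bool = True,
    noise_fraction: float | None = None,
) -> DotField:
    """Advance every dot by one frame of noisy rotation.

    Each dot's nominal tangential jump (arc length ``r * Omega * dt``) is
    rotated in the image plane by an independent uniform angle on ±(180·p)°
    and, when ``rescale`` is true, multiplied by ``scale_constant(p)`` so the
    expected field velocity stays at nominal.  Dots whose jump leaves the
    annulus are respawned uniformly inside it (limited-lifetime style).

    ``noise_fraction`` overrides the spec's value; combined with
    ``rescale=False`` this permits probing the raw (unscaled) noise up to
    p = 1, where the net field motion vanishes.
    """
    p = noise.noise_fraction if noise_fraction is None else noise_fraction
    if not (0.0 <= p <= 1.0):
        raise ValueError("noise fraction must lie in [0, 1]")
    c = scale_constant(p) if rescale else 1.0
    dt = 1.0 / noise.frame_rate

    r, az = field.radius, field.azimuth
    x, y = r * np.cos(az), r * np.sin(az)
    # nominal tangential jump vector for rotation about the centre
    jump_len = r * math.radians(noise.field_velocity) * dt
    jx = -jump_len * np.sin(az)
    jy = jump_len * np.cos(az)
    eta = rng.uniform(-math.pi * p, math.pi * p, len(field))
    ce, se = np.cos(eta), np.sin(eta)
    nx = x + c * (ce * jx - se * jy)
    ny = y + c * (se * jx + ce * jy)

    new_r = np.hypot(nx, ny)
    new_az = np.arctan2(ny, nx)
    daz = _wrap(new_az - az)
    out = (new_r < annulus.inner_radius) | (new_r > annulus.outer_radius)
    if np.any(out):
        new_r[out], new_az[out] = _sample_annulus(annulus, int(out.sum()), rng)
    return DotField(radius=new_r, azimuth=new_az, last_jump_azimuth=daz, respawned=out)


def mean_field_velocity(
    annulus: AnnulusSpec,
    noise: NoiseSpec,
    n_frames: int,
    rng: np.random.Generator,
    field: DotField | None = None,
    rescale: bool = True,
    noise_fraction: float | None = None,
) -> tuple[float, float]:
    """Empirical mean field angular velocity (deg/s) and its standard error.

    Averages the realized azimuthal jump of every surviving (non-respawned)
    dot over ``n_frames`` frames.
    """
    if field is None:
        field = sample_dot_field(annulus, rng)
    jumps = []
    for _ in range(n_frames):
        field = advance_frame(
            field, annulus, noise, rng, rescale=rescale, noise_fraction=noise_fraction
        )
        jumps.append(field.last_jump_azimuth[~field.respawned])
    d = np.degrees(np.concatenate(jumps)) * noise.frame_rate
    return float(d.mean()), float(d.std(ddof=1) / math.sqrt(d.size))


def generate_bar_noise(
    spec: BarNoiseSpec, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Generate one band-limited bar-angle noise trace, in degrees.

    White Gaussian noise is zero-phase low-pass filtered at the band's upper
    edge (4th-order Butterworth, filtered forward and backward), recentred,
    rescaled to the target standard deviation, and clipped to the range limit.
    The white sequence is padded on both sides by several filter time
    constants and only the stationary interior is kept, so the trace is free
    of filter start-up transients.
    """
    if duration <= 0.0:
        raise ValueError("duration must be positive")
    n = int(round(duration * spec.sample_rate))
    if n < 2:
        raise ValueError("duration too short at this sample rate")
    b, a = butter(4, spec.bandwidth[1] / (spec.sample_rate / 2.0), btype="low")
    pad = int(round(3.0 / spec.bandwidth[1] * spec.sample_rate))  # ~several 1/fc
    x = filtfilt(b, a, rng.standard_normal(n + 2 * pad))[pad : pad + n]
    x -= x.mean()
    sd = x.std()
    if sd > 0.0:
        x *= spec.target_sd / sd
    return np.clip(x, -spec.range_limit, spec.range_limit)
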