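"""Wide-field 3D flow-field ("star field") stimulus simulation.

Dots live in 2-D screen-angle coordinates (degrees of visual angle,
x rightward, y upward, origin at fixation).  The "3D" character of the
stimuli is carried by eccentricity-dependent speed and size gradients
that mimic depth, not by a true 3-D point cloud.

Seven conditions are supported: four coherent flows (translational,
circular, radial, spiral), incoherent ``random`` motion, a ``static``
dot scene, and (at the design level) null/fixation periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "FieldGeometry",
    "SpeedProfile",
    "DotFieldState",
    "COHERENT_CONDITIONS",
    "MOTION_CONDITIONS",
    "SPEED_PROFILES",
    "make_field_geometry",
    "default_geometry",
    "dot_speed",
    "dot_size",
    "velocity_field",
    "init_field",
    "step_flow",
    "simulate_clip",
    "summarize_stimulus",
    "frames_to_table",
]

COHERENT_CONDITIONS = ("translational", "circular", "radial", "spiral")
MOTION_CONDITIONS = COHERENT_CONDITIONS + ("random",)
ALL_CONDITIONS = MOTION_CONDITIONS + ("static",)

#: dot lifetime (s) after which a dot is respawned at a random position
DOT_LIFETIME_S = 0.350
#: interval (s) between global direction reversals (and, in the random
#: condition, per-dot direction/speed resampling)
REVERSAL_PERIOD_S = 0.500
#: target dot density, dots per square degree
DEFAULT_DENSITY = 0.04
#: dot angular diameter range (deg) mapped affinely onto eccentricity
DOT_SIZE_RANGE = (0.1, 4.0)


class GeometryError(ValueError):
    """Invalid screen geometry."""


class OutOfFieldError(ValueError):
    """Eccentricity or position outside the stimulated field."""


class UnsupportedConditionError(ValueError):
    """Condition not handled by the requested operation."""


@dataclass(frozen=True)
class FieldGeometry:
    """Flat-screen projection geometry of the wide-field display.

    Angular extents follow flat-screen trigonometry: a point at screen
    offset ``s`` cm seen from ``viewing_distance`` cm subtends
    ``atan(s / viewing_distance)`` degrees.
    """

    viewing_distance_cm: float
    half_width_cm: float
    half_height_cm: float

    def __post_init__(self) -> None:
        for v in (self.viewing_distance_cm, self.half_width_cm, self.half_height_cm):
            if not v > 0:
                raise GeometryError("all geometry lengths must be positive")

    @property
    def h_half_deg(self) -> float:
        return math.degrees(math.atan(self.half_width_cm / self.viewing_distance_cm))

    @property
    def v_half_deg(self) -> float:
        return math.degrees(math.atan(self.half_height_cm / self.viewing_distance_cm))

    @property
    def oblique_half_deg(self) -> float:
        # corner of the flat screen: tangents add in quadrature
        th = math.tan(math.radians(self.h_half_deg))
        tv = math.tan(math.radians(self.v_half_deg))
        return math.degrees(math.atan(math.hypot(th, tv)))

    @property
    def max_eccentricity_deg(self) -> float:
        return self.oblique_half_deg

    def deg_to_cm(self, angle_deg: float) -> float:
        """Screen offset (cm) of a point at ``angle_deg`` from center."""
        return self.viewing_distance_cm * math.tan(math.radians(angle_deg))

    def cm_to_deg(self, offset_cm: float) -> float:
        """Visual angle (deg) of a point at ``offset_cm`` from center."""
        return math.degrees(math.atan(offset_cm / self.viewing_distance_cm))

    def contains(self, xy_deg: np.ndarray) -> np.ndarray:
        """Boolean mask of positions inside the rectangular field."""
        xy = np.atleast_2d(np.asarray(xy_deg, dtype=float))
        return (np.abs(xy[:, 0]) <= self.h_half_deg + 1e-12) & (
            np.abs(xy[:, 1]) <= self.v_half_deg + 1e-12
        )

    @property
    def area_deg2(self) -> float:
        """Field area in square degrees (angle-coordinate rectangle)."""
        return (2 * self.h_half_deg) * (2 * self.v_half_deg)

    def eccentricity(self, x_deg, y_deg) -> np.ndarray | float:
        """True angular eccentricity of a screen point given by its
        per-axis visual angles: atan(hypot(tan x, tan y)).  Unlike the
        naive hypot of the two angles, this never exceeds the oblique
        half-extent (flat-screen trigonometry)."""
        tx = np.tan(np.radians(x_deg))
        ty = np.tan(np.radians(y_deg))
        return np.degrees(np.arctan(np.hypot(tx, ty)))


def make_field_geometry(
    viewing_distance_cm: float, half_width_cm: float, half_height_cm: float
) -> FieldGeometry:
    """Build a :class:`FieldGeometry`; raises :class:`GeometryError` on
    non-positive lengths."""
    return FieldGeometry(viewing_distance_cm, half_width_cm, half_height_cm)


def default_geometry() -> FieldGeometry:
    """The scanner-bore wide-field setup: 20-cm viewing distance with a
    screen subtending +/-34.5 deg horizontally and +/-27.5 deg vertically
    (82 deg full oblique extent)."""
    d = 20.0
    return FieldGeometry(
        viewing_distance_cm=d,
        half_width_cm=d * math.tan(math.radians(34.5)),
        half_height_cm=d * math.tan(math.radians(27.5)),
    )


@dataclass
class SpeedProfile:
    """Eccentricity-dependent dot speed law.

    Speeds grow logarithmically with eccentricity ``e``::

        v(e) = v_min + (v_max - v_min) * ln(1 + e/e0) / ln(1 + e_max/e0)

    with the scale ``e0`` calibrated so that the number-weighted mean
    speed over a uniformly dense rectangular field equals
    ``v_mean_target``.  The calibration is a one-dimensional root find,
    done lazily and cached per geometry.
    """

    v_min: float
    v_max: float
    v_mean_target: float
    scale_param: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.v_min < self.v_mean_target < self.v_max):
            raise ValueError("require 0 < v_min < v_mean_target < v_max")

    def calibrated_scale(self, geometry: FieldGeometry) -> float:
        if self.scale_param is None:
            self.scale_param = _calibrate_scale(self, geometry)
        return self.scale_param


#: the three speed tiers used in the event-related experiment
SPEED_PROFILES = {
    "low": SpeedProfile(1.0, 20.0, 18.0),
    "mid": SpeedProfile(5.0, 50.0, 30.0),
    "high": SpeedProfile(10.0, 70.0, 50.0),
}


def _speed_law(ecc: np.ndarray, profile: SpeedProfile, e0: float, e_max: float) -> np.ndarray:
    ecc = np.asarray(ecc, dtype=float)
    span = profile.v_max - profile.v_min
    return profile.v_min + span * np.log1p(ecc / e0) / np.log1p(e_max / e0)


def _uniform_field_mean_speed(
    profile: SpeedProfile, e0: float, geometry: FieldGeometry, n: int = 257
) -> float:
    """Mean of the speed law over a uniform rectangular field (tensor
    trapezoid quadrature in screen-angle coordinates)."""
    x = np.linspace(-geometry.h_half_deg, geometry.h_half_deg, n)
    y = np.linspace(-geometry.v_half_deg, geometry.v_half_deg, n)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    v = _speed_law(geometry.eccentricity(xx, yy), profile, e0, geometry.max_eccentricity_deg)
    return float(np.trapezoid(np.trapezoid(v, y, axis=1), x) / geometry.area_deg2)


def _calibrate_scale(profile: SpeedProfile, geometry: FieldGeometry) -> float:
    """Solve for e0 such that the uniform-field mean speed hits
    v_mean_target.  Mean speed decreases monotonically in e0 (small e0
    -> law saturates near v_max almost everywhere)."""

    def objective(log_e0: float) -> float:
        return (
            _uniform_field_mean_speed(profile, 10.0**log_e0, geometry)
            - profile.v_mean_target
        )

    lo, hi = -9.0, 6.0
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        # the law is concave, so its uniform-field mean is bounded below
        # by the linear (e0 -> inf) limit; a target below that limit is
        # unattainable and the nearest (quasi-linear) law is used
        import warnings

        warnings.warn(
            f"mean speed {profile.v_mean_target} deg/s unattainable by the "
            f"logarithmic law (closest achievable "
            f"{_uniform_field_mean_speed(profile, 10.0**hi, geometry):.2f}); "
            "using the quasi-linear limit",
            stacklevel=2,
        )
        return 10.0**hi
    return 10.0 ** brentq(objective, lo, hi, xtol=1e-12)


def _check_in_field_ecc(ecc: np.ndarray, geometry: FieldGeometry) -> np.ndarray:
    ecc = np.asarray(ecc, dtype=float)
    if np.any(ecc < 0) or np.any(ecc > geometry.max_eccentricity_deg + 1e-9):
        raise OutOfFieldError("eccentricity outside the stimulated field")
    return ecc


def dot_speed(
    eccentricity_deg, profile: SpeedProfile, geometry: FieldGeometry
) -> np.ndarray | float:
    """Speed (deg/s) of a dot at the given eccentricity under the
    calibrated logarithmic law.  Scalar in, scalar out."""
    ecc = _check_in_field_ecc(eccentricity_deg, geometry)
    e0 = profile.calibrated_scale(geometry)
    v = _speed_law(ecc, profile, e0, geometry.max_eccentricity_deg)
    return float(v) if np.isscalar(eccentricity_deg) else v


def dot_size(eccentricity_deg, geometry: FieldGeometry) -> np.ndarray | float:
    """Dot angular diameter (deg): affine map of eccentricity from
    [0, e_max] onto [0.1, 4.0] deg."""
    ecc = _check_in_field_ecc(eccentricity_deg, geometry)
    lo, hi = DOT_SIZE_RANGE
    s = lo + (hi - lo) * ecc / geometry.max_eccentricity_deg
    return float(s) if np.isscalar(eccentricity_deg) else s


def velocity_field(
    position_deg,
    condition: str,
    direction_sign: int,
    profile: SpeedProfile,
    geometry: FieldGeometry,
    spiral_angle_deg: float = 45.0,
) -> np.ndarray:
    """Coherent-flow velocity (deg/s) at one or more screen positions.

    translational -> horizontal (sign: +1 rightward); circular -> tangent
    to the circle through the position (+1 counterclockwise); radial ->
    along the radius (+1 outward); spiral -> radial and tangential
    components mixed at ``spiral_angle_deg``.  At the exact center the
    circular/radial/spiral direction is the zero vector.
    """
    if condition not in COHERENT_CONDITIONS:
        raise UnsupportedConditionError(
            f"velocity_field only defines coherent flows, not {condition!r}"
        )
    pos = np.atleast_2d(np.asarray(position_deg, dtype=float))
    ecc = geometry.eccentricity(pos[:, 0], pos[:, 1])
    speed = dot_speed(ecc, profile, geometry)
    r = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        radial_u = np.where(r[:, None] > 0, pos / r[:, None], 0.0)
    tangent_u = np.stack([-radial_u[:, 1], radial_u[:, 0]], axis=1)

    if condition == "translational":
        unit = np.tile([1.0, 0.0], (pos.shape[0], 1))
    elif condition == "circular":
        unit = tangent_u
    elif condition == "radial":
        unit = radial_u
    else:  # spiral
        a = math.radians(spiral_angle_deg)
        unit = math.cos(a) * radial_u + math.sin(a) * tangent_u

    vel = direction_sign * speed[:, None] * unit
    return vel[0] if np.asarray(position_deg).ndim == 1 else vel


@dataclass
class DotFieldState:
    """Instantaneous dot field for one condition.

    Arrays are parallel over dots.  ``speed`` and ``size`` are the
    per-dot values fixed at (re)birth for translational/circular dots;
    radial/spiral dots re-read the speed law at their current
    eccentricity every frame (dots accelerate along the radius).
    """

    condition: str
    geometry: FieldGeometry
    profile: SpeedProfile
    positions: np.ndarray  # (n, 2) deg
    velocities: np.ndarray  # (n, 2) deg/s
    sizes: np.ndarray  # (n,) deg
    ages: np.ndarray  # (n,) s
    birth_eccentricity: np.ndarray  # (n,) deg
    direction_sign: int = 1
    sim_time: float = 0.0
    density_target: float = DEFAULT_DENSITY
    spiral_angle_deg: float = 45.0
    # per-dot speed for the random condition (resampled every 500 ms)
    random_speeds: np.ndarray | None = None
    random_dirs: np.ndarray | None = None

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]

    @property
    def density(self) -> float:
        return self.n_dots / self.geometry.area_deg2


def _spawn_positions(n: int, geometry: FieldGeometry, rng: np.random.Generator) -> np.ndarray:
    x = rng.uniform(-geometry.h_half_deg, geometry.h_half_deg, size=n)
    y = rng.uniform(-geometry.v_half_deg, geometry.v_half_deg, size=n)
    return np.stack([x, y], axis=1)


def _coherent_velocities(state: DotFieldState) -> np.ndarray:
    """Current-frame velocities for a coherent condition."""
    cond = state.condition
    pos = state.positions
    r = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        radial_u = np.where(r[:, None] > 0, pos / r[:, None], 0.0)
    tangent_u = np.stack([-radial_u[:, 1], radial_u[:, 0]], axis=1)

    if cond in ("translational", "circular"):
        # constant per-dot speed fixed at birth eccentricity
        speed = _speed_law(
            state.birth_eccentricity,
            state.profile,
            state.profile.calibrated_scale(state.geometry),
            state.geometry.max_eccentricity_deg,
        )
    else:  # radial, spiral: speed follows the current eccentricity
        ecc = state.geometry.eccentricity(pos[:, 0], pos[:, 1])
        speed = dot_speed(ecc, state.profile, state.geometry)

    if cond == "translational":
        unit = np.tile([1.0, 0.0], (pos.shape[0], 1))
    elif cond == "circular":
        unit = tangent_u
    elif cond == "radial":
        unit = radial_u
    else:
        a = math.radians(state.spiral_angle_deg)
        unit = math.cos(a) * radial_u + math.sin(a) * tangent_u
    return state.direction_sign * speed[:, None] * unit


def init_field(
    condition: str,
    geometry: FieldGeometry | None = None,
    profile: SpeedProfile | None = None,
    density: float = DEFAULT_DENSITY,
    seed: int = 0,
    direction_sign: int = 1,
    spiral_angle_deg: float = 45.0,
) -> DotFieldState:
    """Create a fresh dot field at sim_time 0.

    Ages are initialised uniformly over [0, lifetime) so that respawns
    are desynchronised from the first frame, as they would be in a
    steady-state display.
    """
    if condition not in ALL_CONDITIONS:
        raise UnsupportedConditionError(f"unknown condition {condition!r}")
    geometry = geometry or default_geometry()
    profile = profile or SPEED_PROFILES["low"]
    rng = np.random.default_rng(seed)
    n = int(round(density * geometry.area_deg2))
    pos = _spawn_positions(n, geometry, rng)
    ecc = geometry.eccentricity(pos[:, 0], pos[:, 1])
    state = DotFieldState(
        condition=condition,
        geometry=geometry,
        profile=profile,
        positions=pos,
        velocities=np.zeros((n, 2)),
        sizes=np.asarray(dot_size(ecc, geometry)),
        ages=rng.uniform(0.0, DOT_LIFETIME_S, size=n),
        birth_eccentricity=ecc,
        direction_sign=direction_sign,
        density_target=density,
        spiral_angle_deg=spiral_angle_deg,
    )
    if condition == "random":
        state.random_dirs = rng.uniform(0.0, 2 * np.pi, size=n)
        state.random_speeds = rng.uniform(profile.v_min, profile.v_max, size=n)
    if condition != "static":
        state.velocities = _current_velocities(state)
    return state


def _current_velocities(state: DotFieldState) -> np.ndarray:
    if state.condition == "static":
        return np.zeros_like(state.positions)
    if state.condition == "random":
        d = state.random_dirs
        return state.random_speeds[:, None] * np.stack([np.cos(d), np.sin(d)], axis=1)
    return _coherent_velocities(state)


def step_flow(state: DotFieldState, dt: float, rng: np.random.Generator) -> DotFieldState:
    """Advance the dot field by one frame of duration ``dt`` seconds.

    Event order within a step: (1) flip the global direction sign (or
    resample random-condition directions/speeds) if the step crosses a
    500-ms boundary; (2) advance positions (exact rotation for circular
    dots, explicit Euler otherwise); (3) age dots, respawn those past
    the 350-ms lifetime or outside the field.  The static condition only
    advances sim_time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = replace(
        state,
        positions=state.positions.copy(),
        velocities=state.velocities.copy(),
        sizes=state.sizes.copy(),
        ages=state.ages.copy(),
        birth_eccentricity=state.birth_eccentricity.copy(),
        random_speeds=None if state.random_speeds is None else state.random_speeds.copy(),
        random_dirs=None if state.random_dirs is None else state.random_dirs.copy(),
    )
    t0, t1 = s.sim_time, s.sim_time + dt
    s.sim_time = t1
    if s.condition == "static":
        return s

    eps = 1e-9
    crossed = math.floor(t1 / REVERSAL_PERIOD_S + eps) > math.floor(
        t0 / REVERSAL_PERIOD_S + eps
    )
    if crossed:
        if s.condition == "random":
            n = s.n_dots
            s.random_dirs = rng.uniform(0.0, 2 * np.pi, size=n)
            s.random_speeds = rng.uniform(s.profile.v_min, s.profile.v_max, size=n)
        else:
            s.direction_sign = -s.direction_sign

    # --- advance positions ---
    if s.condition == "circular":
        ecc = np.hypot(s.positions[:, 0], s.positions[:, 1])
        speed = _speed_law(
            s.birth_eccentricity,
            s.profile,
            s.profile.calibrated_scale(s.geometry),
            s.geometry.max_eccentricity_deg,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            dtheta = np.where(ecc > 0, s.direction_sign * speed * dt / ecc, 0.0)
        c, sn = np.cos(dtheta), np.sin(dtheta)
        x, y = s.positions[:, 0], s.positions[:, 1]
        s.positions = np.stack([c * x - sn * y, sn * x + c * y], axis=1)
    else:
        s.velocities = _current_velocities(s)
        s.positions = s.positions + s.velocities * dt

    s.ages = s.ages + dt

    # --- respawn expired / escaped dots ---
    dead = (s.ages > DOT_LIFETIME_S + eps) | ~s.geometry.contains(s.positions)
    n_dead = int(dead.sum())
    if n_dead:
        new_pos = _spawn_positions(n_dead, s.geometry, rng)
        new_ecc = s.geometry.eccentricity(new_pos[:, 0], new_pos[:, 1])
        s.positions[dead] = new_pos
        s.ages[dead] = 0.0
        s.birth_eccentricity[dead] = new_ecc
        s.sizes[dead] = dot_size(new_ecc, s.geometry)
        if s.condition == "random":
            s.random_dirs[dead] = rng.uniform(0.0, 2 * np.pi, size=n_dead)
            s.random_speeds[dead] = rng.uniform(
                s.profile.v_min, s.profile.v_max, size=n_dead
            )

    s.velocities = _current_velocities(s)
    return s


def simulate_clip(
    condition: str,
    duration_s: float = 3.0,
    dt: float = 1.0 / 60.0,
    seed: int = 0,
    geometry: FieldGeometry | None = None,
    profile: SpeedProfile | None = None,
    density: float = DEFAULT_DENSITY,
) -> list[DotFieldState]:
    """Simulate a clip and return the list of frames.

    A clip of duration T at frame interval dt has round(T/dt) frames at
    times 0, dt, ..., T - dt (the frame at T belongs to the next clip).
    """
    state = init_field(condition, geometry, profile, density, seed=seed)
    rng = np.random.default_rng(seed + 1)
    frames = [state]
    n_steps = int(round(duration_s / dt)) - 1
    for _ in range(n_steps):
        state = step_flow(state, dt, rng)
        frames.append(state)
    return frames


def summarize_stimulus(frames: Sequence[DotFieldState]) -> dict:
    """Empirical statistics of a simulated clip.

    Returns mean density (dots/deg^2), number-weighted mean speed
    (deg/s), maximum dot age (s), and the times (s) at which the global
    direction sign flipped.
    """
    if len(frames) == 0:
        raise ValueError("summarize_stimulus requires at least one frame")
    densities = [f.density for f in frames]
    speeds = np.concatenate(
        [np.hypot(f.velocities[:, 0], f.velocities[:, 1]) for f in frames]
    )
    max_age = max(float(f.ages.max()) for f in frames)
    reversal_times = [
        f1.sim_time
        for f0, f1 in zip(frames[:-1], frames[1:])
        if f1.direction_sign != f0.direction_sign
    ]
    return {
        "mean_density": float(np.mean(densities)),
        "mean_speed": float(np.mean(speeds)),
        "max_age": max_age,
        "reversal_times": reversal_times,
    }


def frames_to_table(frames: Sequence[DotFieldState]) -> pd.DataFrame:
    """Flatten a clip into a tidy per-dot frame table (one row per dot
    per frame): t, x_deg, y_deg, vx, vy, size_deg, age."""
    recs = []
    for f in frames:
        n = f.n_dots
        recs.append(
            pd.DataFrame(
                {
                    "t": np.full(n, f.sim_time),
                    "x_deg": f.positions[:, 0],
                    "y_deg": f.positions[:, 1],
                    "vx": f.velocities[:, 0],
                    "vy": f.velocities[:, 1],
                    "size_deg": f.sizes,
                    "age": f.ages,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)
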