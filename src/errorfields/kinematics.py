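"""Reference kinematics for planar reaching in the angle-angle display plane.

The task is a goal-directed reach between two on-screen targets.  The screen
shows a plot of shoulder rotation against elbow flexion/extension, so the
"screen plane" and the joint-angle plane are related by a per-axis affine
calibration (cm per radian plus an offset).  All positions, errors and
torque components in this package live in the screen plane, in centimeters.

The ideal movement is a straight line from start to target traversed with
the minimum-jerk speed profile

    x(t) = x0 + (xT - x0) * (10 s^3 - 15 s^4 + 6 s^5),   s = t / td,

which starts and ends at rest and arrives at the target at the ideal
duration ``td`` (1.5 s by default, with targets 15 cm apart).

Deviations from the reference are resolved into an *extent* component along
the start-to-target direction (a timing/progress error) and a
*perpendicular* component orthogonal to it (a path-shape error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ReachSpec",
    "Trajectory",
    "ErrorSample",
    "AffineCalibration",
    "minimum_jerk_position",
    "minimum_jerk_trajectory",
    "angle_to_screen",
    "screen_to_angle",
    "decompose_error",
    "default_reach_specs",
]

#: Default ideal reach duration in seconds.
DEFAULT_TD = 1.5
#: Default start-to-target distance on the display, cm.
DEFAULT_REACH_LENGTH = 15.0
#: Default control/logging sample period, seconds (100 Hz).
DEFAULT_DT = 0.01


def _as_point(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"{name} must be a 2-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite, got {a}")
    return a


@dataclass(frozen=True)
class ReachSpec:
    """Geometry and timing of one reference reach.

    Parameters
    ----------
    x0, xT
        Start and target positions on the display, cm.
    td
        Ideal movement duration, seconds.
    direction_id
        Integer label of the movement direction (0, 1, 2 in the default
        three-direction protocol).
    """

    x0: np.ndarray
    xT: np.ndarray
    td: float = DEFAULT_TD
    direction_id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "x0", _as_point(self.x0, "x0"))
        object.__setattr__(self, "xT", _as_point(self.xT, "xT"))
        if not (np.isfinite(self.td) and self.td > 0):
            raise ValueError(f"td must be positive and finite, got {self.td}")
        if self.length == 0:
            raise ValueError("zero-length reach: x0 and xT coincide")

    @property
    def length(self) -> float:
        """Start-to-target distance, cm."""
        return float(np.linalg.norm(self.xT - self.x0))

    @property
    def u_hat(self) -> np.ndarray:
        """Unit vector pointing from start to target (extent axis)."""
        return (self.xT - self.x0) / self.length

    @property
    def n_hat(self) -> np.ndarray:
        """Unit normal, +90 deg counter-clockwise from ``u_hat``."""
        u = self.u_hat
        return np.array([-u[1], u[0]])


@dataclass
class Trajectory:
    """Sampled path through the display plane.

    ``times`` starts at 0 and increases strictly; ``points`` has one 2-vector
    per time.  ``joint_states`` optionally carries the corresponding
    (shoulder, elbow) angles in radians.
    """

    times: np.ndarray
    points: np.ndarray
    joint_states: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.times.ndim != 1 or self.points.shape != (self.times.size, 2):
            raise ValueError("times must be 1-D and points (n, 2) with matching n")
        if self.times.size == 0 or self.times[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.joint_states is not None:
            self.joint_states = np.asarray(self.joint_states, dtype=float)
            if self.joint_states.shape != self.points.shape:
                raise ValueError("joint_states must match points in shape")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ErrorSample:
    """Time-stamped error decomposed along a reach's axes.

    ``extent`` is signed displacement along the start-to-target direction
    (positive toward/past the target relative to the reference) and
    ``perpendicular`` is signed displacement on the counter-clockwise side
    of that direction; both in cm.
    """

    t: float
    extent: float
    perpendicular: float
    direction_id: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.t) and np.isfinite(self.extent)
                and np.isfinite(self.perpendicular)):
            raise ValueError("ErrorSample fields must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.extent, self.perpendicular))


@dataclass(frozen=True)
class AffineCalibration:
    """Per-axis affine map from joint angles (rad) to screen position (cm).

    screen = scale * angles + offset, applied axis-wise; ``scale`` is in
    cm/rad.  The map must be invertible (both scales nonzero).
    """

    scale: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0]))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        object.__setattr__(self, "scale", _as_point(self.scale, "scale"))
        object.__setattr__(self, "offset", _as_point(self.offset, "offset"))
        if np.any(self.scale == 0.0):
            raise ValueError("singular calibration: zero scale on an axis")

    def to_screen(self, joints) -> np.ndarray:
        return self.scale * np.asarray(joints, dtype=float) + self.offset

    def to_angles(self, point) -> np.ndarray:
        return (np.asarray(point, dtype=float) - self.offset) / self.scale


def minimum_jerk_position(spec: ReachSpec, t) -> np.ndarray:
    """Reference position at time ``t`` (scalar or array), clamped to [0, td].

    For ``t > td`` the reference rests at the target; for ``t`` in [0, td] it
    follows the minimum-jerk polynomial along the straight start-to-target
    segment.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    s = np.clip(t / spec.td, 0.0, 1.0)
    shape = s**3 * (10.0 + s * (-15.0 + 6.0 * s))
    disp = np.multiply.outer(shape, spec.xT - spec.x0)
    return spec.x0 + disp


def minimum_jerk_trajectory(spec: ReachSpec, dt: float = DEFAULT_DT) -> Trajectory:
    """Sample the reference on a regular grid covering [0, td].

    The grid step is ``dt``; the final grid point is td itself (appended when
    td is not an integer multiple of dt), so the trajectory always ends
    exactly at the target.
    """
    if not (np.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    if dt >= spec.td:
        raise ValueError(f"dt={dt} must be smaller than td={spec.td}")
    n_steps = int(round(spec.td / dt))
    times = np.arange(n_steps + 1) * dt
    if times[-1] < spec.td - 1e-12:
        times = np.append(times, spec.td)
    else:
        times[-1] = spec.td
    return Trajectory(times=times, points=minimum_jerk_position(spec, times))


def angle_to_screen(joints, calibration: AffineCalibration) -> np.ndarray:
    """Map a (shoulder, elbow) joint state to its on-screen cursor position."""
    return calibration.to_screen(joints)


def screen_to_angle(point, calibration: AffineCalibration) -> np.ndarray:
    """Inverse of :func:`angle_to_screen`."""
    return calibration.to_angles(point)


def decompose_error(actual, spec: ReachSpec, t: float) -> ErrorSample:
    """Resolve the deviation from the reference into extent/perpendicular.

    The error vector is ``actual - minimum_jerk_position(spec, t)``; its
    projection on the start-to-target unit vector is the extent component and
    the projection on the counter-clockwise normal is the perpendicular
    component.  The decomposition is an isometry:
    extent^2 + perpendicular^2 = |error|^2.
    """
    actual = _as_point(actual, "actual")
    eps = actual - minimum_jerk_position(spec, float(t))
    return ErrorSample(
        t=float(t),
        extent=float(eps @ spec.u_hat),
        perpendicular=float(eps @ spec.n_hat),
        direction_id=spec.direction_id,
    )


def default_reach_specs(
    length: float = DEFAULT_REACH_LENGTH,
    td: float = DEFAULT_TD,
    headings_deg: Sequence[float] = (0.0, 120.0, 240.0),
) -> tuple[ReachSpec, ...]:
    """Three outward reaches from the origin at evenly spaced headings.

    The movement directions of the protocol are not pinned by the task
    geometry; evenly spaced headings give balanced, linearly independent
    excitation of the visuomotor map.
    """
    specs = []
    for d, ang in enumerate(headings_deg):
        a = np.deg2rad(ang)
        specs.append(
            ReachSpec(
                x0=np.zeros(2),
                xT=length * np.array([np.cos(a), np.sin(a)]),
                td=td,
                direction_id=d,
            )
        )
    return tuple(specs)
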