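"""Haptic error-augmentation torque controllers.

Three modes act on the instantaneous error vector (extent, perpendicular):

* ``NULL`` — no torque (control condition).
* ``EA``  — classic error augmentation, torque proportional to error:
  tau = lambda * eps.
* ``EF``  — the error field: each component is additionally weighted by the
  Gaussian likelihood of that error under the subject's own statistics,
  tau_i = lambda * p_i(eps_i) * eps_i, so repeatable errors are amplified
  while rare/spurious ones are de-emphasized.

Every emitted torque is time-gated (zero from ``force_window`` onward, so
the mover can finish the reach unopposed) and magnitude-capped at
``torque_cap`` with the direction preserved (a safety limit on the vector
norm, not per component).

The scale factor lambda is calibrated per subject from characterization
trials so that the 80th percentile of per-trial uncapped peak torques equals
the 15 Nm cap — i.e. roughly one trial in five would saturate the limiter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .error_model import ErrorStatModel
from .kinematics import ErrorSample

__all__ = [
    "MODES",
    "ControllerConfig",
    "TorqueCommand",
    "compute_torque",
    "estimate_peak_torque",
    "calibrate_lambda",
]

MODES = ("EF", "EA", "NULL")

#: Default safety cap on torque magnitude, Nm.
DEFAULT_TORQUE_CAP = 15.0
#: Default force presentation window, seconds.
DEFAULT_FORCE_WINDOW = 1.5
#: Default calibration percentile and torque level.
DEFAULT_PERCENTILE = 0.80
DEFAULT_LEVEL = 15.0


@dataclass(frozen=True)
class ControllerConfig:
    """Controller mode and scaling.

    ``lambda_scale`` is the augmentation gain lambda: Nm/cm in EA mode; in
    EF mode the error is additionally weighted by a density with units
    1/cm, so there lambda carries units of Nm (the per-subject calibration
    procedure makes the distinction immaterial in practice).
    """

    mode: str = "NULL"
    lambda_scale: float = 1.0
    torque_cap: float = DEFAULT_TORQUE_CAP
    force_window: float = DEFAULT_FORCE_WINDOW

    def __post_init__(self):
        mode = str(self.mode).upper()
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if not (np.isfinite(self.lambda_scale) and self.lambda_scale >= 0):
            raise ValueError("lambda_scale must be >= 0")
        if not (np.isfinite(self.torque_cap) and self.torque_cap > 0):
            raise ValueError("torque_cap must be > 0")
        if not (np.isfinite(self.force_window) and self.force_window > 0):
            raise ValueError("force_window must be > 0")


@dataclass(frozen=True)
class TorqueCommand:
    """Torque in the extent/perpendicular frame of the reach, Nm."""

    extent: float = 0.0
    perpendicular: float = 0.0

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.extent, self.perpendicular))


_ZERO = TorqueCommand(0.0, 0.0)


def _raw_torque(
    cfg: ControllerConfig,
    model: ErrorStatModel | None,
    d: int,
    t: float,
    extent: float,
    perpendicular: float,
) -> tuple[float, float]:
    """Uncapped, ungated torque components for the configured mode."""
    if cfg.mode == "NULL":
        return 0.0, 0.0
    if cfg.mode == "EA":
        return cfg.lambda_scale * extent, cfg.lambda_scale * perpendicular
    if model is None:
        raise ValueError("EF mode requires an ErrorStatModel")
    p_ext = model.likelihood(d, "extent", t, extent)
    p_perp = model.likelihood(d, "perpendicular", t, perpendicular)
    return (
        cfg.lambda_scale * p_ext * extent,
        cfg.lambda_scale * p_perp * perpendicular,
    )


def compute_torque(
    cfg: ControllerConfig,
    model: ErrorStatModel | None,
    d: int,
    t: float,
    err: ErrorSample,
) -> TorqueCommand:
    """Torque command for error ``err`` at time ``t`` of the movement.

    The raw mode-specific torque is time-gated (identically zero for
    ``t >= force_window``) and then capped: if the vector magnitude exceeds
    ``torque_cap`` it is rescaled onto the cap with direction preserved.
    """
    if t >= cfg.force_window or cfg.mode == "NULL":
        return _ZERO
    tx, tn = _raw_torque(cfg, model, d, t, err.extent, err.perpendicular)
    mag = float(np.hypot(tx, tn))
    if mag > cfg.torque_cap:
        scale = cfg.torque_cap / mag
        tx, tn = tx * scale, tn * scale
    return TorqueCommand(tx, tn)


def estimate_peak_torque(
    cfg: ControllerConfig,
    model: ErrorStatModel | None,
    trial_errors: Sequence[ErrorSample],
) -> float:
    """Peak *uncapped* torque magnitude over one trial's error samples.

    Only samples inside the force window contribute (the gate would zero the
    rest).  Used to calibrate lambda, where the saturation behaviour of the
    cap must not hide the underlying torque demand.
    """
    peak = None
    for s in trial_errors:
        if s.t >= cfg.force_window:
            continue
        tx, tn = _raw_torque(cfg, model, s.direction_id, s.t, s.extent, s.perpendicular)
        mag = float(np.hypot(tx, tn))
        peak = mag if peak is None else max(peak, mag)
    if peak is None:
        raise ValueError("trial has no error samples inside the force window")
    return peak


def calibrate_lambda(
    mode: str,
    model: ErrorStatModel | None,
    characterization_trials: Iterable[Sequence[ErrorSample]],
    percentile: float = DEFAULT_PERCENTILE,
    level: float = DEFAULT_LEVEL,
    torque_cap: float = DEFAULT_TORQUE_CAP,
    force_window: float = DEFAULT_FORCE_WINDOW,
) -> float:
    """Choose lambda so the given percentile of peak torques equals ``level``.

    Per-trial uncapped peak torques are computed at lambda = 1; by
    homogeneity the calibrated gain is ``level`` divided by the requested
    quantile (linear interpolation between order statistics) of those peaks.
    The returned lambda is held constant for the whole training phase.

    Raises
    ------
    ValueError
        With fewer than 5 characterization trials, or when the quantile of
        peak torques is zero (degenerate, error-free subject).
    """
    trials = [list(t) for t in characterization_trials]
    if len(trials) < 5:
        raise ValueError(
            f"need at least 5 characterization trials to calibrate, got {len(trials)}"
        )
    unit_cfg = ControllerConfig(
        mode=mode, lambda_scale=1.0, torque_cap=torque_cap, force_window=force_window
    )
    peaks = np.array([estimate_peak_torque(unit_cfg, model, t) for t in trials])
    q = float(np.quantile(peaks, percentile))  # linear interpolation
    if q <= 0.0:
        raise ValueError("all peak torques are zero; cannot calibrate lambda")
    return level / q
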