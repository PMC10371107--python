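"""Synthetic adapting learner and the experiment protocol runner.

The original study trained humans; this module supplies a minimal adapting
stand-in so the whole characterization -> calibration -> training loop can
be exercised and tested without human data.

Model
-----
The task remaps joint angles to cursor position.  The simulated subject
plans a minimum-jerk cursor reach and produces motor commands ``u(t)``
through an internal affine inverse model of the visuomotor map,

    u(t) = A x_ref(t) + b,

where ``A`` (2x2) and ``b`` (2-vector) are the learner's current estimate.
Under the transformed condition the displayed cursor is ``G u + c`` for a
fixed distortion ``(G, c)``; in baseline the cursor shows the commands
directly.  White motor noise is added per sample, and any applied haptic
torque displaces the cursor through a scalar admittance (cm/Nm) — the
stand-in for limb compliance.  Torque at each sample is computed from the
error at the previous sample (one-sample control latency), so the loop is
causal and explicit.

After each trial the map adapts by a retention + error-driven gradient
(LMS) rule on the *experienced* cursor error — the error including any
torque-induced displacement.  This is the standard trial-by-trial linear
state-space adaptation model and produces the exponential error decay that
the analysis stage fits.  Error augmentation therefore influences learning
by physically enlarging the experienced error that drives the update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import controllers as ctl
from . import error_model as em
from .controllers import ControllerConfig, TorqueCommand, calibrate_lambda
from .error_model import ErrorStatModel, characterize
from .kinematics import (
    DEFAULT_DT,
    AffineCalibration,
    ErrorSample,
    ReachSpec,
    Trajectory,
    default_reach_specs,
    minimum_jerk_position,
)

__all__ = [
    "VisuomotorTransform",
    "LearnerState",
    "TrialRecord",
    "SimConfig",
    "ProtocolResult",
    "SubjectResult",
    "execute_trial",
    "update_learner",
    "run_protocol",
    "generate_cohort",
]

#: Divergence guard on the cursor error, cm.
MAX_ERROR_CM = 1e3
#: Half-width of the "proper timing" duration-feedback band, seconds.
DURATION_BAND = 0.15
#: SD of the simulated movement-duration jitter, seconds.
DURATION_JITTER_SD = 0.08
#: Default physiological joint limits, radians (generous planar range).
JOINT_LIMITS = (-2.0 * np.pi, 2.0 * np.pi)

PHASES = ("baseline", "intermittent", "training")


@dataclass(frozen=True)
class VisuomotorTransform:
    """The true cursor map ``y = G u + c`` of the transformed condition.

    Default: a 25 degree rotation composed with mild axis scaling — a
    smooth, everywhere-invertible distortion that produces large,
    direction-dependent initial errors while keeping the symmetric part of
    ``G`` positive definite (so the error-driven learner converges).
    """

    G: np.ndarray = field(
        default_factory=lambda: _rotation(np.deg2rad(25.0)) @ np.diag([1.1, 0.9])
    )
    c: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if G.shape != (2, 2) or c.shape != (2,):
            raise ValueError("G must be 2x2 and c a 2-vector")
        if abs(np.linalg.det(G)) < 1e-12:
            raise ValueError("visuomotor transform must be invertible")
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "c", c)

    def apply(self, u: np.ndarray) -> np.ndarray:
        return u @ self.G.T + self.c


def _rotation(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


@dataclass
class LearnerState:
    """Internal model and noise/compliance parameters of the subject.

    ``A``/``b`` form the internal affine inverse of the visuomotor map
    (naive default: identity — appropriate for baseline feedback).
    ``learning_rate`` scales the per-trial error-gradient step,
    ``retention`` pulls the map back toward the naive default between
    trials, ``motor_noise_sd`` is per-sample white execution noise (cm) and
    ``admittance`` the cursor displacement per unit applied torque (cm/Nm).
    """

    A: np.ndarray = field(default_factory=lambda: np.eye(2))
    b: np.ndarray = field(default_factory=lambda: np.zeros(2))
    learning_rate: float = 0.10
    retention: float = 0.98
    motor_noise_sd: float = 0.3
    admittance: float = 0.08

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2).copy()
        self.b = np.asarray(self.b, dtype=float).reshape(2).copy()
        if not 0.0 <= self.learning_rate < 1.0:
            raise ValueError("learning_rate must be in [0, 1)")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must be in (0, 1]")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if self.admittance < 0:
            raise ValueError("admittance must be >= 0")

    def plan(self, x_ref: np.ndarray) -> np.ndarray:
        """Motor commands for reference cursor positions (n, 2)."""
        return x_ref @ self.A.T + self.b

    def copy(self) -> "LearnerState":
        return LearnerState(
            A=self.A,
            b=self.b,
            learning_rate=self.learning_rate,
            retention=self.retention,
            motor_noise_sd=self.motor_noise_sd,
            admittance=self.admittance,
        )


@dataclass
class TrialRecord:
    """Everything observed on one trial of the protocol."""

    trial_index: int
    phase: str
    spec: ReachSpec
    transformed: bool
    forces_on: bool
    trajectory: Trajectory
    errors: list[ErrorSample]
    torques: list[TorqueCommand]
    duration: float
    duration_feedback: str  # proper | slow | fast

    @property
    def direction_id(self) -> int:
        return self.spec.direction_id

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.forces_on and any(t.magnitude != 0.0 for t in self.torques):
            raise ValueError("forces_on is False but nonzero torques recorded")
        if len(self.errors) != len(self.trajectory):
            raise ValueError("errors must be time-aligned with the trajectory")


@dataclass(frozen=True)
class SimConfig:
    """Protocol layout and sampling configuration."""

    seed: int = 0
    n_baseline: int = 30
    n_intermittent: int = 50
    n_training: int = 70
    intermittent_fraction: float = 0.2
    directions: tuple[ReachSpec, ...] = field(default_factory=default_reach_specs)
    dt: float = DEFAULT_DT
    transform: VisuomotorTransform = field(default_factory=VisuomotorTransform)
    calibration: AffineCalibration = field(default_factory=AffineCalibration)
    sigma_floor: float = em.DEFAULT_SIGMA_FLOOR

    def __post_init__(self):
        for name in ("n_baseline", "n_intermittent", "n_training"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.intermittent_fraction < 1.0:
            raise ValueError("intermittent_fraction must be in (0, 1)")
        if not self.directions:
            raise ValueError("need at least one reach direction")

    @property
    def td(self) -> float:
        return self.directions[0].td


def _duration_feedback(duration: float, td: float) -> str:
    if abs(duration - td) <= DURATION_BAND:
        return "proper"
    return "slow" if duration > td else "fast"


def execute_trial(
    state: LearnerState,
    spec: ReachSpec,
    transformed: bool,
    cfg: ControllerConfig,
    model: ErrorStatModel | None,
    rng: np.random.Generator,
    transform: VisuomotorTransform | None = None,
    dt: float = DEFAULT_DT,
    calibration: AffineCalibration | None = None,
    trial_index: int = 0,
    phase: str = "training",
) -> TrialRecord:
    """Simulate one closed-loop reach and record its full time course.

    The learner's plan is pushed through the (possibly transformed)
    visuomotor map with additive motor noise; when forces are on, each
    sample's torque is computed from the previous sample's error and
    displaces the cursor through the learner's admittance.  Deterministic
    given ``state`` and the generator's state.
    """
    if transform is None:
        transform = VisuomotorTransform()
    if calibration is None:
        calibration = AffineCalibration()
    forces_on = cfg.mode != "NULL" and cfg.lambda_scale > 0.0
    if forces_on and cfg.mode == "EF" and model is None:
        raise ValueError("EF mode with forces on requires an ErrorStatModel")

    n_steps = int(round(spec.td / dt))
    times = np.arange(n_steps + 1) * dt
    x_ref = minimum_jerk_position(spec, times)
    u_cmd = state.plan(x_ref)
    y = transform.apply(u_cmd) if transformed else u_cmd.copy()
    y += rng.normal(0.0, state.motor_noise_sd, size=y.shape)

    u_hat, n_hat = spec.u_hat, spec.n_hat
    d = spec.direction_id
    raw = y - x_ref
    ext = raw @ u_hat
    perp = raw @ n_hat

    errors: list[ErrorSample] = []
    torques: list[TorqueCommand] = []
    if not forces_on:
        if np.max(np.hypot(ext, perp)) > MAX_ERROR_CM:
            raise RuntimeError("unstable configuration: cursor error diverged")
        zero = TorqueCommand(0.0, 0.0)
        for k in range(times.size):
            errors.append(ErrorSample(float(times[k]), float(ext[k]), float(perp[k]), d))
            torques.append(zero)
    else:
        adm = state.admittance
        prev: ErrorSample | None = None
        for k in range(times.size):
            tk = float(times[k])
            if prev is None:
                tau = TorqueCommand(0.0, 0.0)
            else:
                tau = ctl.compute_torque(cfg, model, d, tk, prev)
            e_ext = float(ext[k]) + adm * tau.extent
            e_perp = float(perp[k]) + adm * tau.perpendicular
            if np.hypot(e_ext, e_perp) > MAX_ERROR_CM:
                raise RuntimeError(
                    "unstable admittance loop: cursor error diverged past "
                    f"{MAX_ERROR_CM} cm at t={tk:.3f}s"
                )
            prev = ErrorSample(tk, e_ext, e_perp, d)
            errors.append(prev)
            torques.append(tau)
        # fold the torque displacement back into the recorded cursor path
        disp = np.array(
            [adm * t.extent * u_hat + adm * t.perpendicular * n_hat for t in torques]
        )
        y = y + disp

    joints = calibration.to_angles(u_cmd)
    lo, hi = JOINT_LIMITS
    joints = np.clip(joints, lo, hi)
    traj = Trajectory(times=times, points=y, joint_states=joints)

    duration = spec.td + float(rng.normal(0.0, DURATION_JITTER_SD))
    return TrialRecord(
        trial_index=trial_index,
        phase=phase,
        spec=spec,
        transformed=transformed,
        forces_on=forces_on,
        trajectory=traj,
        errors=errors,
        torques=torques,
        duration=duration,
        duration_feedback=_duration_feedback(duration, spec.td),
    )


def update_learner(state: LearnerState, record: TrialRecord) -> LearnerState:
    """One trial-by-trial adaptation step from the experienced error.

    Retention shrinks the map toward the naive default (identity, zero
    bias); the gradient term is a normalized LMS step computed from the
    time-averaged experienced cursor error over the ideal duration.  The
    update never consults the true visuomotor transform.
    """
    if not record.errors:
        raise ValueError("record has no error samples")
    spec = record.spec
    u_hat, n_hat = spec.u_hat, spec.n_hat
    td = spec.td
    L = spec.length

    samples = [s for s in record.errors if s.t <= td]
    e_xy = np.array(
        [s.extent * u_hat + s.perpendicular * n_hat for s in samples]
    )  # (n, 2)
    x_ref = minimum_jerk_position(spec, np.array([s.t for s in samples]))

    eta = state.learning_rate
    r = state.retention
    grad_b = e_xy.mean(axis=0)
    grad_A = (e_xy.T @ x_ref) / (len(samples) * L**2 / 2.0)

    A_def, b_def = np.eye(2), np.zeros(2)
    new = state.copy()
    new.A = A_def + r * (state.A - A_def) - eta * grad_A
    new.b = b_def + r * (state.b - b_def) - eta * grad_b
    return new


@dataclass
class SubjectResult:
    """Per-subject output of a full protocol run."""

    subject_id: str
    mode: str
    records: list[TrialRecord]
    model: ErrorStatModel | None
    lambda_scale: float | None
    seed: int
    final_state: LearnerState

    def phase_records(self, phase: str) -> list[TrialRecord]:
        return [rec for rec in self.records if rec.phase == phase]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


#: Alias used where the protocol output is consumed as a plain record list.
ProtocolResult = SubjectResult


def _direction_sequence(
    n: int, n_dirs: int, rng: np.random.Generator
) -> np.ndarray:
    """Balanced direction labels: shuffled blocks of all directions."""
    blocks = []
    while sum(len(b) for b in blocks) < n:
        blocks.append(rng.permutation(n_dirs))
    return np.concatenate(blocks)[:n]


def _transformed_slots(
    dir_seq: np.ndarray, fraction: float, n_dirs: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of transformed trials, stratified by direction.

    Exactly ``round(n * fraction)`` trials are transformed in total, spread
    as evenly as possible across directions and placed at random within
    each direction's trials.
    """
    n = dir_seq.size
    total = int(round(n * fraction))
    base, extra = divmod(total, n_dirs)
    counts = np.full(n_dirs, base)
    if extra:
        counts[rng.choice(n_dirs, size=extra, replace=False)] += 1
    mask = np.zeros(n, dtype=bool)
    for d in range(n_dirs):
        idx = np.flatnonzero(dir_seq == d)
        k = min(counts[d], idx.size)
        if k:
            mask[rng.choice(idx, size=k, replace=False)] = True
    return mask


def run_protocol(
    sim: SimConfig,
    learner: LearnerState,
    cfg: ControllerConfig,
    subject_id: str = "S0",
) -> SubjectResult:
    """Run baseline -> intermittent exposure -> characterization -> training.

    Baseline trials use veridical feedback with no forces.  During
    intermittent exposure the visuomotor transformation appears on a random
    one-in-five subset (stratified across directions), still force-free.
    The transformed intermittent trials characterize the subject's error
    statistics and, for EF/EA, calibrate lambda; training then runs with the
    transformation always on and forces per the configured mode.  The
    learner adapts after every trial throughout.
    """
    rng = np.random.default_rng(sim.seed)
    n_dirs = len(sim.directions)
    state = learner.copy()
    records: list[TrialRecord] = []
    null_cfg = ControllerConfig(
        mode="NULL", torque_cap=cfg.torque_cap, force_window=cfg.force_window
    )
    idx = 0

    def do_trial(spec, transformed, trial_cfg, model, phase):
        nonlocal state, idx
        rec = execute_trial(
            state,
            spec,
            transformed,
            trial_cfg,
            model,
            rng,
            transform=sim.transform,
            dt=sim.dt,
            calibration=sim.calibration,
            trial_index=idx,
            phase=phase,
        )
        records.append(rec)
        state = update_learner(state, rec)
        idx += 1
        return rec

    for d in _direction_sequence(sim.n_baseline, n_dirs, rng):
        do_trial(sim.directions[d], False, null_cfg, None, "baseline")

    dir_seq = _direction_sequence(sim.n_intermittent, n_dirs, rng)
    transformed_mask = _transformed_slots(
        dir_seq, sim.intermittent_fraction, n_dirs, rng
    )
    for d, tr in zip(dir_seq, transformed_mask):
        do_trial(sim.directions[d], bool(tr), null_cfg, None, "intermittent")

    char_trials = [
        rec.errors
        for rec in records
        if rec.phase == "intermittent" and rec.transformed
    ]
    model: ErrorStatModel | None = None
    lam: float | None = None
    train_cfg = null_cfg
    if cfg.mode != "NULL":
        model = characterize(char_trials, td=sim.td, sigma_floor=sim.sigma_floor)
        lam = calibrate_lambda(
            cfg.mode,
            model,
            char_trials,
            torque_cap=cfg.torque_cap,
            force_window=cfg.force_window,
        )
        train_cfg = replace(cfg, lambda_scale=lam)

    for d in _direction_sequence(sim.n_training, n_dirs, rng):
        do_trial(sim.directions[d], True, train_cfg, model, "training")

    return SubjectResult(
        subject_id=subject_id,
        mode=cfg.mode,
        records=records,
        model=model,
        lambda_scale=lam,
        seed=sim.seed,
        final_state=state,
    )


def generate_cohort(
    n_per_group: int,
    group_modes: Sequence[str] = ("EF", "EA", "NULL"),
    base_seed: int = 0,
    sim: SimConfig | None = None,
    learning_rate_range: tuple[float, float] = (0.06, 0.16),
    noise_sd_range: tuple[float, float] = (0.2, 0.45),
    map_perturbation_sd: float = 0.05,
) -> dict[str, list[SubjectResult]]:
    """Simulate a cohort: ``n_per_group`` subjects for each controller mode.

    Per-subject heterogeneity enters through the learning rate, the motor
    noise level and a small random perturbation of the initial internal
    map, each drawn from the configured ranges.  Fully reproducible from
    ``base_seed``.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if sim is None:
        sim = SimConfig()
    root = np.random.SeedSequence(base_seed)
    cohort: dict[str, list[SubjectResult]] = {}
    children = root.spawn(len(group_modes) * n_per_group)
    k = 0
    for mode in group_modes:
        mode_key = str(mode).upper()
        subjects = []
        for j in range(n_per_group):
            ss = children[k]
            k += 1
            draw = np.random.default_rng(ss)
            lr = draw.uniform(*learning_rate_range)
            noise = draw.uniform(*noise_sd_range)
            A0 = np.eye(2) + draw.normal(0.0, map_perturbation_sd, size=(2, 2))
            state = LearnerState(A=A0, learning_rate=lr, motor_noise_sd=noise)
            subj_seed = int(ss.generate_state(1)[0] % (2**31))
            subj_sim = replace(sim, seed=subj_seed)
            cfg = ControllerConfig(mode=mode_key)
            subjects.append(
                run_protocol(subj_sim, state, cfg, subject_id=f"{mode_key}_{j:02d}")
            )
        cohort[mode_key] = subjects
    return cohort
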