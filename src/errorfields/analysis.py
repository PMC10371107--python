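"""Learning-curve fitting and group-level statistics.

Performance on each training trial is summarized as the time-averaged
error-vector magnitude over the ideal movement duration.  The trial series
is then described by a three-parameter exponential decay

    y(t) = S + R * exp(-t / tau),        t = trial number,

with S >= 0 the steady-state error, R >= 0 the error reduction and tau > 0
the learning time constant (trials).  Fitting is non-negative least
squares: for any fixed tau the model is linear in (S, R) and solved
exactly by NNLS; tau itself is found by a global scan over a log-spaced
grid followed by bounded 1-D refinement, which keeps the notoriously
ill-identified time constant inspectable (the grid bounds are explicit)
while still resolving it to high precision on clean data.

Group comparisons use Shapiro-Wilk normality checks, the Kruskal-Wallis
omnibus test and Dunn's rank-based pairwise post hoc tests with Sidak
correction.  A distribution-shift measure quantifies, per direction and
component, how far the late-training error ensemble moved from the
early-training ensemble in units of early-training standard deviations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .kinematics import DEFAULT_TD, ErrorSample
from .learner import TrialRecord

__all__ = [
    "LearningCurveFit",
    "ShiftMeasure",
    "trial_error_series",
    "fit_decay",
    "fit_decay_xy",
    "cross_validated_fit",
    "change_in_error",
    "group_compare",
    "shift_measure",
]

#: tau search grid: log-spaced points, in trials.
TAU_GRID = np.geomspace(0.5, 500.0, 200)


@dataclass(frozen=True)
class LearningCurveFit:
    """Parameters of the exponential decay model with its fit quality.

    ``nrmse`` is the root-mean-square residual divided by the range of the
    fitted series (test-set residuals in cross-validation).  ``tau_at_edge``
    flags an unidentifiable time constant (R = 0 or tau pinned to the
    search-grid boundary).
    """

    S: float
    R: float
    tau_trials: float
    nrmse: float
    tau_at_edge: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.S) and self.S >= 0):
            raise ValueError("S must be finite and >= 0")
        if not (np.isfinite(self.R) and self.R >= 0):
            raise ValueError("R must be finite and >= 0")
        if not (np.isfinite(self.tau_trials) and self.tau_trials > 0):
            raise ValueError("tau_trials must be finite and > 0")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.S + self.R * np.exp(-t / self.tau_trials)


@dataclass(frozen=True)
class ShiftMeasure:
    """Early-to-late shift of the error ensemble, in early-SD units."""

    direction_id: int
    component: str
    delta: float


def trial_error_series(records: Sequence[TrialRecord]) -> np.ndarray:
    """One scalar per trial: time-averaged error magnitude over [0, td], cm."""
    records = list(records)
    if not records:
        raise ValueError("no trial records supplied")
    out = np.empty(len(records))
    for k, rec in enumerate(records):
        td = rec.spec.td
        mags = [s.magnitude for s in rec.errors if s.t <= td]
        if not mags:
            raise ValueError(f"trial {rec.trial_index} has no samples in [0, td]")
        out[k] = float(np.mean(mags))
    return out


def _nnls_at_tau(t: np.ndarray, y: np.ndarray, tau: float):
    """Exact (S, R) >= 0 solve at fixed tau; returns (S, R, sse)."""
    X = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
    coef, _ = optimize.nnls(X, y)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_decay_xy(t, y) -> LearningCurveFit:
    """Fit S + R exp(-t/tau) to (t, y) points by NNLS over a tau scan."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if t.size < 3:
        raise ValueError("need at least 3 points to fit the decay model")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in fit input")

    sse_grid = np.array([_nnls_at_tau(t, y, tau)[2] for tau in TAU_GRID])
    k = int(np.argmin(sse_grid))

    # bounded refinement between the neighbouring grid points (log scale)
    lo = TAU_GRID[max(k - 1, 0)]
    hi = TAU_GRID[min(k + 1, TAU_GRID.size - 1)]
    if lo < hi:
        res = optimize.minimize_scalar(
            lambda logtau: _nnls_at_tau(t, y, float(np.exp(logtau)))[2],
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        tau = float(np.exp(res.x))
        if _nnls_at_tau(t, y, tau)[2] > sse_grid[k]:
            tau = float(TAU_GRID[k])
    else:
        tau = float(TAU_GRID[k])

    S, R, sse = _nnls_at_tau(t, y, tau)
    # with R = 0 the time constant is unidentifiable: report the grid edge
    if R == 0.0:
        tau = float(TAU_GRID[0])
    rng_y = float(np.ptp(y))
    rmse = float(np.sqrt(sse / t.size))
    nrmse = rmse / rng_y if rng_y > 0 else rmse
    at_edge = R == 0.0 or tau <= TAU_GRID[0] * (1 + 1e-9) or tau >= TAU_GRID[-1] * (1 - 1e-9)
    return LearningCurveFit(S=S, R=R, tau_trials=tau, nrmse=nrmse, tau_at_edge=at_edge)


def fit_decay(series) -> LearningCurveFit:
    """Fit the decay model to a trial series (t = 0, 1, 2, ...)."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("need a 1-D series of at least 10 trials")
    return fit_decay_xy(np.arange(y.size, dtype=float), y)


def cross_validated_fit(
    subject_series: Sequence[Sequence[float]],
    n_repeats: int = 50,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> list[LearningCurveFit]:
    """Group-level decay fits with leave-one-subject-out cross-validation.

    Returns ``n_subjects + 1`` fits: index 0 pools all subjects, index
    ``j + 1`` omits subject ``j``.  Each fit is repeated ``n_repeats`` times
    on random (1 - test_fraction) subsets of the pooled trial points and
    the repeat with the lowest test NRMSE is retained.  Deterministic given
    ``seed``.
    """
    series = [np.asarray(s, dtype=float) for s in subject_series]
    if len(series) < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)

    def pooled(exclude: int | None):
        ts, ys = [], []
        for j, s in enumerate(series):
            if j == exclude:
                continue
            ts.append(np.arange(s.size, dtype=float))
            ys.append(s)
        return np.concatenate(ts), np.concatenate(ys)

    fits = []
    for exclude in [None] + list(range(len(series))):
        t, y = pooled(exclude)
        n = t.size
        n_test = max(1, int(round(test_fraction * n)))
        best: LearningCurveFit | None = None
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            fit = fit_decay_xy(t[train], y[train])
            resid = y[test] - fit.predict(t[test])
            rng_train = float(np.ptp(y[train]))
            rmse = float(np.sqrt(np.mean(resid**2)))
            test_nrmse = rmse / rng_train if rng_train > 0 else rmse
            cand = LearningCurveFit(
                S=fit.S,
                R=fit.R,
                tau_trials=fit.tau_trials,
                nrmse=test_nrmse,
                tau_at_edge=fit.tau_at_edge,
            )
            if best is None or cand.nrmse < best.nrmse:
                best = cand
        fits.append(best)
    return fits


def change_in_error(series) -> float:
    """Mean of the first five trial errors minus the mean of the last five."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("change_in_error needs at least 10 trials")
    return float(np.mean(y[:5]) - np.mean(y[-5:]))


def _dunn_sidak(groups: Mapping[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based pairwise z tests with Sidak-adjusted p values."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n_g = groups[g].size
        mean_ranks[g] = float(np.mean(ranks[start : start + n_g]))
        sizes[g] = n_g
        start += n_g

    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = float(1.0 - (1.0 - min(p, 1.0)) ** m)
        out.append(
            {"pair": (a, b), "z": float(z), "p_raw": float(p), "p_adj": p_adj}
        )
    return out


def _percent_contrasts(groups: Mapping[str, np.ndarray]) -> list[dict]:
    """Percent differences of group medians and means for every pair."""
    out = []
    for a, b in itertools.combinations(groups, 2):
        row = {"pair": (a, b)}
        for stat_name, fn in (("median", np.median), ("mean", np.mean)):
            va, vb = float(fn(groups[a])), float(fn(groups[b]))
            row[f"{stat_name}_a"] = va
            row[f"{stat_name}_b"] = vb
            row[f"pct_diff_{stat_name}"] = (
                100.0 * (va - vb) / abs(vb) if vb != 0 else float("nan")
            )
        out.append(row)
    return out


def group_compare(per_subject_values: Mapping[str, Sequence[float]]) -> dict:
    """Omnibus and pairwise comparison of a per-subject scalar across groups.

    Runs Shapiro-Wilk per group (motivating the non-parametric omnibus),
    Kruskal-Wallis across groups, and Dunn-Sidak pairwise contrasts, and
    reports percent differences of group medians/means.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in per_subject_values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values identical across groups")

    shapiro = {}
    for g, v in groups.items():
        w, p = stats.shapiro(v)
        shapiro[g] = {"W": float(w), "p": float(p)}
    H, p_omni = stats.kruskal(*groups.values())
    return {
        "groups": {g: v.tolist() for g, v in groups.items()},
        "shapiro": shapiro,
        "kruskal": {
            "H": float(H),
            "p": float(p_omni),
            "df": len(groups) - 1,
        },
        "pairwise": _dunn_sidak(groups),
        "percent_differences": _percent_contrasts(groups),
    }


def shift_measure(
    early: Iterable[ErrorSample],
    late: Iterable[ErrorSample],
    component: str = "extent",
    td: float = DEFAULT_TD,
    n_bins: int = 50,
    sd_floor: float = 1e-9,
) -> ShiftMeasure:
    """Shift of the error distribution from early to late training.

    Both ensembles are binned on a common time grid over [0, td]; in each
    bin the late-minus-early difference in mean error is normalized by the
    early-training SD, and the magnitudes are averaged over bins populated
    by both ensembles.
    """
    early = list(early)
    late = list(late)
    if not early or not late:
        raise ValueError("both ensembles must be non-empty")
    dirs = {s.direction_id for s in early} | {s.direction_id for s in late}
    if len(dirs) != 1:
        raise ValueError(f"ensembles mix directions {sorted(dirs)}")
    if component not in ("extent", "perpendicular"):
        raise ValueError(f"unknown component {component!r}")

    def values(samples):
        t = np.array([s.t for s in samples])
        v = np.array([getattr(s, component) for s in samples])
        keep = t <= td
        return t[keep], v[keep]

    t_e, v_e = values(early)
    t_l, v_l = values(late)
    edges = np.linspace(0.0, td, n_bins + 1)
    bin_e = np.clip(np.digitize(t_e, edges) - 1, 0, n_bins - 1)
    bin_l = np.clip(np.digitize(t_l, edges) - 1, 0, n_bins - 1)

    deltas = []
    for b in range(n_bins):
        ve = v_e[bin_e == b]
        vl = v_l[bin_l == b]
        if ve.size < 2 or vl.size == 0:
            continue
        sd = float(np.std(ve, ddof=1))
        if sd < sd_floor:
            raise ValueError(f"early-training SD below floor in time bin {b}")
        deltas.append(abs(float(np.mean(vl)) - float(np.mean(ve))) / sd)
    if not deltas:
        raise ValueError("no time bin is populated by both ensembles")
    return ShiftMeasure(
        direction_id=dirs.pop(), component=component, delta=float(np.mean(deltas))
    )
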