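"""Statistical characterization of an individual's reaching errors.

From a set of characterization trials (the transformed trials of the
intermittent-exposure phase), the across-trial mean and standard deviation
of each error component are estimated on a common time grid and summarized
by degree-7 polynomials mu(t) and sigma(t), separately for each movement
direction d and each error component i (extent, perpendicular).  These
define a time-varying scalar Gaussian likelihood of error,

    p(eps) = exp(-(eps - mu_{d,t,i})^2 / (2 sigma_{d,t,i}^2))
             / (sigma_{d,t,i} sqrt(2 pi)),

evaluated per component: extent and perpendicular carry separate scalar
densities rather than one joint 2-D density.

Numerical notes: time is rescaled to [0, 1] before polynomial fitting
(degree-7 fits on raw seconds are ill-conditioned), and the evaluated sigma
is floored at ``sigma_floor`` so the density never blows up where a subject
happens to be extremely consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import stats

from .kinematics import DEFAULT_TD, ErrorSample

__all__ = [
    "COMPONENTS",
    "ErrorStatModel",
    "characterize",
    "mu_sigma_at",
    "likelihood",
]

#: Error-vector component names, in storage order.
COMPONENTS = ("extent", "perpendicular")

#: Default polynomial degree for the mu/sigma time courses.
DEFAULT_DEGREE = 7
#: Default number of time bins for the characterization grid.
DEFAULT_N_BINS = 50
#: Default lower bound for the evaluated standard deviation, cm.
DEFAULT_SIGMA_FLOOR = 0.05

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class ErrorStatModel:
    """Per-direction, per-component polynomial error statistics.

    Coefficients are stored in ascending order on normalized time
    s = t / td in [0, 1].  Evaluation clamps t to [0, td] and floors the
    standard deviation at ``sigma_floor``.
    """

    td: float = DEFAULT_TD
    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    degree: int = DEFAULT_DEGREE
    mu_coeffs: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    sigma_coeffs: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isfinite(self.td) and self.td > 0):
            raise ValueError("td must be positive")
        if not (np.isfinite(self.sigma_floor) and self.sigma_floor > 0):
            raise ValueError("sigma_floor must be positive")
        for table in (self.mu_coeffs, self.sigma_coeffs):
            for key, c in table.items():
                c = np.asarray(c, dtype=float)
                if not np.all(np.isfinite(c)):
                    raise ValueError(f"non-finite coefficients for {key}")
                table[key] = c

    @property
    def directions(self) -> tuple[int, ...]:
        return tuple(sorted({d for d, _ in self.mu_coeffs}))

    def _key(self, d: int, component: str) -> tuple[int, str]:
        key = (int(d), component)
        if key not in self.mu_coeffs:
            known = sorted(self.mu_coeffs)
            raise KeyError(
                f"no statistics for direction={d}, component={component!r}; "
                f"model covers {known}"
            )
        return key

    def mu_sigma_at(self, d: int, component: str, t):
        """Evaluate (mu, sigma) at time ``t`` (scalar or array), cm."""
        key = self._key(d, component)
        s = np.clip(np.asarray(t, dtype=float) / self.td, 0.0, 1.0)
        mu = P.polyval(s, self.mu_coeffs[key])
        sigma = np.maximum(P.polyval(s, self.sigma_coeffs[key]), self.sigma_floor)
        if np.ndim(t) == 0:
            return float(mu), float(sigma)
        return mu, sigma

    def likelihood(self, d: int, component: str, t, eps):
        """Scalar Gaussian density of error ``eps`` (cm) at time ``t``."""
        mu, sigma = self.mu_sigma_at(d, component, t)
        if np.ndim(eps) == 0 and np.ndim(t) == 0:
            # scalar fast path: called once per control sample in the loop
            z = (float(eps) - mu) / sigma
            return math.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)
        return stats.norm.pdf(eps, loc=mu, scale=sigma)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "td": self.td,
            "sigma_floor": self.sigma_floor,
            "degree": self.degree,
            "time_rescaling": "s = t / td",
            "mu_coeffs": {
                f"{d}:{c}": coeffs.tolist() for (d, c), coeffs in self.mu_coeffs.items()
            },
            "sigma_coeffs": {
                f"{d}:{c}": coeffs.tolist()
                for (d, c), coeffs in self.sigma_coeffs.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ErrorStatModel":
        def parse(table):
            out = {}
            for key, coeffs in table.items():
                d, c = key.split(":")
                out[(int(d), c)] = np.asarray(coeffs, dtype=float)
            return out

        return cls(
            td=float(doc["td"]),
            sigma_floor=float(doc["sigma_floor"]),
            degree=int(doc["degree"]),
            mu_coeffs=parse(doc["mu_coeffs"]),
            sigma_coeffs=parse(doc["sigma_coeffs"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ErrorStatModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _trial_direction(trial: Sequence[ErrorSample]) -> int:
    dirs = {s.direction_id for s in trial}
    if len(dirs) != 1:
        raise ValueError(f"trial mixes directions {sorted(dirs)}")
    return dirs.pop()


def _bin_trial(trial: Sequence[ErrorSample], centers: np.ndarray) -> np.ndarray:
    """Nearest-sample value of each error component at each bin center.

    Returns an array of shape (2, n_bins): extent row then perpendicular row.
    """
    ts = np.array([s.t for s in trial])
    order = np.argsort(ts, kind="stable")
    ts = ts[order]
    vals = np.array(
        [[trial[k].extent for k in order], [trial[k].perpendicular for k in order]]
    )
    if ts.size == 1:
        return np.repeat(vals, centers.size, axis=1)
    idx = np.searchsorted(ts, centers)
    idx = np.clip(idx, 1, ts.size - 1)
    left_closer = centers - ts[idx - 1] <= ts[idx] - centers
    nearest = np.where(left_closer, idx - 1, idx)
    return vals[:, nearest]


def characterize(
    trials: Iterable[Sequence[ErrorSample]],
    td: float = DEFAULT_TD,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    n_bins: int = DEFAULT_N_BINS,
    degree: int = DEFAULT_DEGREE,
) -> ErrorStatModel:
    """Fit the per-direction polynomial error statistics from trials.

    Parameters
    ----------
    trials
        Characterization trials; each trial is a sequence of
        :class:`~errorfields.kinematics.ErrorSample` from a single movement
        direction, with sample times covering [0, td].
    td
        Ideal movement duration; the statistics are modelled on [0, td].
    sigma_floor
        Lower bound (cm) applied to the evaluated standard deviation.
    n_bins
        Number of uniform time bins of the characterization grid; samples
        are assigned to bin centers by nearest time.
    degree
        Degree of the polynomials fitted to the binned mean and SD curves.

    Raises
    ------
    ValueError
        If any direction has fewer than 2 trials (across-trial SD needs at
        least two observations) or a sample is non-finite.
    """
    by_direction: dict[int, list[Sequence[ErrorSample]]] = {}
    for trial in trials:
        trial = list(trial)
        if not trial:
            raise ValueError("empty trial in characterization set")
        by_direction.setdefault(_trial_direction(trial), []).append(trial)

    if not by_direction:
        raise ValueError("no characterization trials supplied")
    for d, dir_trials in sorted(by_direction.items()):
        if len(dir_trials) < 2:
            raise ValueError(
                f"direction {d} has {len(dir_trials)} trial(s); "
                "need at least 2 for across-trial statistics"
            )

    centers = (np.arange(n_bins) + 0.5) / n_bins * td
    s_grid = centers / td

    model = ErrorStatModel(td=td, sigma_floor=sigma_floor, degree=degree)
    for d, dir_trials in sorted(by_direction.items()):
        # stacked: (n_trials, 2 components, n_bins)
        stacked = np.stack([_bin_trial(trial, centers) for trial in dir_trials])
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0, ddof=1)
        for ci, comp in enumerate(COMPONENTS):
            model.mu_coeffs[(d, comp)] = P.polyfit(s_grid, mean[ci], degree)
            model.sigma_coeffs[(d, comp)] = P.polyfit(s_grid, sd[ci], degree)
    return model


def mu_sigma_at(model: ErrorStatModel, d: int, component: str, t):
    """Module-level convenience for :meth:`ErrorStatModel.mu_sigma_at`."""
    return model.mu_sigma_at(d, component, t)


def likelihood(model: ErrorStatModel, d: int, component: str, t, eps):
    """Module-level convenience for :meth:`ErrorStatModel.likelihood`."""
    return model.likelihood(d, component, t, eps)
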