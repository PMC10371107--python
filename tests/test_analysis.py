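"""Learning-curve fits, group statistics, and the distribution shift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from errorfields import (
    ControllerConfig,
    ErrorSample,
    LearnerState,
    change_in_error,
    cross_validated_fit,
    execute_trial,
    fit_decay,
    group_compare,
    shift_measure,
    trial_error_series,
)
from errorfields.kinematics import default_reach_specs


def make_record(extent, perp, n=20, td=1.5, direction=0):
    """Minimal trial record carrying a constant error, for series tests."""
    spec = default_reach_specs()[direction]
    state = LearnerState(motor_noise_sd=0.0)
    rec = execute_trial(state, spec, False, ControllerConfig(mode="NULL"),
                        None, np.random.default_rng(0))
    rec.errors = [ErrorSample(s.t, extent, perp, direction) for s in rec.errors]
    return rec


class TestTrialErrorSeries:
    def test_zero_errors_give_zero_series(self):
        recs = [make_record(0.0, 0.0) for _ in range(3)]
        np.testing.assert_array_equal(trial_error_series(recs), np.zeros(3))

    def test_constant_error_three_four_gives_five(self):
        recs = [make_record(3.0, 4.0) for _ in range(4)]
        np.testing.assert_allclose(trial_error_series(recs), np.full(4, 5.0))

    def test_homogeneous_scaling(self):
        recs1 = [make_record(1.0, 2.0)]
        recs2 = [make_record(2.0, 4.0)]
        assert trial_error_series(recs2)[0] == pytest.approx(
            2 * trial_error_series(recs1)[0]
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trial_error_series([])


def brute_force_decay_fit(y):
    """Dense (S, R, tau) grid oracle, independent of the NNLS solver."""
    t = np.arange(y.size, dtype=float)
    best = (np.inf, None)
    taus = np.geomspace(0.5, 500, 400)
    s_grid = np.linspace(0, max(y.max(), 1e-9), 200)
    for tau in taus:
        basis = np.exp(-t / tau)
        bb = basis @ basis
        # R solved in closed form (clipped at 0) for every S on the grid
        R = np.clip((basis @ y - s_grid * basis.sum()) / bb, 0.0, None)
        resid = y[None, :] - s_grid[:, None] - R[:, None] * basis[None, :]
        sse = np.sum(resid**2, axis=1)
        k = int(np.argmin(sse))
        if sse[k] < best[0]:
            best = (float(sse[k]), (float(s_grid[k]), float(R[k]), float(tau)))
    return best


class TestFitDecay:
    def test_noiseless_round_trip(self):
        y = 1.0 + 4.0 * np.exp(-np.arange(70) / 10.0)
        fit = fit_decay(y)
        assert fit.S == pytest.approx(1.0, rel=1e-3)
        assert fit.R == pytest.approx(4.0, rel=1e-3)
        assert fit.tau_trials == pytest.approx(10.0, rel=1e-3)
        assert fit.nrmse < 1e-6

    def test_constant_series_degenerate(self):
        fit = fit_decay(np.full(30, 2.5))
        assert fit.S == pytest.approx(2.5)
        assert fit.R == 0.0
        assert fit.tau_at_edge

    def test_increasing_series_forces_nonnegative_R(self):
        y = np.linspace(1.0, 3.0, 30)
        fit = fit_decay(y)
        assert fit.R == 0.0
        assert fit.S == pytest.approx(y.mean(), rel=1e-6)

    def test_matches_brute_force_oracle_on_noisy_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            S, R, tau = rng.uniform(0.5, 2), rng.uniform(1, 5), rng.uniform(3, 40)
            y = S + R * np.exp(-np.arange(40) / tau) + rng.normal(0, 0.15, 40)
            y = np.abs(y)
            fit = fit_decay(y)
            sse_fit = np.sum((y - fit.predict(np.arange(40))) ** 2)
            sse_brute, _ = brute_force_decay_fit(y)
            assert sse_fit <= sse_brute * 1.01

    def test_parameter_recovery_under_noise(self):
        """Median recovery error: S, R within 10%, tau within 25%."""
        rng = np.random.default_rng(7)
        rel = {"S": [], "R": [], "tau": []}
        for _ in range(100):
            S, R, tau = rng.uniform(0.5, 2), rng.uniform(2, 6), rng.uniform(5, 30)
            y = S + R * np.exp(-np.arange(70) / tau) + rng.normal(0, 0.1 * R, 70)
            f = fit_decay(y)
            rel["S"].append(abs(f.S - S) / S)
            rel["R"].append(abs(f.R - R) / R)
            rel["tau"].append(abs(f.tau_trials - tau) / tau)
        assert np.median(rel["S"]) <= 0.10
        assert np.median(rel["R"]) <= 0.10
        assert np.median(rel["tau"]) <= 0.25

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(np.array([1.0, np.nan] + [1.0] * 10))


class TestCrossValidatedFit:
    def test_seven_subjects_give_eight_fits(self):
        rng = np.random.default_rng(0)
        series = [1 + 3 * np.exp(-np.arange(40) / 8) + rng.normal(0, 0.2, 40)
                  for _ in range(7)]
        fits = cross_validated_fit(series, seed=1)
        assert len(fits) == 8

    def test_identical_noiseless_subjects_agree(self):
        y = 1 + 3 * np.exp(-np.arange(40) / 8)
        fits = cross_validated_fit([y.copy() for _ in range(4)], seed=0)
        params = np.array([[f.S, f.R, f.tau_trials] for f in fits])
        np.testing.assert_allclose(params, np.tile(params[0], (len(fits), 1)),
                                   rtol=1e-4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        series = [2 + 2 * np.exp(-np.arange(30) / 6) + rng.normal(0, 0.3, 30)
                  for _ in range(3)]
        a = cross_validated_fit(series, seed=42)
        b = cross_validated_fit(series, seed=42)
        assert [(f.S, f.R, f.tau_trials, f.nrmse) for f in a] == [
            (f.S, f.R, f.tau_trials, f.nrmse) for f in b
        ]


class TestChangeInError:
    def test_worked_toy_series(self):
        series = [10] * 5 + [6] * 10 + [2] * 5
        assert change_in_error(series) == 8.0

    def test_constant_series_is_zero(self):
        assert change_in_error([3.0] * 12) == 0.0

    def test_reversal_negates(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 5, 25)
        assert change_in_error(y[::-1]) == pytest.approx(-change_in_error(y))

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(list(range(10))))
    def test_invariant_to_middle_permutation(self, order):
        y = np.concatenate([[9, 8, 7, 6, 5], np.array(order, float), [4, 3, 2, 1, 0]])
        base = np.concatenate([[9, 8, 7, 6, 5], np.arange(10.0), [4, 3, 2, 1, 0]])
        assert change_in_error(y) == change_in_error(base)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            change_in_error([1.0] * 9)


def kruskal_reference(groups):
    """Hand-rolled Kruskal-Wallis H with tie correction (oracle)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestGroupCompare:
    def test_identical_groups_null_result(self):
        vals = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
        rep = group_compare(vals)
        assert rep["kruskal"]["p"] == pytest.approx(1.0)
        assert all(p["p_adj"] > 0.9 for p in rep["pairwise"])

    def test_separated_groups_detected(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(5, 1, 8)
        rep = group_compare({"lo": a, "hi": b})
        assert rep["kruskal"]["p"] < 0.05

    def test_percent_difference_of_group_means(self):
        rep = group_compare({"EF": [1.0, 1.0, 1.0, 1.001],
                             "Ctrl": [4.0, 4.0, 4.0, 4.001]})
        pct = rep["percent_differences"][0]["pct_diff_mean"]
        assert pct == pytest.approx(-75.0, abs=0.1)  # EF 75% lower

    def test_omnibus_matches_reference_implementation(self, rng):
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(4, 9))
                      for _ in range(3)]
            rep = group_compare({f"g{i}": g for i, g in enumerate(groups)})
            assert rep["kruskal"]["H"] == pytest.approx(
                kruskal_reference(groups), abs=1e-8
            )

    def test_degenerate_all_ties_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0, 1, 1], "b": [1.0, 1, 1]})


def ensemble(mean_fn, sd, n_trials, rng, direction=0, n_t=30):
    out = []
    for _ in range(n_trials):
        for t in np.linspace(0, 1.5, n_t):
            out.append(ErrorSample(float(t), float(mean_fn(t) + rng.normal(0, sd)),
                                   0.0, direction))
    return out


class TestShiftMeasure:
    def test_identical_ensembles_give_zero(self, rng):
        early = ensemble(lambda t: 2.0, 0.5, 20, np.random.default_rng(0))
        m = shift_measure(early, list(early), component="extent")
        assert m.delta == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_shift_everywhere(self):
        """Construct a late ensemble exactly +1 early-SD above the early one."""
        rng = np.random.default_rng(0)
        early = ensemble(lambda t: 1.0, 0.5, 40, rng)
        # shift each late sample by the *empirical* early SD of its time bin
        edges = np.linspace(0, 1.5, 51)
        t_e = np.array([s.t for s in early])
        v_e = np.array([s.extent for s in early])
        bins = np.clip(np.digitize(t_e, edges) - 1, 0, 49)
        sd_by_bin = {b: np.std(v_e[bins == b], ddof=1)
                     for b in np.unique(bins)}
        late = [
            ErrorSample(s.t, s.extent + sd_by_bin[int(np.clip(np.digitize(s.t, edges) - 1, 0, 49))],
                        0.0, 0)
            for s in early
        ]
        # mean shift per bin is exactly one early SD
        m = shift_measure(early, late, component="extent")
        assert m.delta == pytest.approx(1.0, abs=1e-9)

    def test_half_bins_shifted_two_sd_averages_one(self):
        rng = np.random.default_rng(1)
        early = ensemble(lambda t: 0.0, 0.4, 40, rng)
        edges = np.linspace(0, 1.5, 51)
        t_e = np.array([s.t for s in early])
        v_e = np.array([s.extent for s in early])
        bins = np.clip(np.digitize(t_e, edges) - 1, 0, 49)
        sd_by_bin = {b: np.std(v_e[bins == b], ddof=1)
                     for b in np.unique(bins)}
        late = []
        for s in early:
            b = int(np.clip(np.digitize(s.t, edges) - 1, 0, 49))
            shift = 2.0 * sd_by_bin[b] if b % 2 == 0 else 0.0
            late.append(ErrorSample(s.t, s.extent + shift, 0.0, 0))
        m = shift_measure(early, late, component="extent")
        assert m.delta == pytest.approx(1.0, abs=1e-9)

    def test_mixed_directions_rejected(self):
        early = [ErrorSample(0.1, 1.0, 0.0, 0), ErrorSample(0.2, 1.0, 0.0, 0)]
        late = [ErrorSample(0.1, 1.0, 0.0, 1)]
        with pytest.raises(ValueError):
            shift_measure(early, late)

    def test_degenerate_early_sd_rejected(self):
        early = [ErrorSample(t, 1.0, 0.0, 0) for t in (0.1, 0.11, 0.5, 0.51)]
        late = [ErrorSample(0.1, 2.0, 0.0, 0)]
        with pytest.raises(ValueError):
            shift_measure(early, late)
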