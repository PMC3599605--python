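"""Sweeps, intervention comparison, late-outcome convolution, CSV export."""

import numpy as np
import pandas as pd
import pytest

from obesim import (
    LateOutcomeConfig,
    ModelParams,
    State,
    combined_sweep,
    export_csv,
    hazard_recovery_sweep,
    headline_equilibrium,
    integrate,
    late_outcome_risk,
    solve_age_profile,
    univariate_sweep,
)
from obesim.equilibrium import self_consistency
from obesim.scenarios import BETA_HIGH, BETA_LOW


def oracle_prevalence(params, n=1_000_000):
    """Headline stable-branch prevalence by brute-force dense scanning.

    Roots of the self-consistency function are located as midpoints of
    sign-change cells on a very fine grid (no polishing), then the stable
    branch reached from the obesity-free start is chosen by the same
    reachability rule the package uses.
    """
    upper = params.beta * params.N + params.epsilon
    if upper == 0:
        return 0.0
    grid = np.linspace(upper * 1e-9, upper, n + 1)
    g = self_consistency(grid, params)
    idx = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    roots = [(grid[j] + grid[j + 1]) / 2 for j in idx]
    if params.epsilon == 0.0:
        roots = [0.0] + roots
    from obesim import prevalence_given_lambda
    from obesim.equilibrium import _stability_raw
    from obesim.params import InterventionFactors

    stable = []
    for lam in roots:
        i = prevalence_given_lambda(lam, params)
        S = params.mu * params.N / (lam + params.mu)
        _, cls = _stability_raw(S, i * params.N, params, InterventionFactors())
        if cls == "stable":
            stable.append((lam, i))
    if not stable:
        return None
    if params.epsilon == 0.0 and any(i < 1e-12 for _, i in stable):
        return 0.0
    return stable[0][1]


class TestUnivariateSweep:
    def test_unit_multiplier_returns_baseline(self, baseline_params, baseline_equilibrium):
        base_prev = baseline_equilibrium.I_star / baseline_params.N
        for target in ("epsilon", "beta", "inverse_gamma", "sigma"):
            res = univariate_sweep(target, [1.0], baseline_params)
            assert res.curves[0].prevalence[0] == pytest.approx(base_prev, rel=1e-9)

    def test_matches_dense_scan_oracle(self, baseline_params):
        res = univariate_sweep("epsilon", [0.25, 0.5, 1.0, 2.0], baseline_params)
        for mult, prev in zip(res.curves[0].grid, res.curves[0].prevalence):
            p = baseline_params.replace(epsilon=baseline_params.epsilon * mult)
            assert prev == pytest.approx(oracle_prevalence(p), abs=1e-6)

    def test_epsilon_reduction_dominates_at_low_beta(self):
        # with weak transmissibility, preventing spontaneous weight gain is
        # the most effective single-parameter intervention
        p = ModelParams(beta=BETA_LOW)
        mult = [0.25, 0.5, 0.75]
        eps_curve = univariate_sweep("epsilon", mult, p).curves[0].prevalence
        for other in ("beta", "inverse_gamma", "sigma"):
            other_curve = univariate_sweep(other, mult, p).curves[0].prevalence
            assert np.all(eps_curve < other_curve)

    def test_unknown_target_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            univariate_sweep("mu", [1.0], baseline_params)

    def test_negative_multipliers_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            univariate_sweep("beta", [-0.5], baseline_params)


class TestCombinedSweep:
    def test_unit_factors_return_baseline(self, baseline_params, baseline_equilibrium):
        base_prev = baseline_equilibrium.I_star / baseline_params.N
        res = combined_sweep([1.0], [1.0], baseline_params)
        assert res.curve("alpha").prevalence[0] == pytest.approx(base_prev, rel=1e-9)
        assert res.curve("kappa").prevalence[0] == pytest.approx(base_prev, rel=1e-9)

    def test_prevalence_non_decreasing_in_alpha(self, baseline_params):
        grid = np.linspace(0.0, 1.0, 11)
        res = combined_sweep(grid, [1.0], baseline_params)
        prev = res.curve("alpha").prevalence
        assert np.all(np.diff(prev) > -1e-9)

    def test_primary_vs_secondary_gap_reported_at_high_beta(self):
        # the population-impact comparison between the two programs: the
        # maximal pointwise prevalence gap is reported as data, and both
        # curves coincide at factor one
        p = ModelParams(beta=BETA_HIGH)
        grid = np.linspace(0.2, 1.0, 9)
        res = combined_sweep(grid, grid, p)
        gap = np.max(np.abs(res.curve("alpha").prevalence - res.curve("kappa").prevalence))
        assert np.isfinite(gap) and 0.0 <= gap <= 1.0
        assert res.curve("alpha").prevalence[-1] == pytest.approx(
            res.curve("kappa").prevalence[-1], rel=1e-9
        )


@pytest.fixture(scope="module")
def panels(baseline_params):
    beta_grid = np.linspace(0.0, 8e-7, 41)
    duration_grid = np.linspace(5.0, 70.0, 14)
    return hazard_recovery_sweep(baseline_params, beta_grid, duration_grid)


class TestHazardRecoverySweep:
    def test_no_hazard_no_obesity(self, panels):
        panel_a, _ = panels
        curve = panel_a.curve("epsilon_x0")
        assert curve.prevalence[0] == pytest.approx(0.0, abs=1e-12)

    def test_prevalence_non_decreasing_in_duration(self, panels, baseline_params):
        _, panel_b = panels
        for curve in panel_b.curves:
            assert np.all(np.diff(curve.prevalence) > -1e-9)
            # spot-check against the dense-scan oracle
            d = curve.grid[5]
            mult = float(curve.name.split("x")[1])
            p = baseline_params.replace(
                gamma=1.0 / d, sigma=baseline_params.sigma * mult
            )
            assert curve.prevalence[5] == pytest.approx(oracle_prevalence(p), abs=1e-6)

    def test_abrupt_rise_at_zero_epsilon(self, panels):
        # prevalence jumps at the transmissibility threshold: the largest
        # finite-difference slope dwarfs the median slope
        panel_a, _ = panels
        curve = panel_a.curve("epsilon_x0")
        slopes = np.abs(np.diff(curve.prevalence))
        positive = slopes[slopes > 0]
        assert slopes.max() >= 10 * np.median(positive)

    def test_bistable_cells_record_both_branches(self, panels):
        panel_a, _ = panels
        curve = panel_a.curve("epsilon_x0")
        n_stable = [
            sum(cls == "stable" for _, cls in branches) for branches in curve.branches
        ]
        assert max(n_stable) >= 2

    def test_empty_grid_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            hazard_recovery_sweep(baseline_params, [], [30.0])


class TestLateOutcomeRisk:
    def test_point_mass_delay_reduces_to_ever_obese_curve(self, baseline_params):
        lam, mu = 0.03, baseline_params.mu
        cfg = LateOutcomeConfig(p=0.4, delay="point")
        for a in (0.0, 10.0, 50.0):
            expected = 0.4 * (1.0 - np.exp(-(lam + mu) * a))
            assert late_outcome_risk(a, cfg, lam, mu) == pytest.approx(expected, abs=1e-12)

    def test_linear_in_overall_risk(self, baseline_params):
        lam, mu = 0.03, baseline_params.mu
        lo = LateOutcomeConfig(p=0.2, delay="gamma", shape=2.0, scale=8.0)
        hi = LateOutcomeConfig(p=0.4, delay="gamma", shape=2.0, scale=8.0)
        for a in (15.0, 60.0):
            assert late_outcome_risk(a, hi, lam, mu) == pytest.approx(
                2.0 * late_outcome_risk(a, lo, lam, mu), rel=1e-9
            )

    def test_gamma_delay_against_monte_carlo(self, baseline_params, rng):
        # sample the delay s, average the ever-obese indicator risk
        lam, mu = 0.03, baseline_params.mu
        shape, scale, p, age = 2.0, 10.0, 0.5, 60.0
        cfg = LateOutcomeConfig(p=p, delay="gamma", shape=shape, scale=scale)
        draws = rng.gamma(shape, scale, size=1_000_000)
        u = age - draws
        vals = p * np.where(u > 0, 1.0 - np.exp(-(lam + mu) * np.maximum(u, 0)), 0.0)
        mc, se = vals.mean(), vals.std() / np.sqrt(len(vals))
        assert abs(late_outcome_risk(age, cfg, lam, mu) - mc) < 3 * se

    def test_monotone_and_bounded(self, baseline_params):
        lam, mu = 0.03, baseline_params.mu
        cfg = LateOutcomeConfig(p=0.3, delay="exponential", scale=12.0)
        ages = np.linspace(0, 120, 25)
        w = late_outcome_risk(ages, cfg, lam, mu)
        assert np.all(np.diff(w) >= -1e-12)
        assert np.all(w <= 0.3 + 1e-12)

    def test_unnormalised_density_rejected(self):
        with pytest.raises(ValueError):
            LateOutcomeConfig(p=0.5, pdf=lambda s: 0.5 * np.exp(-s))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            LateOutcomeConfig(p=1.5, delay="point")


class TestExportCsv:
    def test_trajectory_round_trip(self, baseline_params, tmp_path):
        traj = integrate(State(S=baseline_params.N, I=0, R=0), 10.0, baseline_params)
        path = export_csv(traj, tmp_path / "traj.csv")
        # the writer emits shortest round-trip decimals; parse them exactly
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        assert list(frame.columns) == ["t", "S", "I", "R"]
        assert frame.iloc[0].tolist() == [0.0, baseline_params.N, 0.0, 0.0]
        np.testing.assert_array_equal(frame["I"].values, traj.I)

    def test_metadata_header_present(self, baseline_params, tmp_path):
        traj = integrate(State(S=baseline_params.N, I=0, R=0), 5.0, baseline_params)
        path = export_csv(traj, tmp_path / "t.csv")
        header = path.read_text().splitlines()[:7]
        assert header[0].startswith("#")
        assert any("beta" in line for line in header)

    def test_sweep_export_row_count(self, baseline_params, tmp_path):
        res = univariate_sweep("sigma", [0.5, 1.0, 2.0], baseline_params)
        path = export_csv(res, tmp_path / "sweep.csv")
        frame = pd.read_csv(path, comment="#")
        assert len(frame) == 3

    def test_bit_identical_across_runs(self, baseline_params, tmp_path):
        for name in ("a.csv", "b.csv"):
            res = univariate_sweep("beta", [0.5, 1.0], baseline_params)
            export_csv(res, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_age_profile_export(self, baseline_params, tmp_path):
        profile = solve_age_profile(0.03, baseline_params, max_age=10.0, step=1.0)
        frame = pd.read_csv(export_csv(profile, tmp_path / "p.csv"), comment="#")
        assert list(frame.columns) == ["age", "X", "Y", "Z"]

    def test_unknown_object_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            export_csv(object(), tmp_path / "x.csv")


class TestHeadlineEquilibrium:
    def test_bistable_window_headline_is_reachable_branch(self):
        # starting exactly obesity-free with no spontaneous hazard, the
        # system stays obesity-free throughout the bistable window
        p = ModelParams(epsilon=0.0, beta=3.5e-7)
        head, points = headline_equilibrium(p)
        assert head.I_star == pytest.approx(0.0, abs=1e-9)
        assert len(points) == 3

    def test_supercritical_headline_is_endemic(self):
        p = ModelParams(epsilon=0.0, beta=5e-7)
        head, _ = headline_equilibrium(p)
        assert head.I_star > 0.1 * p.N
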