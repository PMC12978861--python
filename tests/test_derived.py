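import itertools

import numpy as np
import pytest

import occdebt as od
from occdebt.derived import (DebtThresholds, classify_debt, equilibrium_occupancy,
                             non_equilibrium, occupancy_recursion,
                             subpopulation_summary, summary_table,
                             turnover_probability)

from conftest import make_dataset


class TestOccupancyRecursion:
    @pytest.mark.parametrize("psi,gamma,eps,expected", [
        (1.0, 0.7, 0.0, 1.0),            # occupied, no extinction: absorbing
        (0.5, 0.3, 0.3, 0.5),            # gamma = eps: 0.5 is a fixed point
        (0.4, 0.1, 0.2, 0.38),           # 0.4*0.8 + 0.6*0.1
    ])
    def test_arithmetic(self, psi, gamma, eps, expected):
        assert occupancy_recursion(psi, gamma, eps) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            occupancy_recursion(1.2, 0.1, 0.1)


class TestTurnover:
    def test_limits(self):
        assert turnover_probability(0.0, 0.4, 0.6) == 0.0
        assert turnover_probability(0.3, 0.0, 0.6) == 1.0

    def test_direct_arithmetic(self):
        assert turnover_probability(0.2, 0.5, 0.7) == pytest.approx(0.1 / 0.45, abs=1e-12)

    def test_equals_two_state_joint_conditional_on_grid(self):
        # tau must equal Pr(Z_{t-1}=0, Z_t=1) / Pr(Z_t=1) from the explicit joint
        grid = np.linspace(0.05, 0.95, 7)
        for g, psi, phi in itertools.product(grid, repeat=3):
            joint_01 = (1 - psi) * g               # unoccupied -> occupied
            joint_11 = psi * phi                   # occupied -> occupied
            want = joint_01 / (joint_01 + joint_11)
            assert abs(turnover_probability(g, psi, phi) - want) < 1e-12

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            turnover_probability(0.0, 0.0, 0.5)


class TestEquilibrium:
    def test_symmetry_and_limits(self):
        assert equilibrium_occupancy(0.3, 0.3) == 0.5
        assert equilibrium_occupancy(0.4, 0.0) == 1.0

    def test_study_wide_means(self):
        # gamma = 0.185, eps = 0.285 -> 0.185/0.470
        assert equilibrium_occupancy(0.185, 0.285) == pytest.approx(0.3936, abs=5e-5)

    def test_is_fixed_point_of_recursion_on_grid(self):
        grid = np.linspace(0.02, 0.98, 25)
        for g, e in itertools.product(grid, repeat=2):
            psi_eq = equilibrium_occupancy(g, e)
            assert abs(occupancy_recursion(psi_eq, g, e) - psi_eq) < 1e-12

    def test_undefined_at_origin(self):
        with pytest.raises(ValueError):
            equilibrium_occupancy(0.0, 0.0)


class TestSubpopulationSummary:
    def test_single_site_constant_rates_matches_site_formulas(self):
        # one site per subpopulation, fully surveyed, intercept-only model
        y = np.zeros((2, 4, 2))
        y[0, 1, 0] = 1.0
        ds = make_dataset(y, subpopulation=["A", "B"])
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        r = est.predict_rates()
        fs = est.predict_smoothed()
        out = {s.subpopulation: s for s in subpopulation_summary(est, ds)}
        a = out["A"]
        assert a.n_sites == 1
        np.testing.assert_allclose(a.psi_fs_t, fs[0], atol=1e-12)
        g, e = r.gamma[0, 0], r.epsilon[0, 0]
        assert a.mean_psi_eq == pytest.approx(g / (g + e), abs=1e-12)
        # turnover seasons 2..T-1 use the previous season's averages
        for t in (1, 2):
            want = turnover_probability(g, fs[0, t - 1], 1 - e)
            assert a.tau_t[t - 1] == pytest.approx(want, abs=1e-12)
        assert len(a.tau_t) == 2 and len(a.psi_eq_t) == 3  # never the final season

    def test_non_equilibrium_worked_rows(self):
        # management-unit arithmetic: occupancy minus equilibrium
        assert non_equilibrium(0.66, 0.59) == pytest.approx(0.07)
        assert non_equilibrium(0.25, 0.28) == pytest.approx(-0.03)
        assert non_equilibrium(0.32, 0.38) == pytest.approx(-0.06)

    def test_invariant_to_site_ordering(self):
        ds, _ = od.generate_study(od.SimulationConfig(
            n_sites=40, subpopulations={"A": 25, "B": 15}, seed=31))
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        base = summary_table(subpopulation_summary(est, ds)).set_index("subpopulation")

        perm = np.random.default_rng(1).permutation(ds.n_sites)
        ds2 = make_dataset(ds.detections.y[perm],
                           subpopulation=list(ds.sites["subpopulation"].to_numpy()[perm]),
                           habitat=ds.sites["habitat_score"].to_numpy()[perm],
                           drought=ds.drought[perm],
                           discharge=ds.discharge[perm],
                           site_ids=[ds.site_ids[i] for i in perm])
        est2 = od.DynamicOccupancyModel().fit(ds2, compute_se=False)
        tab2 = summary_table(subpopulation_summary(est2, ds2)).set_index("subpopulation")
        for col in ("occupancy_mean", "turnover_mean", "equilibrium_mean", "non_equilibrium"):
            np.testing.assert_allclose(base[col].sort_index(), tab2[col].sort_index(),
                                       atol=1e-6)

    def test_homogeneous_parameters_give_common_turnover(self):
        # all subpopulations share the same generating rates, so their
        # turnover summaries must agree up to Monte Carlo error
        cfg = od.SimulationConfig(
            n_sites=600, n_seasons=5,
            subpopulations={"A": 200, "B": 200, "C": 200},
            revisit_probs={5: 1.0},
            coefficients={"psi1": {"(intercept)": 0.0},
                          "gamma": {"(intercept)": -1.0},
                          "epsilon": {"(intercept)": -1.0},
                          "p": {"(intercept)": 1.5}},
            spec=od.ModelSpec(name="null"), seed=32)
        ds, truth = od.generate_study(cfg)
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        taus = [s.mean_tau for s in subpopulation_summary(est, ds)]
        assert np.std(taus) < 0.05
        g, e = truth.rates.gamma[0, 0], truth.rates.epsilon[0, 0]
        analytic = turnover_probability(g, equilibrium_occupancy(g, e), 1 - e)
        np.testing.assert_allclose(taus, analytic, atol=0.1)


class TestBootstrap:
    def test_same_seed_identical_intervals(self):
        ds, _ = od.generate_study(od.SimulationConfig(
            n_sites=50, subpopulations={"A": 50}, revisit_probs={3: 0.5, 4: 0.5},
            seed=33))
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        a = od.bootstrap_summaries(est, ds, n_sim=6, seed=99)
        b = od.bootstrap_summaries(est, ds, n_sim=6, seed=99)
        assert a.equals(b)
        c = od.bootstrap_summaries(est, ds, n_sim=6, seed=100)
        assert not a.drop(columns=["subpopulation"]).equals(c.drop(columns=["subpopulation"]))

    def test_interval_brackets_point_estimate(self):
        ds, _ = od.generate_study(od.SimulationConfig(
            n_sites=120, subpopulations={"A": 120}, revisit_probs={4: 0.5, 5: 0.5},
            seed=34))
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        ci = od.bootstrap_summaries(est, ds, n_sim=30, seed=1)
        row = ci.iloc[0]
        assert row["turnover_ci_lower"] <= row["turnover_ci_upper"]
        assert row["equilibrium_ci_lower"] < row["equilibrium_mean"] < row["equilibrium_ci_upper"]


class TestClassifyDebt:
    @pytest.mark.parametrize("tau,neq,label", [
        (0.74, -0.03, "debt being realized"),
        (0.57, +0.04, "debt accruing, not yet realized"),
        (0.11, +0.07, "near stable"),
        (0.10, -0.20, "below equilibrium, low turnover"),
        (0.35, -0.02, "elevated turnover"),
    ])
    def test_rule_labels(self, tau, neq, label):
        a = classify_debt({"subpopulation": "X", "turnover": tau,
                           "non_equilibrium": neq})
        assert a.label == label
        assert str(round(tau, 3)) in a.rule  # the rule that fired is recorded

    def test_thresholds_configurable(self):
        th = DebtThresholds(low=0.05, high=0.9, stable_band=0.01)
        a = classify_debt({"subpopulation": "X", "turnover": 0.11,
                           "non_equilibrium": 0.07}, th)
        assert a.turnover_tier == "moderate"
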