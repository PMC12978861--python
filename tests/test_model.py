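import numpy as np
import pytest
from scipy.special import expit

import occdebt as od
from occdebt.errors import ConvergenceError
from occdebt.model import aicc, rank_models, rates_from_params
from occdebt.design import ModelSpec, build_design

from conftest import make_dataset


class TestAicc:
    def test_closed_form(self):
        assert aicc(5.0, 2, 10) == pytest.approx(14 + 12 / 7)

    def test_approaches_aic_for_large_n(self):
        assert aicc(5.0, 2, 10 ** 8) == pytest.approx(14.0, abs=1e-6)

    def test_strictly_exceeds_aic(self):
        for n in (10, 100, 1000):
            assert aicc(3.0, 4, n) > 2 * 3.0 + 2 * 4

    def test_undefined_below_k_plus_one(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(5.0, 9, 10)


class _FakeFit:
    def __init__(self, name, nll, k, n, converged=True):
        self.name = name
        self.nll_ = nll
        self.n_params_ = k
        self.aicc_ = aicc(nll, k, n)
        self.converged_ = converged


class TestRankModels:
    def test_delta_and_support_flags(self):
        # choose NLLs giving AICc exactly {100, 101.5, 104} at K=2, large n
        fits = [_FakeFit(n, (a - 4) / 2, 2, 10 ** 9)
                for n, a in [("m1", 100.0), ("m2", 101.5), ("m3", 104.0)]]
        tab = rank_models(fits)
        np.testing.assert_allclose(tab["delta_aicc"], [0.0, 1.5, 4.0], atol=1e-6)
        assert list(tab["equally_supported"]) == [True, True, False]

    def test_delta_above_two_not_supported(self):
        fits = [_FakeFit("a", 48.0, 2, 10 ** 9), _FakeFit("b", 49.165, 2, 10 ** 9)]
        tab = rank_models(fits)
        assert tab["delta_aicc"].iloc[1] == pytest.approx(2.33)
        assert not tab["equally_supported"].iloc[1]

    def test_tie_break_fewer_parameters_then_name(self):
        # equal AICc: K=2 at NLL x vs K=3 at NLL x-1 (large n)
        fits = [_FakeFit("zzz", 49.0, 3, 10 ** 9), _FakeFit("aaa", 50.0, 2, 10 ** 9)]
        tab = rank_models(fits)
        assert list(tab["model"]) == ["aaa", "zzz"]

    def test_nonconverged_excluded_with_warning(self):
        fits = [_FakeFit("good", 50.0, 2, 10 ** 9),
                _FakeFit("bad", 10.0, 2, 10 ** 9, converged=False)]
        with pytest.warns(UserWarning, match="did not converge"):
            tab = rank_models(fits)
        assert list(tab["model"]) == ["good"]
        with pytest.raises(ConvergenceError):
            rank_models([_FakeFit("bad", 10.0, 2, 10 ** 9, converged=False)])


class TestPredictRates:
    def test_zero_coefficients_give_half(self):
        ds = make_dataset(np.zeros((3, 3, 2)))
        d = build_design(ModelSpec(psi1=("habitat_score",), p=("discharge",)), ds)
        r = rates_from_params(np.zeros(d.n_params), d)
        assert np.all(r.psi1 == 0.5) and np.all(r.gamma == 0.5)
        assert np.all(r.epsilon == 0.5) and np.all(r.p == 0.5)

    def test_large_negative_extinction_intercept_gives_phi_one(self):
        ds = make_dataset(np.zeros((2, 3, 1)))
        d = build_design(ModelSpec(), ds)
        theta = np.zeros(d.n_params)
        theta[2] = -40.0  # epsilon intercept
        r = rates_from_params(theta, d)
        assert np.all(r.epsilon < 1e-15) and np.all(r.phi == pytest.approx(1.0))

    def test_matches_hand_computed_logistic(self):
        ds = make_dataset(np.zeros((4, 2, 1)), habitat=[40.0, 55.0, 70.0, 95.0])
        d = build_design(ModelSpec(psi1=("habitat_score",)), ds)
        beta = np.array([0.3, -0.8])
        theta = np.zeros(d.n_params)
        theta[:2] = beta
        r = rates_from_params(theta, d)
        hs = np.array([40.0, 55.0, 70.0, 95.0])
        z = (hs - hs.mean()) / hs.std()
        np.testing.assert_allclose(r.psi1, expit(0.3 - 0.8 * z), atol=1e-12)

    def test_phi_is_exactly_one_minus_epsilon(self):
        ds = make_dataset(np.zeros((3, 4, 2)))
        d = build_design(ModelSpec(), ds)
        r = rates_from_params(np.array([0.2, -0.3, 0.7, 0.1]), d)
        np.testing.assert_array_equal(r.phi, 1.0 - r.epsilon)


def _perfect_detection_dataset(seed=0, n=300, T=3, J=2,
                               psi1=0.45, gamma=0.25, eps=0.3):
    rng = np.random.default_rng(seed)
    Z = np.zeros((n, T), dtype=int)
    Z[:, 0] = rng.random(n) < psi1
    for t in range(T - 1):
        Z[:, t + 1] = np.where(Z[:, t] == 1, rng.random(n) > eps, rng.random(n) < gamma)
    y = np.repeat(Z[:, :, None], J, axis=2).astype(float)
    return make_dataset(y), Z


class TestFit:
    def test_perfect_detection_recovers_observed_proportions(self):
        ds, Z = _perfect_detection_dataset()
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        r = est.predict_rates()
        assert est.converged_
        assert r.psi1[0] == pytest.approx(Z[:, 0].mean(), abs=1e-4)
        # pooled transition frequencies (intercept-only shares rates over t)
        T = Z.shape[1]
        g_emp = (sum(((Z[:, t] == 0) & (Z[:, t + 1] == 1)).sum() for t in range(T - 1))
                 / sum((Z[:, t] == 0).sum() for t in range(T - 1)))
        e_emp = (sum(((Z[:, t] == 1) & (Z[:, t + 1] == 0)).sum() for t in range(T - 1))
                 / sum((Z[:, t] == 1).sum() for t in range(T - 1)))
        assert r.gamma[0, 0] == pytest.approx(g_emp, abs=1e-4)
        assert r.epsilon[0, 0] == pytest.approx(e_emp, abs=1e-4)

    def test_multistart_reaches_same_optimum(self):
        ds, _ = od.generate_study(od.SimulationConfig(
            n_sites=80, subpopulations={"A": 80}, seed=21))
        single = od.DynamicOccupancyModel(p=("discharge",)).fit(ds, compute_se=False)
        multi = od.DynamicOccupancyModel(p=("discharge",), n_starts=5,
                                         random_state=9).fit(ds, compute_se=False)
        assert multi.nll_ == pytest.approx(single.nll_, abs=1e-6)

    def test_aicc_consistent_with_nll_and_k(self):
        ds, _ = od.generate_study(od.SimulationConfig(
            n_sites=60, subpopulations={"A": 60}, seed=22))
        est = od.DynamicOccupancyModel().fit(ds, compute_se=False)
        assert est.aicc_ == pytest.approx(aicc(est.nll_, est.n_params_, ds.n_sites))

    def test_sklearn_clone_and_get_params_roundtrip(self):
        from sklearn.base import clone
        est = od.DynamicOccupancyModel(epsilon=("habitat_score", "drought"), name="m")
        c = clone(est)
        assert c.get_params() == est.get_params()
        assert not hasattr(c, "coef_")

    def test_requires_two_seasons(self):
        ds = make_dataset(np.zeros((4, 1, 2)))
        with pytest.raises(ValueError, match="2 seasons"):
            od.DynamicOccupancyModel().fit(ds)

    def test_coefficients_table_layout(self):
        ds, _ = od.generate_study(od.SimulationConfig(
            n_sites=80, subpopulations={"A": 80}, seed=23))
        est = od.DynamicOccupancyModel(p=("discharge",)).fit(ds)
        tab = est.coefficients_table()
        assert list(tab.columns) == ["group", "term", "estimate", "se",
                                     "ci_lower", "ci_upper", "p_value"]
        assert list(tab["group"].unique()) == ["psi1", "gamma", "epsilon", "p"]
        assert (tab["ci_upper"] >= tab["ci_lower"]).all()
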