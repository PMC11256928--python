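"""ECM updates, KKT weight solver and fit driver contracts."""

import numpy as np
import pytest
from scipy import optimize

from xlfdr import constraints as C
from xlfdr import em
from xlfdr.data import ScoreDataset
from xlfdr.model import (
    OneSampleModel,
    Responsibilities,
    S1_COMPONENTS,
    TwoSampleModel,
    loglik,
    responsibilities,
)
from xlfdr.sn import SNParams, sn_sample
from xlfdr.synthetic import default_model, sample_mixture_faithful


def small_dataset(rng, n=200):
    m = default_model()
    return sample_mixture_faithful(m, n, seed=int(rng.integers(2**31))).to_score_dataset()


class TestKKTWeights:
    def test_unconstrained_equals_responsibility_averages(self, rng):
        omega = rng.dirichlet(np.ones(3) * 5, size=120)
        nu = rng.dirichlet(np.ones(5) * 5, size=90)
        resp = Responsibilities(omega=omega, nu=nu)
        sol = em.solve_weights_kkt(resp, 0.2)
        np.testing.assert_allclose(sol.w, omega.sum(0) / 120, rtol=1e-14)
        np.testing.assert_allclose(sol.v, nu.sum(0) / 90, rtol=1e-14)
        assert sol.active_set == ()

    def test_uniform_responsibilities_give_uniform_weights(self):
        resp = Responsibilities(omega=np.full((50, 3), 1 / 3), nu=np.full((40, 5), 0.2))
        sol = em.solve_weights_kkt(resp, 0.0)
        np.testing.assert_allclose(sol.w, 1 / 3, atol=1e-12)
        np.testing.assert_allclose(sol.v, 0.2, atol=1e-12)

    def _oracle(self, a, b, v_phi):
        # generic inequality-constrained optimizer, independent of the
        # greedy active-set route
        c = 1 - v_phi
        A = np.zeros((2, 8))
        A[0, :3] = 1.0
        A[1, 3:] = 1.0
        G = np.zeros((8, 8))
        G[:, :3] = C._CW
        G[:, 3:] = c * C._CV
        r = optimize.minimize(
            lambda x: -(a @ np.log(x[:3]) + b @ np.log(x[3:8])),
            np.concatenate([np.full(3, 1 / 3), np.full(5, 0.2)]),
            jac=lambda x: np.concatenate([-a / x[:3], -b / x[3:8]]),
            hess=lambda x: np.diag(np.concatenate([a / x[:3] ** 2, b / x[3:8] ** 2])),
            method="trust-constr",
            bounds=optimize.Bounds(1e-10, 1.0),
            constraints=[
                optimize.LinearConstraint(A, 1.0, 1.0),
                optimize.LinearConstraint(G, -C._C0 * v_phi, np.inf),
            ],
            options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
        )
        if r.status not in (1, 2):
            return None
        return r.x[:3], r.x[3:8]

    def test_binding_constraints_match_generic_optimizer(self, rng):
        checked = 0
        while checked < 12:
            a = rng.dirichlet(rng.uniform(0.5, 3, 3)) * 1500
            a[0] *= rng.uniform(1.5, 3.0)  # push wC up so b1 binds
            b = rng.dirichlet(rng.uniform(0.5, 3, 5)) * 1000
            v_phi = rng.uniform(0.0, 0.4)
            if C.check_weights_B(a / a.sum(), b / b.sum(), v_phi).satisfied:
                continue
            sol = em._solve_weights(a, b, v_phi)
            ref = self._oracle(a, b, v_phi)
            if ref is None:
                continue
            np.testing.assert_allclose(sol.w, ref[0], atol=1e-6)
            np.testing.assert_allclose(sol.v, ref[1], atol=1e-6)
            checked += 1

    def test_complementary_slackness(self, rng):
        checked = 0
        while checked < 8:
            a = rng.dirichlet(rng.uniform(0.5, 3, 3)) * 1500
            a[0] *= rng.uniform(1.5, 3.0)
            b = rng.dirichlet(rng.uniform(0.5, 3, 5)) * 1000
            v_phi = 0.1
            if C.check_weights_B(a / a.sum(), b / b.sum(), v_phi).satisfied:
                continue
            sol = em._solve_weights(a, b, v_phi)
            slack = C.weight_slacks_B(sol.w, sol.v, v_phi)
            assert np.max(np.abs(sol.eta * slack)) < 1e-8
            assert sol.residual < 1e-8
            checked += 1


class TestComponentUpdates:
    def test_symmetric_update_reduces_to_weighted_mean(self, rng):
        # with Delta = 0 the location update collapses to the responsibility-
        # weighted mean of the scores
        p = SNParams(2.0, 1.5, 0.0)
        s = rng.normal(2, 1.5, 300)
        r = rng.uniform(0.2, 1.0, 300)
        theta = {"C": SNParams(8.0, 1.5, 0.0), "J1": p, "I1": SNParams(-4.0, 1.5, 0.0)}
        new = em.ecm_update_component("J1", s, r, theta, chain=C.CHAIN_ONE_SAMPLE)
        from xlfdr.sn import to_alternate

        assert to_alternate(new["J1"]).mu == pytest.approx(
            float((r * s).sum() / r.sum()), rel=1e-10
        )

    def test_single_component_mle_recovery(self):
        # iterating the conditional updates with unit responsibilities must
        # reach the skew-normal MLE, checked against a generic numeric MLE
        from scipy.stats import skewnorm

        truth = SNParams(1.0, 2.0, 3.0)
        s = sn_sample(5000, truth, seed=11)
        r = np.ones_like(s)
        # run far from any chain neighbour so constraints never bind
        theta = {
            "C": SNParams(80.0, 1.0, 1.0),
            "J1": SNParams(float(s.mean()), float(s.std()), 1.0),
            "I1": SNParams(-80.0, 1.0, -1.0),
        }
        for _ in range(2000):
            theta = em.ecm_update_component("J1", s, r, theta, chain=C.CHAIN_ONE_SAMPLE)
        a_mle, loc_mle, sc_mle = skewnorm.fit(s)
        got = theta["J1"]
        assert got.mu == pytest.approx(loc_mle, abs=1e-2)
        assert got.sigma == pytest.approx(sc_mle, abs=1e-2)
        assert got.lam == pytest.approx(a_mle, abs=5e-2)

    def test_frozen_when_mass_vanishes(self, rng):
        theta = dict(default_model().theta)
        s = rng.normal(20, 5, 50)
        r = np.zeros(50)
        new = em.ecm_update_component("J2", s, r, theta)
        assert new["J2"] == theta["J2"]


class TestInitialization:
    def test_schedule_counts(self):
        sched = em.initialization_schedule(40)
        assert len(sched) == 240
        assert {lam0 for _, lam0, _ in sched} == {1.0, 2.0, 5.0}

    def test_kkt_system_enumeration(self):
        assert em.count_kkt_systems() == 256

    def test_init_satisfies_chain_and_exact_v(self, rng):
        ds = small_dataset(rng, n=500)
        for lam0, sign in ((1, 1), (2, -1), (5, 1)):
            m = em.init_params(ds, lam0, sign, rng)
            ok, _ = C.check_chain(m.theta)
            assert ok
            np.testing.assert_allclose(m.w, 1 / 3)
            assert m.v[0] == 0.001
            np.testing.assert_allclose(m.v[1:], 0.999 / 4)
            mus = [m.theta[c].mu for c in ("C", "J1", "J2", "I1", "I2")]
            assert mus == sorted(mus, reverse=True)
            assert m.theta["C"].lam > 0 and m.theta["J2"].lam < 0
            assert np.sign(m.theta["J1"].lam) == sign

    def test_lambda0_one_is_degenerate_at_unit_shape(self, rng):
        ds = small_dataset(rng, n=500)
        m = em.init_params(ds, 1, -1, rng)
        for c in ("C", "J1", "J2", "I1", "I2"):
            assert abs(m.theta[c].lam) == pytest.approx(1.0)


class TestFit:
    def test_deterministic_given_seed(self, rng):
        ds = small_dataset(rng, n=400)
        st1 = em.fit(ds, n_restarts=6, seed=5, tol=1e-6, max_iter=40)
        st2 = em.fit(ds, n_restarts=6, seed=5, tol=1e-6, max_iter=40)
        np.testing.assert_array_equal(st1.model.w, st2.model.w)
        np.testing.assert_array_equal(st1.model.v, st2.model.v)
        for c in st1.model.theta:
            assert st1.model.theta[c] == st2.model.theta[c]

    def test_final_loglik_not_below_initial(self, rng):
        ds = small_dataset(rng, n=400)
        st = em.fit(ds, n_restarts=6, seed=2, tol=1e-6, max_iter=60)
        assert st.loglik_trace[-1] >= st.loglik_trace[0]

    def test_fitted_model_satisfies_all_constraints(self, rng):
        ds = small_dataset(rng, n=400)
        st = em.fit(ds, n_restarts=6, seed=3, tol=1e-6, max_iter=60)
        ok, _ = C.check_chain(st.model.theta)
        assert ok
        assert C.check_weights_B(st.model.w, st.model.v, st.model.v_phi, tol=1e-9).satisfied

    def test_one_sample_weight_update_is_responsibility_average(self, rng):
        ds = small_dataset(rng, n=400)
        st = em.fit_one_sample(ds, n_restarts=3, seed=4, tol=1e-6, max_iter=30)
        r = responsibilities(st.model, ds)
        # at convergence the weights are the fixed point of the M-step
        np.testing.assert_allclose(st.model.w, r.omega.mean(axis=0), atol=5e-4)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            em.fit(ScoreDataset(s1=np.array([]), s2=np.array([])), n_restarts=1, seed=0)
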