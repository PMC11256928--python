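"""Mixture likelihood, responsibilities and Q-function against brute force."""

import math

import numpy as np
import pytest

from xlfdr.data import ScoreDataset
from xlfdr.model import (
    OneSampleModel,
    S1_COMPONENTS,
    S2_COMPONENTS,
    TwoSampleModel,
    loglik,
    q_function,
    responsibilities,
)
from xlfdr.sn import SNParams, sn_pdf, tn_moments, to_alternate
from xlfdr.synthetic import default_model, sample_mixture_faithful

from conftest import random_sn


def random_model(rng, v_phi=0.3) -> TwoSampleModel:
    # random parameters; constraints are irrelevant for likelihood algebra
    theta = {}
    mus = np.sort(rng.normal(0, 5, 5))[::-1]
    for name, mu in zip(S2_COMPONENTS, mus):
        theta[name] = SNParams(float(mu), float(rng.uniform(0.8, 3)), float(rng.normal(0, 2)))
    w = rng.dirichlet(np.ones(3) * 3)
    v = rng.dirichlet(np.ones(5) * 3)
    return TwoSampleModel(theta=theta, w=w, v=v, v_phi=v_phi)


def random_dataset(rng, n=40, p_missing=0.3) -> ScoreDataset:
    s1 = rng.normal(0, 6, n)
    s2 = np.where(rng.random(n) < p_missing, np.nan, s1 - rng.uniform(0, 4, n))
    return ScoreDataset(s1=s1, s2=s2)


def brute_loglik(model, ds):
    total = 0.0
    for s in ds.s1:
        total += math.log(
            sum(
                w * float(sn_pdf(s, model.theta[c]))
                for w, c in zip(model.w, S1_COMPONENTS)
            )
        )
    for s in ds.s2:
        if np.isnan(s):
            continue
        total += math.log(
            sum(
                v * float(sn_pdf(s, model.theta[c]))
                for v, c in zip(model.v, S2_COMPONENTS)
            )
        )
    return total


class TestLoglik:
    def test_matches_brute_force(self, rng):
        for _ in range(25):
            m = random_model(rng)
            ds = random_dataset(rng)
            assert loglik(m, ds) == pytest.approx(brute_loglik(m, ds), abs=1e-10)

    def test_single_component_limit(self, rng):
        # the epsilon components sit nearby, so their density ratio cannot
        # overcome the 1e-12 weight anywhere the data lives
        eps = 1e-12
        base = random_sn(rng)
        theta = {
            c: SNParams(base.mu + 0.5 * i, base.sigma, base.lam)
            for i, c in enumerate(S2_COMPONENTS)
        }
        m = TwoSampleModel(
            theta=theta, w=np.array([1 - 2 * eps, eps, eps]), v=np.full(5, 0.2), v_phi=1.0
        )
        ds = ScoreDataset(
            s1=rng.normal(base.mu, base.sigma, 50), s2=np.full(50, np.nan)
        )
        direct = float(np.log(sn_pdf(ds.s1, theta["C"])).sum())
        assert loglik(m, ds) == pytest.approx(direct, abs=1e-6)

    def test_missing_s2_only_contributes_via_s1(self, rng):
        m = random_model(rng)
        ds = random_dataset(rng, n=30, p_missing=0.0)
        base = loglik(m, ds)
        extra = ScoreDataset(
            s1=np.append(ds.s1, 1.5), s2=np.append(ds.s2, np.nan)
        )
        s1_term = math.log(
            sum(w * float(sn_pdf(1.5, m.theta[c])) for w, c in zip(m.w, S1_COMPONENTS))
        )
        assert loglik(m, extra) == pytest.approx(base + s1_term, abs=1e-10)

    def test_one_sample_equals_two_sample_on_all_missing(self, rng):
        m = random_model(rng)
        m1 = OneSampleModel(theta={c: m.theta[c] for c in S1_COMPONENTS}, w=m.w)
        ds = ScoreDataset(s1=rng.normal(0, 4, 40), s2=np.full(40, np.nan))
        assert loglik(m, ds) == pytest.approx(loglik(m1, ds), abs=1e-12)


class TestResponsibilities:
    def test_rows_sum_to_one(self, rng):
        m = random_model(rng)
        ds = random_dataset(rng)
        r = responsibilities(m, ds)
        np.testing.assert_allclose(r.omega.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(r.nu.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_components_give_uniform(self, rng):
        p = random_sn(rng)
        m = TwoSampleModel(
            theta={c: p for c in S2_COMPONENTS},
            w=np.full(3, 1 / 3),
            v=np.full(5, 0.2),
            v_phi=0.0,
        )
        ds = random_dataset(rng, p_missing=0.0)
        r = responsibilities(m, ds)
        np.testing.assert_allclose(r.omega, 1 / 3, atol=1e-12)
        np.testing.assert_allclose(r.nu, 0.2, atol=1e-12)

    def test_dominant_weight_dominates(self, rng):
        eps = 1e-12
        p = random_sn(rng)
        m = TwoSampleModel(
            theta={
                c: SNParams(p.mu + 0.3 * i, p.sigma, p.lam)
                for i, c in enumerate(S2_COMPONENTS)
            },
            w=np.array([1 - 2 * eps, eps, eps]),
            v=np.full(5, 0.2),
            v_phi=0.3,
        )
        ds = ScoreDataset(
            s1=rng.normal(p.mu, p.sigma, 40), s2=np.full(40, np.nan)
        )
        r = responsibilities(m, ds)
        assert np.all(r.omega[:, 0] > 0.999)

    def test_matches_direct_formula(self, rng):
        m = random_model(rng)
        ds = random_dataset(rng)
        r = responsibilities(m, ds)
        for i, s in enumerate(ds.s1):
            dens = np.array(
                [w * float(sn_pdf(s, m.theta[c])) for w, c in zip(m.w, S1_COMPONENTS)]
            )
            np.testing.assert_allclose(r.omega[i], dens / dens.sum(), atol=1e-12)


def brute_q(new, cur, ds):
    r = responsibilities(cur, ds)
    total = 0.0
    for i, s in enumerate(ds.s1):
        for k, c in enumerate(S1_COMPONENTS):
            xi = tn_moments(np.array([s]), cur.theta[c])
            a = to_alternate(new.theta[c])
            q = math.log(a.Gamma) + (
                (s - a.mu) ** 2
                - 2 * (s - a.mu) * a.Delta * float(xi.xi1[0])
                + (a.Delta**2 + a.Gamma) * float(xi.xi2[0])
            ) / a.Gamma
            total += r.omega[i, k] * (math.log(new.w[k]) - q / 2)
    obs = ds.s2_observed
    for i, s in enumerate(obs):
        for k, c in enumerate(S2_COMPONENTS):
            xi = tn_moments(np.array([s]), cur.theta[c])
            a = to_alternate(new.theta[c])
            q = math.log(a.Gamma) + (
                (s - a.mu) ** 2
                - 2 * (s - a.mu) * a.Delta * float(xi.xi1[0])
                + (a.Delta**2 + a.Gamma) * float(xi.xi2[0])
            ) / a.Gamma
            total += r.nu[i, k] * (math.log(new.v[k]) - q / 2)
    return total


class TestQFunction:
    def test_finite_at_current(self, rng):
        for _ in range(5):
            m = random_model(rng)
            ds = random_dataset(rng, n=25)
            assert np.isfinite(q_function(m, m, ds))

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            cur = random_model(rng)
            new = random_model(rng)
            ds = random_dataset(rng, n=20)
            assert q_function(new, cur, ds) == pytest.approx(
                brute_q(new, cur, ds), abs=1e-9
            )

    def test_exact_weight_m_step_does_not_decrease_q(self, rng):
        cur = random_model(rng)
        ds = random_dataset(rng, n=60)
        r = responsibilities(cur, ds)
        new = TwoSampleModel(
            theta=dict(cur.theta),
            w=r.omega.sum(0) / r.omega.sum(),
            v=r.nu.sum(0) / r.nu.sum(),
            v_phi=cur.v_phi,
        )
        assert q_function(new, cur, ds) >= q_function(cur, cur, ds) - 1e-10


def test_loglik_on_generated_data_prefers_truth_scale():
    # sanity: the generating model scores its own data higher than a shifted copy
    m = default_model()
    ds = sample_mixture_faithful(m, 2000, seed=0).to_score_dataset()
    shifted = TwoSampleModel(
        theta={k: SNParams(p.mu + 5, p.sigma, p.lam) for k, p in m.theta.items()},
        w=m.w.copy(),
        v=m.v.copy(),
        v_phi=m.v_phi,
    )
    assert loglik(m, ds) > loglik(shifted, ds)
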