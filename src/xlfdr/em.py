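"""Constrained ECM estimation of the ranked-score SN mixture models.

Each iteration performs:

1. E-step: posterior responsibilities of every score for every component,
   plus the truncated-normal moments of the latent stochastic-representation
   variables (both under the current parameters).
2. Conditional M-steps per component, in the order mu -> Delta -> Gamma,
   using the closed-form update equations; every candidate value is passed
   through the binary-search repair so the density-dominance chain
   C > J1 > J2 > I1 > I2 holds after every single update, and a repaired
   value feeds the subsequent updates of the same component.
3. Weight M-step under constraint set B via the KKT stationarity system:
   the unconstrained solution (responsibility averages) is used when
   feasible; otherwise a greedy active-set search activates violated
   inequalities one at a time, then in pairs, triples, ... up to all eight.

Random restarts draw initial parameters around a normal fit to the top
scores, with location order matching the dominance chain; six
initializations per round (three shape magnitudes x two signs of the J1
skewness), resampled until chain-feasible.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import constraints as cons
from .data import ScoreDataset
from .model import (
    S1_COMPONENTS,
    S2_COMPONENTS,
    OneSampleModel,
    Responsibilities,
    TwoSampleModel,
    _log_weighted,
)
from .sn import SNParams, tn_moments, to_alternate

__all__ = [
    "FitError",
    "ECMState",
    "KKTSolution",
    "ecm_update_component",
    "solve_weights_kkt",
    "init_params",
    "initialization_schedule",
    "count_kkt_systems",
    "fit",
    "fit_one_sample",
]

logger = logging.getLogger(__name__)

_MASS_FLOOR = 1e-10  # below this responsibility mass a component is frozen
_WEIGHT_FLOOR = 1e-12
_SCREEN_N = 5000  # subsample size for the restart-screening stage
_LAMBDA0_GRID = (1.0, 2.0, 5.0)


class FitError(RuntimeError):
    """The constrained fit failed numerically."""


# ---------------------------------------------------------------------------
# KKT weight solver
# ---------------------------------------------------------------------------


@dataclass
class KKTSolution:
    w: np.ndarray
    v: np.ndarray
    active_set: tuple[str, ...]
    gamma: np.ndarray  # multipliers of the two simplex equalities
    eta: np.ndarray  # 8 inequality multipliers, zero when inactive
    residual: float


def count_kkt_systems() -> int:
    """Number of distinct stationarity systems over subsets of the 8 inequality multipliers."""
    return sum(
        1
        for k in range(9)
        for _ in itertools.combinations(range(8), k)
    )


def _kkt_system(a, b, v_phi, active):
    """Residual function and Jacobian of the stationarity system.

    Unknowns x = [w (3), v (5), gamma1, gamma2, eta_active (k)].  Stationarity
    rows are normalized by the sample sizes so the residual criterion is
    scale-free.  Differentiating the Lagrangian in v_Y brings in a factor
    (1 - v_phi) on the eta terms because the constraints act on
    v'_Y = (1 - v_phi) v_Y.
    """
    c = 1.0 - v_phi
    n1 = max(a.sum(), 1.0)
    n2 = max(b.sum(), 1.0)
    CWa = cons._CW[list(active)]  # (k, 3)
    CVa = cons._CV[list(active)]  # (k, 5)
    k = len(active)

    def F(x):
        w, v = x[:3], x[3:8]
        g1, g2 = x[8], x[9]
        eta = x[10:]
        Fw = (a / w + g1 + CWa.T @ eta) / n1
        Fv = (b / v + g2 + c * (CVa.T @ eta)) / n2
        Fs = np.array([w.sum() - 1.0, v.sum() - 1.0])
        Fg = CWa @ w + c * (CVa @ v) + cons._C0[list(active)] * v_phi
        return np.concatenate([Fw, Fv, Fs, Fg])

    def J(x):
        w, v = x[:3], x[3:8]
        m = 10 + k
        out = np.zeros((m, m))
        out[:3, :3] = np.diag(-a / w**2) / n1
        out[:3, 8] = 1.0 / n1
        out[:3, 10:] = CWa.T / n1
        out[3:8, 3:8] = np.diag(-b / v**2) / n2
        out[3:8, 9] = 1.0 / n2
        out[3:8, 10:] = c * CVa.T / n2
        out[8, :3] = 1.0
        out[9, 3:8] = 1.0
        out[10:, :3] = CWa
        out[10:, 3:8] = c * CVa
        return out

    return F, J


def _weight_objective(a, b, w, v) -> float:
    # weight-dependent part of the Q-function
    return float((a * np.log(w)).sum() + (b * np.log(v)).sum())


def _floor_simplex(x: np.ndarray) -> np.ndarray:
    x = np.maximum(x, _WEIGHT_FLOOR)
    return x / x.sum()


def _multipliers_lstsq(a, b, v_phi, active, w, v):
    """Recover (gamma, eta_active) from the stationarity equations at (w, v)."""
    c = 1.0 - v_phi
    k = len(active)
    M = np.zeros((8, 2 + k))
    M[:3, 0] = 1.0
    M[3:, 1] = 1.0
    M[:3, 2:] = cons._CW[list(active)].T
    M[3:, 2:] = c * cons._CV[list(active)].T
    rhs = -np.concatenate([a / w, b / v])
    u, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    n1 = max(a.sum(), 1.0)
    n2 = max(b.sum(), 1.0)
    scale = np.concatenate([np.full(3, n1), np.full(5, n2)])
    res = float(np.max(np.abs((M @ u - rhs) / scale)))
    return u, res


def _validate_candidate(a, b, v_phi, active, w, v, gamma_eta, residual_tol):
    if np.any(w <= 0.0) or np.any(v <= 0.0):
        return None
    if abs(w.sum() - 1.0) > 1e-9 or abs(v.sum() - 1.0) > 1e-9:
        return None
    u, res = _multipliers_lstsq(a, b, v_phi, active, w, v)
    if gamma_eta is not None:
        # prefer the solver's own multipliers when they fit better
        F, _ = _kkt_system(a, b, v_phi, active)
        x = np.concatenate([w, v, gamma_eta])
        res_direct = float(np.max(np.abs(F(x)[:8])))
        if res_direct < res:
            u, res = gamma_eta, res_direct
    if res > residual_tol:
        return None
    # dual feasibility: with a concave objective and linear constraints a KKT
    # point is the global optimum iff the inequality multipliers are >= 0
    scale = max(a.sum() + b.sum(), 1.0)
    if np.any(u[2:] < -1e-6 * scale):
        return None
    slack = cons.weight_slacks_B(w, v, v_phi)
    if np.any(slack[list(active)] < -1e-9) or np.any(np.abs(slack[list(active)]) > 1e-7):
        return None
    report = cons.check_weights_B(w, v, v_phi, tol=1e-9)
    if not report.satisfied:
        return None
    eta = np.zeros(8)
    eta[list(active)] = u[2:]
    return KKTSolution(
        w=w,
        v=v,
        active_set=tuple(cons.B_NAMES[i] for i in active),
        gamma=np.asarray(u[:2], dtype=float),
        eta=eta,
        residual=res,
    )


def _solve_active_set(a, b, v_phi, active, w0, v0, residual_tol):
    # primary: damped root on the full stationarity system
    F, J = _kkt_system(a, b, v_phi, active)
    x0 = np.concatenate([w0, v0, [-a.sum(), -b.sum()], np.zeros(len(active))])
    with np.errstate(divide="ignore", invalid="ignore"):
        sol = optimize.root(F, x0, jac=J, method="hybr")
        out = _validate_candidate(
            a, b, v_phi, active, sol.x[:3], sol.x[3:8], sol.x[8:], residual_tol
        )
    if out is not None:
        return out
    # fallback: equality-constrained concave maximization of the weight
    # objective with the active slacks pinned to zero
    c = 1.0 - v_phi
    CWa = cons._CW[list(active)]
    CVa = cons._CV[list(active)]
    c0a = cons._C0[list(active)]

    def negobj(x):
        w, v = x[:3], x[3:8]
        return -(a @ np.log(w) + b @ np.log(v))

    def negobj_grad(x):
        w, v = x[:3], x[3:8]
        return np.concatenate([-a / w, -b / v])

    eq_cons = [
        {"type": "eq", "fun": lambda x: x[:3].sum() - 1.0},
        {"type": "eq", "fun": lambda x: x[3:8].sum() - 1.0},
        {
            "type": "eq",
            "fun": lambda x: CWa @ x[:3] + c * (CVa @ x[3:8]) + c0a * v_phi,
        },
    ]
    x0 = np.concatenate([_floor_simplex(np.maximum(w0, 1e-6)), _floor_simplex(np.maximum(v0, 1e-6))])
    res = optimize.minimize(
        negobj,
        x0,
        jac=negobj_grad,
        method="SLSQP",
        bounds=[(1e-12, 1.0)] * 8,
        constraints=eq_cons,
        options={"maxiter": 300, "ftol": 1e-14},
    )
    if not res.success:
        return None
    return _validate_candidate(
        a, b, v_phi, active, res.x[:3], res.x[3:8], None, residual_tol
    )


def _solve_full_inequality(a, b, v_phi, residual_tol):
    """Last-resort direct solve of the inequality-constrained weight problem."""
    c = 1.0 - v_phi

    def negobj(x):
        return -(a @ np.log(x[:3]) + b @ np.log(x[3:8]))

    def grad(x):
        return np.concatenate([-a / x[:3], -b / x[3:8]])

    res = optimize.minimize(
        negobj,
        np.concatenate([np.full(3, 1.0 / 3.0), np.full(5, 0.2)]),
        jac=grad,
        method="SLSQP",
        bounds=[(1e-12, 1.0)] * 8,
        constraints=[
            {"type": "eq", "fun": lambda x: x[:3].sum() - 1.0},
            {"type": "eq", "fun": lambda x: x[3:8].sum() - 1.0},
            {
                "type": "ineq",
                "fun": lambda x: cons._CW @ x[:3] + c * (cons._CV @ x[3:8]) + cons._C0 * v_phi,
            },
        ],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        return None
    w, v = res.x[:3], res.x[3:8]
    if np.any(w <= 0.0) or np.any(v <= 0.0):
        return None
    slack = cons.weight_slacks_B(w, v, v_phi)
    active = tuple(int(i) for i in np.flatnonzero(slack < 1e-8))
    u, resid = _multipliers_lstsq(a, b, v_phi, active, w, v)
    if resid > residual_tol:
        return None
    report = cons.check_weights_B(w, v, v_phi, tol=1e-9)
    if not report.satisfied:
        return None
    eta = np.zeros(8)
    eta[list(active)] = u[2:]
    return KKTSolution(
        w=w,
        v=v,
        active_set=tuple(cons.B_NAMES[i] for i in active),
        gamma=np.asarray(u[:2], dtype=float),
        eta=eta,
        residual=resid,
    )


def _solve_weights(a, b, v_phi, residual_tol=1e-8):
    """Maximize the weight part of Q under constraint set B (greedy active set)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # floor collapsed responsibility masses: keeps the stationarity system
    # well conditioned; inactive for any healthily populated component
    if a.sum() > 0 and a.min() < 1e-6 * a.sum():
        a = np.maximum(a, 1e-6 * a.sum())
    if b.sum() > 0 and b.min() < 1e-6 * b.sum():
        b = np.maximum(b, 1e-6 * b.sum())
    w0 = _floor_simplex(a)
    if b.sum() <= 0.0:
        # no observed second scores: the v-mixture carries no likelihood terms
        # and set B is vacuous at v_phi = 1
        return KKTSolution(
            w=w0,
            v=np.full(5, 0.2),
            active_set=(),
            gamma=np.array([-a.sum(), 0.0]),
            eta=np.zeros(8),
            residual=0.0,
        )
    v0 = _floor_simplex(b)
    report = cons.check_weights_B(w0, v0, v_phi)
    if report.satisfied:
        return KKTSolution(
            w=w0,
            v=v0,
            active_set=(),
            gamma=np.array([-a.sum(), -b.sum()]),
            eta=np.zeros(8),
            residual=0.0,
        )
    violated = tuple(cons.B_NAMES.index(n) for n in report.violated)
    pools = [violated, tuple(range(8))]
    tried = set()
    for pool in pools:
        for k in range(1, len(pool) + 1):
            found = []
            for active in itertools.combinations(pool, k):
                if active in tried:
                    continue
                tried.add(active)
                sol = _solve_active_set(a, b, v_phi, active, w0, v0, residual_tol)
                if sol is not None:
                    found.append(sol)
            if found:
                return max(found, key=lambda s: _weight_objective(a, b, s.w, s.v))
    sol = _solve_full_inequality(a, b, v_phi, residual_tol)
    if sol is not None:
        return sol
    raise FitError(
        "no feasible KKT stationary point found at any active-set level "
        f"(violated at the unconstrained optimum: {report.violated})"
    )


def solve_weights_kkt(resp: Responsibilities, v_phi: float, cur_weights=None) -> KKTSolution:
    """Constrained weight M-step from posterior responsibilities."""
    a = resp.omega.sum(axis=0)
    b = resp.nu.sum(axis=0) if resp.nu.size else np.zeros(5)
    return _solve_weights(a, b, v_phi)


# ---------------------------------------------------------------------------
# component conditional M-steps
# ---------------------------------------------------------------------------


def _commit(theta: dict, name: str, param: str, value: float) -> dict:
    out = cons._with_alt_param(theta, name, param, value)
    if out is None:  # pragma: no cover - guarded by feasibility checks
        raise FitError(f"invalid committed value {name}.{param}={value}")
    return out


def ecm_update_component(
    name: str,
    s: np.ndarray,
    r: np.ndarray,
    theta: dict,
    *,
    chain=cons.CHAIN_TWO_SAMPLE,
    n_grid: int = 128,
) -> dict:
    """One conditional-maximization pass for component ``name``.

    ``s`` and ``r`` are the pooled scores and responsibilities this component
    sees (both samples for the shared components C, J1, I1; second sample
    only for J2, I2).  Returns the theta map with the component updated in
    the order mu -> Delta -> Gamma, each candidate repaired onto the
    dominance-feasible region before committing.
    """
    cur = theta[name]
    mass = float(r.sum())
    if mass < _MASS_FLOOR:
        return theta  # freeze a component with no effective evidence
    xi = tn_moments(s, cur)
    alt = to_alternate(cur)

    mu_c = float((r * (s - alt.Delta * xi.xi1)).sum() / mass)
    mu_new = cons.binary_search_repair(
        name, "mu", alt.mu, mu_c, theta, chain=chain, n_grid=n_grid
    )
    theta = _commit(theta, name, "mu", mu_new)

    d = s - mu_new
    den = float((r * xi.xi2).sum())
    D_c = float((r * xi.xi1 * d).sum() / den)
    D_new = cons.binary_search_repair(
        name, "Delta", alt.Delta, D_c, theta, chain=chain, n_grid=n_grid
    )
    theta = _commit(theta, name, "Delta", D_new)

    G_c = float((r * (d * d - 2.0 * D_new * xi.xi1 * d + D_new**2 * xi.xi2)).sum() / mass)
    if G_c <= 0.0:  # numerically degenerate; keep the current residual variance
        G_c = to_alternate(theta[name]).Gamma
    G_new = cons.binary_search_repair(
        name, "Gamma", alt.Gamma, G_c, theta, chain=chain, n_grid=n_grid
    )
    theta = _commit(theta, name, "Gamma", G_new)
    return theta


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialization_schedule(n_rounds: int = 40):
    """Restart schedule: per round, shape magnitudes {1, 2, 5} x 2 signs of lambda_J1."""
    return [
        (rnd, lam0, sign)
        for rnd in range(n_rounds)
        for lam0 in _LAMBDA0_GRID
        for sign in (+1, -1)
    ]


_INIT_V = np.array([0.001, 0.999 / 4, 0.999 / 4, 0.999 / 4, 0.999 / 4])


def init_params(
    ds: ScoreDataset,
    lambda0: float,
    sign_J1: int,
    rng: np.random.Generator,
    *,
    one_sample: bool = False,
    max_tries: int = 1000,
):
    """Draw one chain-feasible random initialization.

    Locations are the sorted (descending) values of five (or three) draws
    from a normal fit to the top scores; scales are uniform on
    [sigma/4, sigma]; |lambda| is uniform on [1/lambda0, lambda0] with signs
    positive for C, negative for J2, I1, I2, and ``sign_J1`` for J1.
    Weight constraints are not required of the initial point.
    """
    if ds.n < 10:
        raise ValueError("need at least 10 spectra to initialize")
    mu0 = float(ds.s1.mean())
    sd0 = float(ds.s1.std())
    comps = S1_COMPONENTS if one_sample else S2_COMPONENTS
    chain = cons.CHAIN_ONE_SAMPLE if one_sample else cons.CHAIN_TWO_SAMPLE
    signs = {"C": 1.0, "J1": float(sign_J1), "J2": -1.0, "I1": -1.0, "I2": -1.0}
    lo, hi = min(1.0 / lambda0, lambda0), max(1.0 / lambda0, lambda0)
    for _ in range(max_tries):
        locs = np.sort(rng.normal(mu0, sd0, len(comps)))[::-1]
        sigmas = rng.uniform(sd0 / 4.0, sd0, len(comps))
        lams = rng.uniform(lo, hi, len(comps))
        theta = {
            name: SNParams(mu=float(m), sigma=float(sg), lam=float(signs[name] * la))
            for name, m, sg, la in zip(comps, locs, sigmas, lams)
        }
        if cons.check_chain(theta, chain)[0]:
            if one_sample:
                return OneSampleModel(theta=theta, w=np.full(3, 1.0 / 3.0))
            return TwoSampleModel(
                theta=theta,
                w=np.full(3, 1.0 / 3.0),
                v=_INIT_V.copy(),
                v_phi=ds.v_phi,
            )
    raise FitError(f"{max_tries} consecutive infeasible initializations")


# ---------------------------------------------------------------------------
# ECM driver
# ---------------------------------------------------------------------------


@dataclass
class ECMState:
    model: TwoSampleModel | OneSampleModel
    loglik_trace: np.ndarray
    iteration: int
    converged: bool
    max_active_set: int = 0
    restart_logliks: np.ndarray = field(default_factory=lambda: np.array([]))
    seed: int | None = None
    n_restarts: int = 0

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _norm_rows(L):
    # in-place row softmax returning (probs, log-sum) without scipy overhead
    m = L.max(axis=1)
    L -= m[:, None]
    np.exp(L, out=L)
    s = L.sum(axis=1)
    L /= s[:, None]
    return L, float((m + np.log(s)).sum())


def _estep(model, ds):
    """Responsibilities, per-component masses and the log-likelihood in one pass."""
    L1 = _log_weighted(ds.s1, S1_COMPONENTS, model.theta, model.w)
    omega, ll = _norm_rows(L1)
    if isinstance(model, TwoSampleModel):
        s2 = ds.s2_observed
        if s2.size:
            L2 = _log_weighted(s2, S2_COMPONENTS, model.theta, model.v)
            nu, ll2 = _norm_rows(L2)
            ll += ll2
        else:
            nu = np.empty((0, 5))
    else:
        nu = np.empty((0, 5))
    return omega, nu, ll


def _run_ecm(model, ds, *, tol, max_iter, n_grid):
    two_sample = isinstance(model, TwoSampleModel)
    chain = cons.CHAIN_TWO_SAMPLE if two_sample else cons.CHAIN_ONE_SAMPLE
    s2 = ds.s2_observed if two_sample else np.empty(0)
    s_pooled = np.concatenate([ds.s1, s2])
    s2_ix = {name: k for k, name in enumerate(S2_COMPONENTS)}
    omega, nu, ll = _estep(model, ds)
    trace = [ll]
    max_active = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta = dict(model.theta)
        comps = S2_COMPONENTS if two_sample else S1_COMPONENTS
        for name in comps:
            if name in S1_COMPONENTS:
                k1 = S1_COMPONENTS.index(name)
                if two_sample and nu.size:
                    s = s_pooled
                    r = np.concatenate([omega[:, k1], nu[:, s2_ix[name]]])
                else:
                    s, r = ds.s1, omega[:, k1]
            else:
                s, r = s2, nu[:, s2_ix[name]]
            theta = ecm_update_component(name, s, r, theta, chain=chain, n_grid=n_grid)
        a = omega.sum(axis=0)
        if two_sample:
            try:
                sol = _solve_weights(
                    a, nu.sum(axis=0) if nu.size else np.zeros(5), model.v_phi
                )
                w_new, v_new = sol.w, sol.v
                max_active = max(max_active, len(sol.active_set))
            except FitError:
                # pathological collapsed-component instance: the previous
                # weights remain set-B feasible, so keep them this iteration
                logger.debug("weight update failed numerically; keeping weights")
                w_new, v_new = model.w, model.v
            model = TwoSampleModel(theta=theta, w=w_new, v=v_new, v_phi=model.v_phi)
        else:
            model = OneSampleModel(theta=theta, w=_floor_simplex(a))
        omega, nu, ll = _estep(model, ds)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0) < tol:
            converged = True
            break
    return ECMState(
        model=model,
        loglik_trace=np.asarray(trace),
        iteration=it,
        converged=converged,
        max_active_set=max_active,
    )


def _fit_driver(
    ds,
    *,
    one_sample,
    n_restarts,
    seed,
    tol,
    max_iter,
    n_grid,
    init_model=None,
    screen_iters=None,
    screen_top=8,
) -> ECMState:
    if ds.n == 0:
        raise ValueError("empty dataset")
    schedule = initialization_schedule(math.ceil(n_restarts / 6))[:n_restarts]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(schedule))
    inits = [] if init_model is None else [init_model]
    for (rnd, lam0, sign), cs in zip(schedule, children):
        rng = np.random.default_rng(cs)
        inits.append(init_params(ds, lam0, sign, rng, one_sample=one_sample))
    if not inits:
        raise ValueError("n_restarts = 0 requires an init_model")

    def run_all(models, iters, data):
        states, lls = [], []
        for i, m0 in enumerate(models):
            try:
                st = _run_ecm(m0, data, tol=tol, max_iter=iters, n_grid=n_grid)
            except FitError as exc:
                logger.warning("restart %d failed: %s", i, exc)
                states.append(None)
                lls.append(float("nan"))
                continue
            states.append(st)
            lls.append(st.loglik)
            logger.debug(
                "restart %d: loglik=%.4f iters=%d max_active=%d",
                i, st.loglik, st.iteration, st.max_active_set,
            )
        return states, np.asarray(lls)

    if screen_iters is not None and len(inits) > screen_top:
        # short runs for every initialization on a fixed subsample (ranking
        # basins of attraction does not need the full data), full runs for
        # the leaders
        if ds.n > _SCREEN_N:
            sub_rng = np.random.default_rng(ss.spawn(1)[0])
            idx = sub_rng.choice(ds.n, size=_SCREEN_N, replace=False)
            ds_screen = ScoreDataset(s1=ds.s1[idx], s2=ds.s2[idx])
        else:
            ds_screen = ds
        states, lls = run_all(inits, screen_iters, ds_screen)
        order = np.argsort(np.nan_to_num(lls, nan=-np.inf))[::-1][:screen_top]
        survivors = [states[i].model for i in order if states[i] is not None]
        states2, lls2 = run_all(survivors, max_iter, ds)
        finals = lls.copy()
        for j, i in enumerate(order):
            if not np.isnan(lls2[j]):
                finals[i] = lls2[j]
        candidates = [s for s in states2 if s is not None]
        max_active0 = max(
            (s.max_active_set for s in states if s is not None), default=0
        )
    else:
        candidates_all, finals = run_all(inits, max_iter, ds)
        candidates = [s for s in candidates_all if s is not None]
        max_active0 = 0
    if not candidates:
        raise FitError("all restarts failed numerically")
    best = max(candidates, key=lambda s: s.loglik)
    # polish the winner at a tighter tolerance
    polished = _run_ecm(
        best.model, ds, tol=tol * 0.1, max_iter=2 * max_iter, n_grid=n_grid
    )
    if polished.loglik >= best.loglik:
        polished.max_active_set = max(
            polished.max_active_set, best.max_active_set, max_active0
        )
        best = polished
    best.restart_logliks = np.asarray(finals)
    best.seed = seed
    best.n_restarts = len(inits)
    return best


def fit(
    ds: ScoreDataset,
    n_restarts: int = 240,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    *,
    n_grid: int = 128,
    init_model: TwoSampleModel | None = None,
    screen_iters: int | None = None,
    screen_top: int = 8,
) -> ECMState:
    """Fit the two-sample constrained mixture; returns the best restart.

    Deterministic given ``seed``.  ``init_model``, when given, is run as an
    additional first initialization (used e.g. to warm-start bootstrap
    replicates from the full-data fit).  ``screen_iters`` enables a
    short-run screening stage: every initialization runs that many
    iterations, and only the ``screen_top`` best continue to ``max_iter``;
    the winner is always polished at a 10x tighter tolerance.
    """
    return _fit_driver(
        ds,
        one_sample=False,
        n_restarts=n_restarts,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
        n_grid=n_grid,
        init_model=init_model,
        screen_iters=screen_iters,
        screen_top=screen_top,
    )


def fit_one_sample(
    ds: ScoreDataset,
    n_restarts: int = 240,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    *,
    n_grid: int = 128,
    init_model: OneSampleModel | None = None,
    screen_iters: int | None = None,
    screen_top: int = 8,
) -> ECMState:
    """Fit the top-score-only three-component mixture (chain C > J1 > I1)."""
    return _fit_driver(
        ds,
        one_sample=True,
        n_restarts=n_restarts,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
        n_grid=n_grid,
        init_model=init_model,
        screen_iters=screen_iters,
        screen_top=screen_top,
    )
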