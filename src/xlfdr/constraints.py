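"""Weight and density constraints for the constrained mixture fit.

Two constraint families encode the competition structure of ranked PSM
scores:

* *Weight constraints* (set B, inequalities b1..b8) bound each top-score
  mixing proportion by combinations of second-score proportions and vice
  versa; second-score proportions enter scaled by the observed fraction,
  ``v'_Y = (1 - v_phi) * v_Y``, so the constraints stay valid under the
  non-random missingness of second scores.  Set A is the special case
  ``v_phi = 0``.

* *Density dominance* ``f > g`` (written f ≻ g): a strict partial order
  requiring mode(f) > mode(g), f above g everywhere right of f's mode, and
  g above f everywhere left of g's mode.  The fit enforces the chain
  C ≻ J1 ≻ J2 ≻ I1 ≻ I2 (transitivity gives the rest).

The "for all x" dominance conditions are evaluated on a bounded window
extending ``window`` (default 4) scale units past each mode, on a dense
grid.  Literal enforcement out to infinity would compare quadratic
tail-decay coefficients, and under that reading two components with equal
shape magnitude can only dominate each other with *exactly* equal scales —
a measure-zero event that the random initialization could never satisfy.
The bounded window covers the region carrying all but ~1e-4 of each
component's mass, i.e. everywhere the likelihood and the FDR inversion can
see data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._fast import dominates_scalar
from .sn import SNParams, from_alternate, to_alternate

__all__ = [
    "B_NAMES",
    "CHAIN_TWO_SAMPLE",
    "CHAIN_ONE_SAMPLE",
    "WeightConstraintReport",
    "DominancePair",
    "weight_slacks_B",
    "check_weights_B",
    "check_weights_A",
    "check_dominance",
    "check_chain",
    "binary_search_repair",
]

B_NAMES = ("b1", "b2", "b3", "b4", "b5", "b6", "b7", "b8")

CHAIN_TWO_SAMPLE = (("C", "J1"), ("J1", "J2"), ("J2", "I1"), ("I1", "I2"))
CHAIN_ONE_SAMPLE = (("C", "J1"), ("J1", "I1"))

_TOL = 1e-12  # comparison tolerance: avoids chatter at exact equality

# Linear form of each set-B slack:  g = cw . w + (1 - v_phi) * (cv . v) + c0 * v_phi,
# with w over (C, J1, I1) and v over (C, J1, J2, I1, I2); feasible iff g >= 0.
_CW = np.array(
    [
        [-1, 0, 0],  # b1: wC  <= v'J1 + v'I1 + v_phi
        [0, -1, 0],  # b2: wJ1 <= v'C + v'J2 + v'I1 + v_phi
        [0, 0, -1],  # b3: wI1 <= v'C + v'J1 + v'I2 + v_phi
        [0, 1, 1],  # b4: v'C  <= wJ1 + wI1
        [1, 0, 1],  # b5: v'J1 <= wC + wI1
        [1, 1, 0],  # b6: v'I1 <= wC + wJ1
        [0, 1, 0],  # b7: v'J2 <= wJ1
        [0, 0, 1],  # b8: v'I2 <= wI1
    ],
    dtype=float,
)
_CV = np.array(
    [
        [0, 1, 0, 1, 0],
        [1, 0, 1, 1, 0],
        [1, 1, 0, 0, 1],
        [-1, 0, 0, 0, 0],
        [0, -1, 0, 0, 0],
        [0, 0, 0, -1, 0],
        [0, 0, -1, 0, 0],
        [0, 0, 0, 0, -1],
    ],
    dtype=float,
)
_C0 = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)


@dataclass(frozen=True)
class WeightConstraintReport:
    violated: tuple[str, ...]
    slacks: dict

    @property
    def satisfied(self) -> bool:
        return not self.violated


@dataclass(frozen=True)
class DominancePair:
    upper: str
    lower: str


def weight_slacks_B(w, v, v_phi: float) -> np.ndarray:
    """Slack of each of the eight set-B inequalities (feasible iff >= 0)."""
    w = np.asarray(w, dtype=float)
    v = np.asarray(v, dtype=float)
    return _CW @ w + (1.0 - v_phi) * (_CV @ v) + _C0 * v_phi


def check_weights_B(w, v, v_phi: float, tol: float = _TOL) -> WeightConstraintReport:
    """Evaluate constraint set B at (w, v) with missingness constant v_phi."""
    if not 0.0 <= v_phi <= 1.0:
        raise ValueError("v_phi must lie in [0, 1]")
    slacks = weight_slacks_B(w, v, v_phi)
    violated = tuple(n for n, s in zip(B_NAMES, slacks) if s < -tol)
    return WeightConstraintReport(violated=violated, slacks=dict(zip(B_NAMES, slacks)))


def check_weights_A(w, v, tol: float = _TOL) -> WeightConstraintReport:
    """Constraint set A: set B with no missing second scores (v_phi = 0)."""
    return check_weights_B(w, v, 0.0, tol=tol)


DOMINANCE_WINDOW = 4.0  # window half-width past each mode, in units of max sigma

def _dominates(
    fmu: float,
    fsg: float,
    fla: float,
    gmu: float,
    gsg: float,
    gla: float,
    n_grid: int,
    window: float,
    tol: float,
) -> bool:
    # raw-float kernel shared by check_dominance and the repair hot path
    return dominates_scalar(fmu, fsg, fla, gmu, gsg, gla, n_grid, window, tol)


def check_dominance(
    f: SNParams,
    g: SNParams,
    *,
    n_grid: int = 512,
    window: float = DOMINANCE_WINDOW,
    tol: float = _TOL,
) -> bool:
    """True iff f strictly dominates g (f ≻ g) on the evaluation window.

    Checks mode(f) > mode(g); f above g on (mode(f), mode(f) + window*smax];
    g above f on [mode(g) - window*smax, mode(g)), with smax the larger of
    the two scales.
    """
    return _dominates(
        f.mu, f.sigma, f.lam, g.mu, g.sigma, g.lam, n_grid, window, tol
    )


def check_chain(
    theta, chain=CHAIN_TWO_SAMPLE, *, n_grid: int = 512
) -> tuple[bool, DominancePair | None]:
    """Check every enforced dominance pair; returns (ok, first violated pair)."""
    for upper, lower in chain:
        if not check_dominance(theta[upper], theta[lower], n_grid=n_grid):
            return False, DominancePair(upper=upper, lower=lower)
    return True, None


def _pairs_involving(component: str, chain) -> tuple:
    return tuple(p for p in chain if component in p)


def _with_alt_param(
    theta: dict, component: str, param: str, value: float
) -> dict | None:
    """Copy of theta with one alternate-form parameter replaced; None if invalid."""
    a = to_alternate(theta[component])
    try:
        a = replace(a, **{param: value})
        p = from_alternate(a)
    except ValueError:
        return None
    out = dict(theta)
    out[component] = p
    return out


def _alt_triplet(p: SNParams) -> tuple[float, float, float]:
    a = to_alternate(p)
    return a.mu, a.Delta, a.Gamma


_PARAM_IX = {"mu": 0, "Delta": 1, "Gamma": 2}


def _canon(alt: tuple[float, float, float]) -> tuple[float, float, float] | None:
    mu, D, G = alt
    if G <= 0.0:
        return None
    sigma = math.sqrt(G + D * D)
    lam = math.copysign(math.sqrt(D * D / G), D)
    return mu, sigma, lam


class _RepairProblem:
    """Feasibility of one varying alternate-form parameter against fixed neighbours."""

    def __init__(self, component, param, theta_context, chain, n_grid, window=DOMINANCE_WINDOW):
        self.ix = _PARAM_IX[param]
        self.base = list(_alt_triplet(theta_context[component]))
        self.n_grid = n_grid
        self.window = window
        # (other canonical triple, True if the varying component is the upper one)
        self.pairs = [
            (
                (
                    theta_context[l].mu,
                    theta_context[l].sigma,
                    theta_context[l].lam,
                )
                if u == component
                else (
                    theta_context[u].mu,
                    theta_context[u].sigma,
                    theta_context[u].lam,
                ),
                u == component,
            )
            for u, l in chain
            if component in (u, l)
        ]

    def feasible(self, value: float, tol: float = _TOL) -> bool:
        alt = list(self.base)
        alt[self.ix] = value
        c = _canon(tuple(alt))
        if c is None:
            return False
        for i, (other, is_upper) in enumerate(self.pairs):
            args = (*c, *other) if is_upper else (*other, *c)
            if not _dominates(*args, self.n_grid, self.window, tol):
                if i:  # re-check the failing pair first next time
                    self.pairs.insert(0, self.pairs.pop(i))
                return False
        return True


def _feasible_at(
    theta: dict, component: str, param: str, value: float, pairs, n_grid: int
) -> bool:
    cand = _with_alt_param(theta, component, param, value)
    if cand is None:
        return False
    return all(check_dominance(cand[u], cand[l], n_grid=n_grid) for u, l in pairs)


def binary_search_repair(
    component: str,
    param: str,
    old_value: float,
    candidate_value: float,
    theta_context: dict,
    *,
    chain=CHAIN_TWO_SAMPLE,
    n_iter: int = 60,
    n_grid: int = 192,
) -> float:
    """Pull an infeasible parameter candidate back to the feasible region.

    Bisects the segment [old_value, candidate_value] of one alternate-form
    parameter (``param`` in {"mu", "Delta", "Gamma"}) and returns the feasible
    point closest to the candidate, to within 1e-9 of the segment length.
    Requires the old value to be feasible (which the fit guarantees by
    starting from a chain-feasible model); only the dominance pairs involving
    ``component`` are re-evaluated since the rest of the chain is untouched.
    """
    if param not in ("mu", "Delta", "Gamma"):
        raise ValueError(f"unknown parameter {param!r}")
    prob = _RepairProblem(component, param, theta_context, chain, n_grid)
    if prob.feasible(candidate_value):
        return candidate_value
    if not prob.feasible(old_value):
        # a previously committed boundary point can drift by ulps through
        # parametrization round-trips; treat it as "on the boundary" rather
        # than a contract violation, and do not move it further
        if prob.feasible(old_value, tol=1e-9):
            return old_value
        raise RuntimeError(
            f"binary_search_repair: old value of {component}.{param} is infeasible"
        )
    step = candidate_value - old_value
    lo, hi = old_value, candidate_value  # lo feasible, hi infeasible
    xtol = 1e-9 * abs(step)
    for _ in range(n_iter):
        if abs(hi - lo) <= xtol:
            break
        mid = 0.5 * (lo + hi)
        if prob.feasible(mid):
            lo = mid
        else:
            hi = mid
    if lo == old_value:
        return old_value
    # back off marginally from the boundary so the committed point survives
    # parametrization round-trips; stays within 1e-8 of the true boundary
    for k in (1e-9, 1e-7, 1e-5):
        backed = lo - k * step
        if prob.feasible(backed):
            return backed
    return old_value
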