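"""One- and two-sample SN mixture models for ranked PSM scores.

The two-sample model couples the top-score sample S1 and the second-score
sample S2 through shared components:

    S1 ~ wC*SN(thC) + wJ1*SN(thJ1) + wI1*SN(thI1)
    S2 ~ vC*SN(thC) + vJ1*SN(thJ1) + vJ2*SN(thJ2) + vI1*SN(thI1) + vI2*SN(thI2)

where C is the correct match, J1/J2 the best and second-best partially
incorrect matches, and I1/I2 the best and second-best fully incorrect
matches.  Sharing thC, thJ1, thI1 between the mixtures is what lets the
second-ranked scores inform the placement of the top-score components.

The observed-data log-likelihood sums the S1 mixture over all spectra and
the S2 mixture over spectra with an observed second score; missingness of
s2 enters the estimation only through the constant ``v_phi`` in the weight
constraint set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .data import ScoreDataset
from .sn import SNParams, sn_logpdf, tn_moments, to_alternate

__all__ = [
    "S1_COMPONENTS",
    "S2_COMPONENTS",
    "TwoSampleModel",
    "OneSampleModel",
    "Responsibilities",
    "loglik",
    "responsibilities",
    "q_function",
]

S1_COMPONENTS = ("C", "J1", "I1")
S2_COMPONENTS = ("C", "J1", "J2", "I1", "I2")


def _check_simplex(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError(f"{name} must be strictly positive")
    if abs(x.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must sum to 1, got {x.sum()}")
    return x


@dataclass
class TwoSampleModel:
    """Five shared-component mixture over (S1, S2) plus the missingness constant."""

    theta: Mapping[str, SNParams]
    w: np.ndarray  # over (C, J1, I1)
    v: np.ndarray  # over (C, J1, J2, I1, I2)
    v_phi: float

    def __post_init__(self) -> None:
        missing = [c for c in S2_COMPONENTS if c not in self.theta]
        if missing:
            raise ValueError(f"theta missing components: {missing}")
        self.w = _check_simplex(self.w, "w")
        self.v = _check_simplex(self.v, "v")
        if self.w.size != 3 or self.v.size != 5:
            raise ValueError("w must have 3 entries and v 5")
        if not 0.0 <= self.v_phi <= 1.0:
            raise ValueError("v_phi must lie in [0, 1]")


@dataclass
class OneSampleModel:
    """Three-component mixture over the top scores only."""

    theta: Mapping[str, SNParams]
    w: np.ndarray  # over (C, J1, I1)

    def __post_init__(self) -> None:
        missing = [c for c in S1_COMPONENTS if c not in self.theta]
        if missing:
            raise ValueError(f"theta missing components: {missing}")
        self.w = _check_simplex(self.w, "w")
        if self.w.size != 3:
            raise ValueError("w must have 3 entries")


@dataclass
class Responsibilities:
    """Posterior component memberships (rows sum to 1).

    ``omega``: per-s1 probabilities over (C, J1, I1); ``nu``: per observed-s2
    probabilities over (C, J1, J2, I1, I2).  These realize the conditional
    expectations of the hidden component indicators in the EM derivation.
    """

    omega: np.ndarray
    nu: np.ndarray


def _log_weighted(s: np.ndarray, comps, theta, weights) -> np.ndarray:
    """Matrix of log(w_k) + logpdf(s; theta_k), one column per component."""
    out = np.empty((s.size, len(comps)))
    logw = np.log(weights)
    for k, name in enumerate(comps):
        out[:, k] = logw[k] + sn_logpdf(s, theta[name])
    return out


def _is_two_sample(model) -> bool:
    return isinstance(model, TwoSampleModel)


def loglik(model, ds: ScoreDataset) -> float:
    """Observed-data log-likelihood.

    S1 terms run over every spectrum; S2 terms only over spectra with an
    observed second score.  All mixture sums use log-sum-exp.
    """
    L1 = _log_weighted(ds.s1, S1_COMPONENTS, model.theta, model.w)
    total = float(logsumexp(L1, axis=1).sum())
    if _is_two_sample(model):
        s2 = ds.s2_observed
        if s2.size:
            L2 = _log_weighted(s2, S2_COMPONENTS, model.theta, model.v)
            total += float(logsumexp(L2, axis=1).sum())
    return total


def _softmax_rows(L: np.ndarray) -> np.ndarray:
    L = L - L.max(axis=1, keepdims=True)
    np.exp(L, out=L)
    L /= L.sum(axis=1, keepdims=True)
    return L


def responsibilities(model, ds: ScoreDataset) -> Responsibilities:
    """Posterior membership probabilities under the current parameters."""
    omega = _softmax_rows(_log_weighted(ds.s1, S1_COMPONENTS, model.theta, model.w))
    if _is_two_sample(model):
        s2 = ds.s2_observed
        if s2.size:
            nu = _softmax_rows(_log_weighted(s2, S2_COMPONENTS, model.theta, model.v))
        else:
            nu = np.empty((0, 5))
    else:
        nu = np.empty((0, 5))
    return Responsibilities(omega=omega, nu=nu)


def _q_kernel(s: np.ndarray, theta_new: SNParams, theta_cur: SNParams) -> np.ndarray:
    """Per-score Q(s, theta, theta_bar) = q(s, xi1, xi2, theta_new).

    q(s, t, tau, theta) = log Gamma + ((s-mu)^2 - 2(s-mu)*Delta*t
                                        + (Delta^2 + Gamma)*tau) / Gamma,
    with the truncated-normal moments (t, tau) evaluated at the *current*
    parameters theta_bar.
    """
    xi = tn_moments(s, theta_cur)
    a = to_alternate(theta_new)
    d = s - a.mu
    num = d * d - 2.0 * d * a.Delta * xi.xi1 + (a.Delta**2 + a.Gamma) * xi.xi2
    return np.log(a.Gamma) + num / a.Gamma


def q_function(new, cur, ds: ScoreDataset) -> float:
    """EM Q-function: E[complete-data log-likelihood | data, cur] at ``new``.

    Responsibilities and truncated-normal moments come from ``cur`` only.
    """
    resp = responsibilities(cur, ds)
    logw = np.log(np.asarray(new.w, dtype=float))
    total = 0.0
    for k, name in enumerate(S1_COMPONENTS):
        q = _q_kernel(ds.s1, new.theta[name], cur.theta[name])
        total += float((resp.omega[:, k] * (logw[k] - 0.5 * q)).sum())
    if _is_two_sample(new):
        s2 = ds.s2_observed
        if s2.size:
            logv = np.log(np.asarray(new.v, dtype=float))
            for k, name in enumerate(S2_COMPONENTS):
                q = _q_kernel(s2, new.theta[name], cur.theta[name])
                total += float((resp.nu[:, k] * (logv[k] - 0.5 * q)).sum())
    return total
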