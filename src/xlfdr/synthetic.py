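"""Labelled synthetic score generators and the ground-truth FDR oracle.

Two deliberately different generators:

* :func:`sample_mixture_faithful` draws (s1, s2) independently from the
  exact two-sample mixture — truth equals the fitted model family, so it
  tests parameter recovery.
* :func:`sample_competition` simulates the latent competition that the
  mixture approximates: per spectrum a correct candidate (present with
  probability ``rho_correct``), an ordered pair of partially incorrect
  candidates (j1 >= j2) and an ordered pair of incorrect candidates
  (i1 >= i2) compete; s1 is the best present candidate, s2 the structural
  runner-up, and the second score is then dropped with a logistic
  probability decreasing in s1 (missingness concentrates in the left tail,
  as in real searches).

Because every record carries its generating component, the true FDR at any
threshold is a simple labelled recount, giving an oracle for calibration
tests.  A separate generator produces exchangeable target/decoy-labelled
scores for the target-decoy baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from scipy.optimize import brentq

from .data import ScoreDataset
from .model import S1_COMPONENTS, S2_COMPONENTS, TwoSampleModel
from .sn import SNParams, sample_sn, sn_cdf

__all__ = [
    "LabeledDataset",
    "default_model",
    "sample_mixture_faithful",
    "sample_competition",
    "true_fdr",
    "sample_tda",
]

_MISSING_LABEL = ""


@dataclass
class LabeledDataset:
    """Scores plus ground-truth component labels (label2 empty when s2 missing)."""

    s1: np.ndarray
    s2: np.ndarray
    label1: np.ndarray
    label2: np.ndarray

    @property
    def n(self) -> int:
        return self.s1.size

    @property
    def v_phi(self) -> float:
        return float(np.isnan(self.s2).mean())

    def to_score_dataset(self) -> ScoreDataset:
        return ScoreDataset(s1=self.s1.copy(), s2=self.s2.copy())


def default_model(v_phi: float = 0.3) -> TwoSampleModel:
    """Reference two-sample scenario with realistic search-score morphology.

    Five chain-ordered components on a typical search-engine score scale:
    a right-skewed correct component on the right, left-skewed partially
    incorrect and incorrect components below it, with increasing left-tail
    spread and increasingly negative skewness down the chain (which is what
    dominance of both tails requires).  Weights reflect a search where most
    top hits are incorrect, and the runner-up of an incorrect top hit is
    usually the second incorrect candidate.
    """
    theta = {
        "C": SNParams(mu=40.0, sigma=5.0, lam=2.0),
        "J1": SNParams(mu=30.0, sigma=5.0, lam=-2.0),
        "J2": SNParams(mu=23.5, sigma=5.0, lam=-2.5),
        "I1": SNParams(mu=17.0, sigma=5.5, lam=-2.5),
        "I2": SNParams(mu=10.0, sigma=5.5, lam=-3.0),
    }
    w = np.array([0.15, 0.25, 0.60])
    v = np.array([0.01, 0.19, 0.18, 0.22, 0.40])
    return TwoSampleModel(theta=theta, w=w, v=v, v_phi=v_phi)


def sample_mixture_faithful(model: TwoSampleModel, n: int, seed: int) -> LabeledDataset:
    """Draw n spectra exactly from the two-sample mixture, with labels."""
    rng = np.random.default_rng(seed)
    k1 = rng.choice(3, size=n, p=np.asarray(model.w, dtype=float))
    s1 = np.empty(n)
    for k, name in enumerate(S1_COMPONENTS):
        mask = k1 == k
        s1[mask] = sample_sn(rng, model.theta[name], int(mask.sum()))
    miss = rng.random(n) < model.v_phi
    s2 = np.full(n, np.nan)
    label2 = np.full(n, _MISSING_LABEL, dtype="<U2")
    n_obs = int((~miss).sum())
    k2 = rng.choice(5, size=n_obs, p=np.asarray(model.v, dtype=float))
    vals = np.empty(n_obs)
    labs = np.empty(n_obs, dtype="<U2")
    for k, name in enumerate(S2_COMPONENTS):
        mask = k2 == k
        vals[mask] = sample_sn(rng, model.theta[name], int(mask.sum()))
        labs[mask] = name
    s2[~miss] = vals
    label2[~miss] = labs
    label1 = np.array(S1_COMPONENTS, dtype="<U2")[k1]
    return LabeledDataset(s1=s1, s2=s2, label1=label1, label2=label2)


def _sn_ppf(q: float, p: SNParams) -> float:
    lo, hi = p.mu - 15.0 * p.sigma, p.mu + 15.0 * p.sigma
    return float(brentq(lambda x: float(sn_cdf(x, p)) - q, lo, hi, xtol=1e-10))


def _ordered_pair(rng, theta_hi: SNParams, theta_lo: SNParams, n: int, max_rounds=100):
    """(hi, lo) with lo ~ SN(theta_lo) conditioned on lo <= hi ~ SN(theta_hi).

    Vectorized rejection; the rare stubborn points (hi deep in the left
    tail, where the acceptance probability vanishes) fall back to exact
    inverse-CDF sampling of the truncated conditional.
    """
    hi = sample_sn(rng, theta_hi, n)
    lo = sample_sn(rng, theta_lo, n)
    bad = lo > hi
    first_rate = float(bad.mean())
    if first_rate > 0.99:
        raise ValueError(
            f"ordered-pair rejection rate {first_rate:.3f} > 0.99; "
            "lower component lies far above the upper one"
        )
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            for i in np.flatnonzero(bad):  # inverse-CDF conditional draw
                q_hi = float(sn_cdf(hi[i], theta_lo))
                if q_hi <= 1e-300:
                    lo[i] = hi[i]  # conditional mass degenerates at the bound
                    continue
                lo[i] = _sn_ppf(rng.random() * q_hi, theta_lo)
            break
        lo[bad] = sample_sn(rng, theta_lo, int(bad.sum()))
        bad = lo > hi
    return hi, lo


def sample_competition(
    theta: dict,
    rho_correct: float,
    missing_params: tuple[float, float],
    n: int,
    seed: int,
) -> LabeledDataset:
    """Simulate the candidate competition that generates ranked scores.

    ``missing_params = (slope, intercept)``: after competition, s2 is dropped
    with probability ``expit(intercept - slope * s1)``; slope > 0 makes
    missingness left-tail-preferential, slope = 0 makes it independent of s1.
    """
    if not 0.0 <= rho_correct <= 1.0:
        raise ValueError("rho_correct must lie in [0, 1]")
    slope, intercept = missing_params
    if slope < 0.0:
        raise ValueError("missingness slope must be >= 0")
    rng = np.random.default_rng(seed)
    c = sample_sn(rng, theta["C"], n)
    present = rng.random(n) < rho_correct
    c_eff = np.where(present, c, -np.inf)
    j1, j2 = _ordered_pair(rng, theta["J1"], theta["J2"], n)
    i1, i2 = _ordered_pair(rng, theta["I1"], theta["I2"], n)

    top_cands = np.stack([c_eff, j1, i1], axis=1)
    k1 = np.argmax(top_cands, axis=1)
    s1 = top_cands[np.arange(n), k1]
    label1 = np.array(S1_COMPONENTS, dtype="<U2")[k1]

    # structural runner-up given who won the top slot
    s2 = np.empty(n)
    label2 = np.empty(n, dtype="<U2")
    runner_sets = {
        0: (("J1", j1), ("I1", i1)),  # top = C
        1: (("C", c_eff), ("J2", j2), ("I1", i1)),  # top = J1
        2: (("C", c_eff), ("J1", j1), ("I2", i2)),  # top = I1
    }
    for k, cands in runner_sets.items():
        mask = k1 == k
        if not mask.any():
            continue
        names = np.array([nm for nm, _ in cands], dtype="<U2")
        block = np.stack([arr[mask] for _, arr in cands], axis=1)
        kk = np.argmax(block, axis=1)
        s2[mask] = block[np.arange(int(mask.sum())), kk]
        label2[mask] = names[kk]

    miss = rng.random(n) < expit(intercept - slope * s1)
    miss |= ~np.isfinite(s2)  # no finite runner-up (absent correct candidate edge)
    s2 = np.where(miss, np.nan, s2)
    label2 = np.where(miss, _MISSING_LABEL, label2)
    return LabeledDataset(s1=s1, s2=s2, label1=label1, label2=label2)


def true_fdr(ds: LabeledDataset, tau: float) -> float:
    """Fraction of accepted top scores (s1 >= tau) whose label is not C."""
    accepted = ds.s1 >= tau
    if not accepted.any():
        return 0.0
    return float((ds.label1[accepted] != "C").mean())


def sample_tda(
    theta_correct: SNParams,
    theta_incorrect: SNParams,
    n_target: int,
    decoy_fraction: float,
    seed: int,
    *,
    n_incorrect: int | None = None,
) -> list[tuple[float, str]]:
    """Exchangeable target/decoy-labelled top-PSM scores.

    ``n_target`` correct PSMs score from ``theta_correct`` and are always TT.
    ``n_incorrect`` (default: equal) incorrect PSMs score from
    ``theta_incorrect``; each of their two peptides is independently a decoy
    with probability ``decoy_fraction``, so labels follow the binomial
    pairing (TT, TD, DD) ~ ((1-d)^2, 2d(1-d), d^2).  The (TD - DD)/TT
    estimator is unbiased for the true FDR exactly at d = 1/2.
    """
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1]")
    if n_incorrect is None:
        n_incorrect = n_target
    rng = np.random.default_rng(seed)
    out: list[tuple[float, str]] = []
    for s in sample_sn(rng, theta_correct, n_target):
        out.append((float(s), "TT"))
    d = decoy_fraction
    labels = rng.choice(
        ["TT", "TD", "DD"], size=n_incorrect, p=[(1 - d) ** 2, 2 * d * (1 - d), d**2]
    )
    scores = sample_sn(rng, theta_incorrect, n_incorrect)
    out.extend((float(s), str(lab)) for s, lab in zip(scores, labels))
    return out
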