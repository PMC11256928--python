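"""FDR estimation: model-based (decoy-free) and target-decoy baseline.

The decoy-free estimate at threshold tau is the mixture tail ratio

    FDR(tau) = [wI1*S(tau; thI1) + wJ1*S(tau; thJ1)]
               / [wC*S(tau; thC) + wI1*S(tau; thI1) + wJ1*S(tau; thJ1)],

with S the SN survival function — the expected fraction of accepted top
PSMs that are not correct matches.  The target-decoy baseline counts top
PSMs above tau by label (TT: both peptides target, TD: exactly one decoy,
DD: both decoy) and estimates FDR(tau) = (TD - DD) / TT, which can be
negative or exceed one; values are reported unclamped with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import S1_COMPONENTS
from .sn import sn_survival

__all__ = [
    "TDACounts",
    "TdaEstimate",
    "FDRCurve",
    "mixture_fdr",
    "fdr_threshold",
    "tda_counts",
    "tda_fdr",
    "tda_threshold",
    "fdr_curve",
]

TDA_LABELS = ("TT", "TD", "DD")


@dataclass(frozen=True)
class TDACounts:
    """Counts of top PSMs at scores >= tau by target/decoy label."""

    TT: int
    TD: int
    DD: int

    def __post_init__(self) -> None:
        if min(self.TT, self.TD, self.DD) < 0:
            raise ValueError("counts must be non-negative")


class TdaEstimate(NamedTuple):
    fdr: float
    over_one: bool


@dataclass
class FDRCurve:
    thresholds: np.ndarray
    fdr: np.ndarray
    n_identified: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.thresholds, "fdr_est": self.fdr, "n_identified": self.n_identified}
        )


def mixture_fdr(model, tau):
    """Model-based FDR estimate at threshold(s) ``tau``, in [0, 1].

    Where the S1 survival underflows entirely (tau far beyond every
    component) the estimate is the analytic limit 0: the dominance chain
    makes the correct component's right tail the heaviest.
    """
    tau = np.asarray(tau, dtype=float)
    w = np.asarray(model.w, dtype=float)
    surv = {name: sn_survival(tau, model.theta[name]) for name in S1_COMPONENTS}
    num = w[1] * surv["J1"] + w[2] * surv["I1"]
    den = w[0] * surv["C"] + num
    out = np.divide(num, den, out=np.zeros_like(den), where=den > 0.0)
    return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))


def _threshold_envelope(grid: np.ndarray, values: np.ndarray, alpha: float):
    """Smallest grid point from which the running suffix maximum stays <= alpha."""
    env = np.maximum.accumulate(values[::-1])[::-1]
    ok = env <= alpha
    if not ok.any():
        return None
    return int(np.argmax(ok))


def fdr_threshold(model, alpha: float, *, grid_size: int = 4096) -> float:
    """Score threshold achieving estimated FDR <= alpha for all higher scores.

    Inverts the monotone envelope of :func:`mixture_fdr` on a fine grid,
    refined by bisection.  Returns ``-inf`` when the FDR is below alpha
    everywhere and ``+inf`` when alpha is unattainable.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mus = np.array([model.theta[c].mu for c in S1_COMPONENTS])
    sds = np.array([model.theta[c].sigma for c in S1_COMPONENTS])
    lo = float((mus - 6.0 * sds).min())
    hi = float((mus + 8.0 * sds).max())
    grid = np.linspace(lo, hi, grid_size)
    vals = mixture_fdr(model, grid)
    idx = _threshold_envelope(grid, vals, alpha)
    if idx is None:
        return math.inf
    if idx == 0:
        return -math.inf
    # pointwise FDR crosses alpha inside (grid[idx-1], grid[idx]); bisect it
    a, b = float(grid[idx - 1]), float(grid[idx])
    xtol = 1e-6 * (hi - lo)
    while b - a > xtol:
        mid = 0.5 * (a + b)
        if mixture_fdr(model, mid) <= alpha:
            b = mid
        else:
            a = mid
    return b


def tda_counts(psms: Sequence[tuple[float, str]], tau: float) -> TDACounts:
    """Count labelled top PSMs with score >= tau."""
    if len(psms) == 0:
        raise ValueError("empty PSM list")
    tallies = {lab: 0 for lab in TDA_LABELS}
    for score, label in psms:
        if label not in tallies:
            raise ValueError(f"unknown label {label!r}")
        if score >= tau:
            tallies[label] += 1
    return TDACounts(TT=tallies["TT"], TD=tallies["TD"], DD=tallies["DD"])


def tda_fdr(counts: TDACounts) -> TdaEstimate:
    """Target-decoy estimate (TD - DD) / TT, unclamped."""
    if counts.TT < 1:
        raise ValueError("TDA FDR undefined with TT = 0")
    est = (counts.TD - counts.DD) / counts.TT
    return TdaEstimate(fdr=est, over_one=est > 1.0)


def tda_threshold(psms: Sequence[tuple[float, str]], alpha: float) -> float:
    """Smallest observed score at which the TDA envelope estimate is <= alpha."""
    if len(psms) == 0:
        raise ValueError("empty PSM list")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    scores = np.array([s for s, _ in psms])
    labels = np.array([lab for _, lab in psms])
    order = np.argsort(scores)[::-1]  # descending: cumulative counts above tau
    s_sorted = scores[order]
    cum = {lab: np.cumsum(labels[order] == lab) for lab in TDA_LABELS}
    uniq, last_ix = np.unique(s_sorted[::-1], return_index=True)
    last_ix = s_sorted.size - 1 - last_ix  # last descending position per distinct score
    tt = cum["TT"][last_ix]
    est = np.where(tt >= 1, (cum["TD"][last_ix] - cum["DD"][last_ix]) / np.maximum(tt, 1), np.inf)
    # uniq is ascending; est[i] is the estimate at tau = uniq[i]
    suffix = np.maximum.accumulate(est[::-1])[::-1]
    ok = suffix <= alpha
    if not ok.any():
        return math.inf
    return float(uniq[np.argmax(ok)])


def fdr_curve(model, ds, grid_size: int = 200) -> FDRCurve:
    """Estimated FDR and identification counts over the observed score range."""
    lo, hi = float(ds.s1.min()), float(ds.s1.max())
    grid = np.linspace(lo, hi, grid_size)
    vals = np.asarray(mixture_fdr(model, grid))
    s_sorted = np.sort(ds.s1)
    n_ident = ds.n - np.searchsorted(s_sorted, grid, side="left")
    return FDRCurve(thresholds=grid, fdr=vals, n_identified=n_ident)
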