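"""Bootstrap variability of the estimated FDR threshold.

Resampling is done at the spectrum level: each replicate draws paired
(s1, s2) rows with replacement (preserving missingness), recomputes the
missing-second-score fraction, refits the two-sample model and inverts the
threshold at the requested FDR level.  Replicate fits use a reduced restart
budget by default, and can be warm-started from the full-data fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ScoreDataset
from .em import FitError, fit
from .fdr import fdr_threshold

__all__ = ["BootstrapResult", "bootstrap_thresholds"]

_DEFAULT_FIT_CONFIG = {"n_restarts": 24, "tol": 1e-8, "max_iter": 1000}


@dataclass
class BootstrapResult:
    thresholds: np.ndarray
    alpha: float
    B: int
    n_failed: int

    @property
    def median(self) -> float:
        return float(np.median(self.thresholds))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.thresholds, [25.0, 75.0])
        return float(q3 - q1)

    def percentile_interval(self, coverage: float = 0.95) -> tuple[float, float]:
        lo = 50.0 * (1.0 - coverage)
        a, b = np.percentile(self.thresholds, [lo, 100.0 - lo])
        return float(a), float(b)


def bootstrap_thresholds(
    ds: ScoreDataset,
    B: int = 50,
    alpha: float = 0.01,
    fit_config: dict | None = None,
    seed: int = 0,
    *,
    resample: bool = True,
) -> BootstrapResult:
    """Estimate the sampling spread of the FDR threshold by bootstrap.

    ``resample=False`` is a test hook: every replicate is the identity
    resample and must reproduce the full-data threshold.  Failed replicate
    fits are counted and excluded from the summary.
    """
    if ds.n == 0:
        raise ValueError("empty dataset")
    cfg = dict(_DEFAULT_FIT_CONFIG)
    if fit_config:
        cfg.update(fit_config)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    thresholds = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        if resample:
            idx = rng.integers(ds.n, size=ds.n)
        else:
            idx = np.arange(ds.n)
        dsb = ScoreDataset(s1=ds.s1[idx], s2=ds.s2[idx])
        fit_seed = int(rng.integers(2**31 - 1))
        try:
            state = fit(dsb, seed=fit_seed, **cfg)
        except FitError:
            n_failed += 1
            continue
        thresholds.append(fdr_threshold(state.model, alpha))
    return BootstrapResult(
        thresholds=np.asarray(thresholds), alpha=alpha, B=B, n_failed=n_failed
    )
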