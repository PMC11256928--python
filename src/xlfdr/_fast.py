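"""Compiled scalar kernels for the constraint hot path.

The ECM fit evaluates density-dominance feasibility thousands of times per
iteration (every parameter candidate, every bisection midpoint).  These
kernels implement exactly the same checks as :mod:`xlfdr.constraints` on
raw floats with early exit, compiled with numba.  A pure-Python fallback
with identical semantics is used if numba is unavailable.
"""

from __future__ import annotations

import math

_LOG_SQRT_2PI = 0.9189385332046727
_INV_SQRT2 = 0.7071067811865476


def _log_ndtr_s(t: float) -> float:
    # log Phi(t); asymptotic Mills-series branch for the far left tail
    if t > -25.0:
        return math.log(0.5 * math.erfc(-t * _INV_SQRT2))
    ti = 1.0 / (t * t)
    return (
        -0.5 * t * t
        - math.log(-t)
        - _LOG_SQRT_2PI
        + math.log1p(-ti * (1.0 - 3.0 * ti * (1.0 - 5.0 * ti)))
    )


def _mills_s(a: float) -> float:
    # phi(a) / Phi(a)
    return math.exp(-0.5 * a * a - _LOG_SQRT_2PI - _log_ndtr_s(a))


def _std_mode_s(lam: float) -> float:
    # mode of SN(0, 1, lam): unique root of g(z) = -z + lam*mills(lam*z);
    # g is strictly decreasing, so safeguarded Newton converges
    if lam == 0.0:
        return 0.0
    sgn = 1.0
    if lam < 0.0:
        sgn, lam = -1.0, -lam
    z = lam / math.sqrt(1.0 + lam * lam) * 0.7978845608028654  # SN mean start
    for _ in range(200):
        a = lam * z
        r = _mills_s(a)
        g = -z + lam * r
        gp = -1.0 - lam * lam * r * (a + r)
        z_new = z - g / gp
        if z_new <= 0.0:
            z_new = 0.5 * z
        if abs(z_new - z) < 1e-13:
            return sgn * z_new
        z = z_new
    return sgn * z


def _dominates_s(
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
    smax = fsg if fsg >= gsg else gsg
    mf = fmu + fsg * _std_mode_s(fla)
    mg = gmu + gsg * _std_mode_s(gla)
    if not mf > mg + tol * smax:
        return False
    span = window * smax
    h = span / (n_grid - 1)
    lr = math.log(gsg / fsg)
    for i in range(1, n_grid):  # right of mode(f): f must stay above g
        x = mf + h * i
        zf = (x - fmu) / fsg
        zg = (x - gmu) / gsg
        d = 0.5 * (zg * zg - zf * zf) + _log_ndtr_s(fla * zf) - _log_ndtr_s(gla * zg) + lr
        if d <= -tol:
            return False
    for i in range(1, n_grid):  # left of mode(g): g must stay above f
        x = mg - h * i
        zf = (x - fmu) / fsg
        zg = (x - gmu) / gsg
        d = 0.5 * (zg * zg - zf * zf) + _log_ndtr_s(fla * zf) - _log_ndtr_s(gla * zg) + lr
        if d >= tol:
            return False
    return True


try:  # pragma: no cover - exercised implicitly everywhere
    import numba as _nb

    _log_ndtr_s = _nb.njit(cache=True)(_log_ndtr_s)
    _mills_s = _nb.njit(cache=True)(_mills_s)
    _std_mode_s = _nb.njit(cache=True)(_std_mode_s)
    _dominates_s = _nb.njit(cache=True)(_dominates_s)
except ImportError:  # pragma: no cover
    pass

log_ndtr_scalar = _log_ndtr_s
std_mode_scalar = _std_mode_s
dominates_scalar = _dominates_s
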