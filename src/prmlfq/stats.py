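"""Statistical primitives: unpaired t-test and two-stage adaptive FDR.

The multiple-testing procedure is the Benjamini–Krieger–Yekutieli two-stage
linear step-up: a first-stage Benjamini–Hochberg pass at the deflated level
q' = q/(1+q) estimates the number of true null hypotheses, and a second
step-up pass at level q'·m/m0_hat does the actual rejection. The procedure
has no closed-form adjusted p-value, so per-hypothesis q-values are defined
by threshold inversion — the smallest nominal FDR level at which the
hypothesis would be rejected — found by bisection.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = ["TTestResult", "unpaired_t_test", "t_test_matrix", "bky_adjust", "BkyResult"]


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float
    degenerate: bool  # zero pooled variance with unequal means


def unpaired_t_test(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample two-tailed t-test (Student pooled-variance by default).

    Degenerate inputs follow a fixed contract: zero pooled variance with
    equal means gives (t=0, p=1); zero pooled variance with unequal means
    gives p=0 with the ``degenerate`` flag set (the statistic is signed
    infinity), so a noise-free spike-in is still called significant rather
    than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    t, df, p, degen = _t_core(
        x.mean(), y.mean(), x.var(ddof=1), y.var(ddof=1), x.size, y.size, equal_var
    )
    return TTestResult(float(t), float(df), float(p), bool(degen))


def _t_core(mx, my, vx, vy, nx, ny, equal_var):
    """Scalar or vectorized t-test core on summary statistics."""
    mx, my, vx, vy = (np.asarray(a, dtype=float) for a in (mx, my, vx, vy))
    diff = mx - my
    if equal_var:
        df = np.full_like(diff, nx + ny - 2.0)
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = pooled * (1.0 / nx + 1.0 / ny)
    else:
        se2 = vx / nx + vy / ny
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        df = np.where(se2 > 0, df, nx + ny - 2.0)

    zero_var = se2 == 0
    degen = zero_var & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(zero_var & (diff == 0), 0.0, t)
    t = np.where(degen, np.copysign(np.inf, diff), t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(zero_var & (diff == 0), 1.0, p)
    p = np.where(degen, 0.0, p)
    return t, df, p, degen


def t_test_matrix(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Row-wise unpaired t-tests for two feature x sample blocks.

    Returns arrays (t, df, p, degenerate), one entry per row.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    return _t_core(
        a.mean(axis=1),
        b.mean(axis=1),
        a.var(axis=1, ddof=1),
        b.var(axis=1, ddof=1),
        a.shape[1],
        b.shape[1],
        equal_var,
    )


class BkyResult(NamedTuple):
    q_values: np.ndarray
    rejected: np.ndarray
    m0_hat: int


def _step_up_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the BH linear step-up at ``level``."""
    m = p_sorted.size
    crit = level * np.arange(1, m + 1) / m
    hits = np.nonzero(p_sorted <= crit)[0]
    return int(hits[-1] + 1) if hits.size else 0


def _two_stage_count(p_sorted: np.ndarray, fdr_level: float) -> tuple[int, int]:
    """Rejection count and m0_hat of the two-stage step-up procedure."""
    m = p_sorted.size
    q_prime = fdr_level / (1.0 + fdr_level)
    r1 = _step_up_count(p_sorted, q_prime)
    if r1 == 0:
        return 0, m
    if r1 == m:
        return m, 0
    m0_hat = m - r1
    r2 = _step_up_count(p_sorted, q_prime * m / m0_hat)
    return r2, m0_hat


def bky_adjust(p_values, fdr_level: float = 0.01, tol: float = 1e-6) -> BkyResult:
    """Two-stage adaptive linear step-up FDR adjustment.

    Parameters
    ----------
    p_values : array-like of floats in [0, 1]
    fdr_level : float in (0, 1)
        Nominal FDR at which the ``rejected`` mask is computed.
    tol : float
        Bisection tolerance for the q-value inversion.

    Returns
    -------
    BkyResult
        ``q_values`` (same order as input; smallest nominal level at which
        each hypothesis is rejected, 1.0 if never), ``rejected`` boolean
        mask from running the procedure directly at ``fdr_level``, and
        ``m0_hat``, the stage-one estimate of the number of true nulls at
        ``fdr_level``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < fdr_level < 1):
        raise ValueError("fdr_level must lie in (0, 1)")

    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]

    # rejections at the nominal level
    r, m0_hat = _two_stage_count(p_sorted, fdr_level)
    rejected_sorted = np.zeros(m, dtype=bool)
    rejected_sorted[:r] = True

    # q-values by threshold inversion: the rejection count is monotone
    # non-decreasing in the nominal level, so q for sorted rank i is the
    # infimum level alpha with count(alpha) >= i+1; bisection with a
    # shrinking upper bracket (q-values are non-decreasing along sorted p).
    q_sorted = np.ones(m)
    hi_bracket = 1.0
    upper = 1.0 - 1e-12
    for i in range(m - 1, -1, -1):
        target = i + 1
        if _two_stage_count(p_sorted, min(hi_bracket, upper))[0] < target:
            q_sorted[i] = 1.0
            continue
        lo, hi = 0.0, min(hi_bracket, upper)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _two_stage_count(p_sorted, mid)[0] >= target:
                hi = mid
            else:
                lo = mid
        q_sorted[i] = hi
        hi_bracket = hi

    q = np.empty(m)
    q[order] = q_sorted
    rejected = np.zeros(m, dtype=bool)
    rejected[order] = rejected_sorted
    return BkyResult(q, rejected, int(m0_hat))
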