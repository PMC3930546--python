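"""Covariate-adjusted partial Pearson correlation association scans.

The core statistic is the partial Pearson correlation: the Pearson
correlation of the residuals of predictor and response after least-squares
projection onto the adjustment design (intercept included). Significance
comes from the Wald statistic

    t = r * sqrt((n - 2 - k) / (1 - r^2)),   df = n - 2 - k,

with k the number of non-intercept adjustment columns and n the per-test
complete-case sample count. Genotypes enter as additive 0/1/2 allele
counts (imputed dosages in [0, 2] are accepted on the same footing).
False-discovery q-values follow the Storey approach with the smoother
estimate of pi0 over lambda in {0.05, ..., 0.95}.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .covariates import DesignMatrix
from .exceptions import CollinearityError, InsufficientDataError

__all__ = ["partial_pearson", "wald_pvalue", "storey_qvalues", "association_scan"]

logger = logging.getLogger(__name__)

_REL_TOL = 1e-10
_MIN_P = np.nextafter(0.0, 1.0)


def _as_design_array(design, n: int) -> tuple[np.ndarray, int]:
    """Return (matrix including intercept, k)."""
    if design is None:
        return np.ones((n, 1)), 0
    if isinstance(design, DesignMatrix):
        return design.matrix, design.k
    Z = np.atleast_2d(np.asarray(design, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    if not np.allclose(Z[:, 0], 1.0):
        Z = np.hstack([np.ones((Z.shape[0], 1)), Z])
    return Z, Z.shape[1] - 1


def partial_pearson(x, y, design=None) -> tuple[float, int]:
    """Partial Pearson correlation of x and y given the adjustment design.

    Complete-case: rows where x, y and every design column are finite.
    Raises CollinearityError when either variable is numerically collinear
    with the design (zero residual), and InsufficientDataError when
    n <= k + 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A, k = _as_design_array(design, x.shape[0])
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(A), axis=1)
    n = int(ok.sum())
    if n <= k + 2:
        raise InsufficientDataError(f"n={n} too small for k={k} covariates")
    Ao, xo, yo = A[ok], x[ok], y[ok]
    Q, _ = np.linalg.qr(Ao)
    rx = xo - Q @ (Q.T @ xo)
    ry = yo - Q @ (Q.T @ yo)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx <= _REL_TOL * max(np.linalg.norm(xo), 1.0):
        raise CollinearityError("predictor is collinear with the adjustment design")
    if ny <= _REL_TOL * max(np.linalg.norm(yo), 1.0):
        raise CollinearityError("response is collinear with the adjustment design")
    r = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))
    return r, n


def wald_pvalue(r: float, n: int, k: int) -> tuple[float, float]:
    """Wald t statistic and two-sided P for a partial correlation."""
    df = n - 2 - k
    if df < 1:
        raise InsufficientDataError(f"df = n - 2 - k = {df} < 1")
    if abs(r) >= 1.0:
        logger.warning("|r| = 1: P clamped to the smallest representable value")
        return float(np.sign(r) * np.inf), _MIN_P
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(max(p, _MIN_P))


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the lambda grid, a
    natural cubic spline through these points evaluated at the largest
    lambda, clipped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = CubicSpline(lambdas, pi0_l, bc_type="natural")
    pi0 = float(spline(lambdas[-1]))
    return min(1.0, max(pi0, 1.0 / m))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; order-invariant and monotone non-decreasing in p.

    With fewer than 100 tests the smoother is unreliable, so pi0 falls
    back to 1 (the conservative Benjamini-Hochberg limit) and the fallback
    is logged. ``pi0`` may be forced explicitly (pi0=1 reduces the output
    exactly to BH-adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        if m < 100:
            logger.info("m=%d < 100: pi0 fixed at 1 (conservative)", m)
            pi0 = 1.0
        else:
            pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def association_scan(
    predictors,
    response,
    design=None,
    predictor_ids=None,
    response_id: str = "phenotype",
    compute_q: bool = True,
    sort_by_p: bool = False,
) -> pd.DataFrame:
    """One partial-correlation Wald test per predictor column.

    ``predictors`` is a sample x predictor array or DataFrame (genotype
    dosages or expression values, NaN = missing); ``response`` a per-sample
    vector. Predictors that fail (collinear, too few complete cases) are
    logged and skipped, never aborting the scan. q-values are computed
    once across the whole scan.
    """
    if isinstance(predictors, pd.DataFrame):
        if predictor_ids is None:
            predictor_ids = predictors.columns.to_numpy()
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if predictor_ids is None:
            predictor_ids = np.array([f"x{j}" for j in range(X.shape[1])])
    predictor_ids = np.asarray(predictor_ids)
    y = np.asarray(response, dtype=float)
    A, k = _as_design_array(design, y.shape[0])

    cols = {"predictor_id": [], "response_id": [], "n": [], "k": [], "r": [], "t": [], "p": []}

    rows_ok = np.isfinite(y) & np.all(np.isfinite(A), axis=1)
    Ao, yo = A[rows_ok], y[rows_ok]
    n0 = int(rows_ok.sum())
    batch_ready = n0 > k + 2
    if batch_ready:
        Q, _ = np.linalg.qr(Ao)
        ry = yo - Q @ (Q.T @ yo)
        ny = np.linalg.norm(ry)
        if ny <= _REL_TOL * max(np.linalg.norm(yo), 1.0):
            logger.warning("response is collinear with the design; scan is empty")
            batch_ready = False

    complete_cols = batch_ready and ~np.isnan(X[rows_ok]).any(axis=0)
    for j in range(X.shape[1]):
        pid = predictor_ids[j]
        try:
            if batch_ready and complete_cols is not False and complete_cols[j]:
                xo = X[rows_ok, j]
                rx = xo - Q @ (Q.T @ xo)
                nx = np.linalg.norm(rx)
                if nx <= _REL_TOL * max(np.linalg.norm(xo), 1.0):
                    raise CollinearityError(f"{pid} collinear with design")
                r, n = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0)), n0
            else:
                r, n = partial_pearson(X[:, j], y, design)
            t, p = wald_pvalue(r, n, k)
        except (CollinearityError, InsufficientDataError) as exc:
            logger.info("skipping %s: %s", pid, exc)
            continue
        cols["predictor_id"].append(pid)
        cols["response_id"].append(response_id)
        cols["n"].append(n)
        cols["k"].append(k)
        cols["r"].append(r)
        cols["t"].append(t)
        cols["p"].append(p)

    out = pd.DataFrame(cols)
    if compute_q and len(out):
        out["q"] = storey_qvalues(out["p"].to_numpy())
    elif compute_q:
        out["q"] = pd.Series(dtype=float)
    if sort_by_p and len(out):
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
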