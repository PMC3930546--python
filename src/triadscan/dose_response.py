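"""Logistic dose-response fitting, IC50 extraction, phenotype transforms.

The response model is the log-logistic curve

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with hill slope ``b``, lower asymptote ``c`` (fixed at 0 in the
3-parameter variant), upper asymptote ``d`` and midpoint concentration
``e``. IC50 is reported as the relative ED50, i.e. the ``e`` parameter:
the dose at which the response is halfway between the asymptotes.

Phenotype transforms: elementwise log10, or the van der Waerden
rank-to-normal-quantile transform Phi^-1(rank / (n + 1)) with average
ranks for ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError, InsufficientDataError, UnavailableValueError

__all__ = [
    "DoseResponseCurve",
    "LogisticFit",
    "fit_logistic",
    "estimate_ic50",
    "transform_phenotype",
    "fit_all_curves",
]

_FLAT_TOL = 1e-8


@dataclass
class DoseResponseCurve:
    sample_id: str
    drug: str
    doses: np.ndarray
    viabilities: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viabilities = np.asarray(self.viabilities, dtype=float)
        if self.doses.shape != self.viabilities.shape or self.doses.ndim != 1:
            raise ValueError("doses and viabilities must be matching 1-D arrays")
        if (self.doses <= 0).any():
            raise DomainError("doses must be strictly positive")

    @property
    def n_distinct_doses(self) -> int:
        return len(np.unique(self.doses))


@dataclass
class LogisticFit:
    model: str  # "3PL" or "4PL"
    b: float
    c: float
    d: float
    e: float
    rss: float
    converged: bool
    n_obs: int = 0

    @property
    def n_params(self) -> int:
        return 3 if self.model == "3PL" else 4

    def aic(self) -> float:
        n = max(self.n_obs, 1)
        rss = max(self.rss, 1e-300)
        return n * np.log(rss / n) + 2 * self.n_params

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        z = np.clip(self.b * (np.log(dose) - np.log(self.e)), -700.0, 700.0)
        return self.c + (self.d - self.c) / (1.0 + np.exp(z))


def _residuals(params, log_x, v, fix_c):
    if fix_c:
        b, d, log_e = params
        c = 0.0
    else:
        b, c, d, log_e = params
    z = np.clip(b * (log_x - log_e), -700.0, 700.0)
    return c + (d - c) / (1.0 + np.exp(z)) - v


def _fit_one_model(curve: DoseResponseCurve, model: str) -> LogisticFit:
    fix_c = model == "3PL"
    n_params = 3 if fix_c else 4
    if curve.n_distinct_doses < n_params:
        raise InsufficientDataError(
            f"{model} needs >= {n_params} distinct doses, got {curve.n_distinct_doses}"
        )
    log_x = np.log(curve.doses)
    v = curve.viabilities
    d0 = float(v.max())
    c0 = float(max(v.min(), 0.0))
    log_e_grid = np.quantile(log_x, [0.1, 0.3, 0.5, 0.7, 0.9])

    # rank the multistart grid by cheap residual evaluation, optimize from
    # the few most promising starts (the surface is multimodal but shallow)
    starts = []
    for b0, log_e0 in itertools.product((-2.0, -1.0, -0.5, 0.5, 1.0, 2.0), log_e_grid):
        x0 = [b0, d0, log_e0] if fix_c else [b0, c0, d0, log_e0]
        starts.append((float(np.sum(_residuals(x0, log_x, v, fix_c) ** 2)), x0))
    starts.sort(key=lambda t: t[0])

    best = None
    for _, x0 in starts[:4]:
        try:
            sol = optimize.least_squares(
                _residuals, x0, args=(log_x, v, fix_c), method="lm", max_nfev=2000
            )
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return LogisticFit(model, np.nan, np.nan, np.nan, np.nan, np.inf, False, v.size)
    if fix_c:
        b, d, log_e = best.x
        c = 0.0
    else:
        b, c, d, log_e = best.x
    rss = float(2.0 * best.cost)
    converged = bool(best.success) and np.isfinite(log_e)
    # unidentifiable midpoint: essentially flat response
    if np.std(v) < _FLAT_TOL or abs(d - c) < 1e-6 * max(1.0, abs(d)):
        converged = False
    return LogisticFit(model, float(b), float(c), float(d), float(np.exp(log_e)), rss, converged, v.size)


def fit_logistic(curve: DoseResponseCurve, model: str = "auto") -> LogisticFit:
    """Least-squares logistic fit with a multi-start optimizer.

    ``model`` is "3PL", "4PL" or "auto". Auto fits both and selects by
    AIC, falling back to the 3PL when the 4PL lower-asymptote estimate is
    negative or the 4PL fails to converge. Starts cover hill slopes
    {+-0.5, +-1, +-2} and midpoints across the observed dose range, since
    logistic least-squares surfaces are multimodal.
    """
    if model in ("3PL", "4PL"):
        return _fit_one_model(curve, model)
    if model != "auto":
        raise ValueError(f"unknown model {model!r}")
    fit3 = _fit_one_model(curve, "3PL")
    if curve.n_distinct_doses < 4:
        return fit3
    fit4 = _fit_one_model(curve, "4PL")
    if not fit4.converged or fit4.c < 0:
        return fit3
    if not fit3.converged:
        return fit4
    return fit4 if fit4.aic() < fit3.aic() else fit3


def estimate_ic50(fit: LogisticFit, kind: str = "relative", control: float = 1.0) -> float:
    """IC50 from a converged fit.

    ``kind="relative"`` (default) returns the midpoint parameter ``e``,
    the dose at which the response is halfway between the asymptotes.
    ``kind="absolute"`` returns the dose at which the fitted curve crosses
    ``control / 2`` in absolute viability units, when that crossing exists.
    """
    if not fit.converged:
        raise UnavailableValueError("fit did not converge; IC50 unavailable")
    if kind == "relative":
        return float(fit.e)
    if kind != "absolute":
        raise ValueError(f"unknown kind {kind!r}")
    target = control / 2.0
    lo, hi = min(fit.c, fit.d), max(fit.c, fit.d)
    if not (lo < target < hi):
        raise UnavailableValueError("fitted curve never crosses half of control")
    ratio = (fit.d - fit.c) / (target - fit.c) - 1.0
    return float(fit.e * np.exp(np.log(ratio) / fit.b))


def transform_phenotype(ic50s, method: str) -> pd.Series:
    """Drug-specific IC50 transform: "log10" or "vdw" (van der Waerden).

    vdW maps the rank r_i among the n non-missing values (average ranks
    for ties) to the standard-normal quantile at r_i / (n + 1); the output
    is invariant under any strictly monotone transform of the input.
    Missing values propagate as missing.
    """
    s = pd.Series(np.asarray(ic50s, dtype=float)) if not isinstance(ic50s, pd.Series) else ic50s.astype(float)
    ok = s.notna()
    if method == "log10":
        if (s[ok] <= 0).any():
            raise DomainError("log10 transform requires positive IC50 values")
        out = s.copy()
        out[ok] = np.log10(s[ok])
        return out
    if method == "vdw":
        n = int(ok.sum())
        if n < 2:
            raise InsufficientDataError("van der Waerden transform needs >= 2 values")
        ranks = stats.rankdata(s[ok].to_numpy(), method="average")
        out = s.copy()
        out[ok] = stats.norm.ppf(ranks / (n + 1))
        return out
    raise ValueError(f"unknown transform {method!r}")


def fit_all_curves(curves: pd.DataFrame, model: str = "auto") -> pd.DataFrame:
    """Fit every (sample, drug) curve in a long-format viability table.

    ``curves`` needs columns sample_id, drug, dose, viability. Returns one
    row per curve with the fitted parameters, the IC50 and a convergence
    flag (non-converged rows carry NaN IC50 and are excluded downstream).
    """
    rows = []
    for (sample_id, drug), grp in curves.groupby(["sample_id", "drug"], sort=True):
        curve = DoseResponseCurve(sample_id, drug, grp["dose"].to_numpy(), grp["viability"].to_numpy())
        try:
            fit = fit_logistic(curve, model=model)
        except InsufficientDataError:
            fit = LogisticFit(model if model != "auto" else "3PL", np.nan, np.nan, np.nan, np.nan, np.inf, False, len(grp))
        ic50 = float(fit.e) if fit.converged else np.nan
        rows.append(
            {
                "sample_id": sample_id,
                "drug": drug,
                "model": fit.model,
                "b": fit.b,
                "c": fit.c,
                "d": fit.d,
                "e": fit.e,
                "rss": fit.rss,
                "ic50": ic50,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
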