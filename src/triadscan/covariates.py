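"""Population-stratification eigenvectors and the adjustment design.

Eigenvectors follow the standardized-genotype convention: each SNP column
is centered by twice its sample allele frequency and scaled by
sqrt(2 f (1 - f)); missing calls are mean-imputed before the
decomposition. The default adjustment set for SNP-involving tests is
race (reference-coded dummies), sex, and five eigenvectors (k = 8 for a
three-population, two-sex cohort); tests not involving SNPs adjust for
race and sex only (k = 3). Aliased (collinear) columns are dropped with a
warning and k adjusted, so race dummies and eigenvectors may coexist even
though they are correlated in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = ["DesignMatrix", "compute_eigenvectors", "build_design"]


@dataclass
class DesignMatrix:
    """Columns: intercept first, then k non-intercept adjustment columns."""

    matrix: np.ndarray
    columns: list
    sample_ids: np.ndarray

    @property
    def k(self) -> int:
        return self.matrix.shape[1] - 1


def _standardize(calls: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        f = np.nanmean(calls, axis=0) / 2.0
    keep = np.isfinite(f) & (f > 0.0) & (f < 1.0)
    X = calls[:, keep].copy()
    f = f[keep]
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = (2.0 * f)[nan_idx[1]]
    X -= 2.0 * f
    X /= np.sqrt(2.0 * f * (1.0 - f))
    return X[:, X.std(axis=0) > 0]


def compute_eigenvectors(G: GenotypeMatrix | np.ndarray, n_components: int = 5) -> np.ndarray:
    """Principal-component loadings of the standardized genotype matrix.

    Returns an (n_samples, n_components) array of orthonormal per-sample
    loadings in decreasing-eigenvalue order. The sign of each component is
    fixed by making its largest-magnitude loading positive.
    """
    calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    if n_components == 0:
        return np.zeros((calls.shape[0], 0))
    if n_components > min(calls.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    X = _standardize(calls)
    if X.shape[1] == 0:
        raise np.linalg.LinAlgError("no polymorphic SNPs; decomposition undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size and np.count_nonzero(s > s[0] * 1e-12) < n_components:
        warnings.warn("requested more components than the numerical rank supports")
    load = U[:, :n_components]
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    return load


def build_design(
    covars: pd.DataFrame,
    eigenvectors: np.ndarray | None = None,
    include_eigenvectors: bool = True,
) -> DesignMatrix:
    """Assemble intercept + population dummies + sex + optional eigenvectors.

    ``covars`` needs columns sample_id, population, sex (non-missing).
    Population enters as reference-coded dummies (first label in sorted
    order is the reference); sex as an indicator for the second sorted
    level. Columns that are numerically collinear with earlier ones are
    dropped with a warning (e.g. a single-sex cohort loses its sex column).
    """
    if covars[["population", "sex"]].isna().any().any():
        raise ValueError("population and sex must be non-missing")
    n = len(covars)
    cols: list = ["intercept"]
    mats = [np.ones((n, 1))]

    pops = sorted(covars["population"].unique())
    for lab in pops[1:]:
        cols.append(f"pop_{lab}")
        mats.append((covars["population"] == lab).to_numpy(float)[:, None])

    sexes = sorted(covars["sex"].unique())
    if len(sexes) > 1:
        cols.append(f"sex_{sexes[1]}")
        mats.append((covars["sex"] == sexes[1]).to_numpy(float)[:, None])
    else:
        warnings.warn("single-sex cohort: sex column dropped from design")

    if include_eigenvectors and eigenvectors is not None and eigenvectors.size:
        ev = np.asarray(eigenvectors, dtype=float)
        if ev.shape[0] != n:
            raise ValueError("eigenvector rows do not match covariate rows")
        for j in range(ev.shape[1]):
            cols.append(f"EV{j + 1}")
            mats.append(ev[:, [j]])

    full = np.hstack(mats)
    # sequentially drop columns collinear with the ones already kept
    kept_idx = [0]
    for j in range(1, full.shape[1]):
        A = full[:, kept_idx]
        col = full[:, j]
        resid = col - A @ np.linalg.lstsq(A, col, rcond=None)[0]
        scale = np.linalg.norm(col) or 1.0
        if np.linalg.norm(resid) <= 1e-8 * scale:
            warnings.warn(f"design column {cols[j]!r} is aliased and was dropped")
        else:
            kept_idx.append(j)
    return DesignMatrix(
        matrix=full[:, kept_idx],
        columns=[cols[j] for j in kept_idx],
        sample_ids=covars["sample_id"].to_numpy(),
    )
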