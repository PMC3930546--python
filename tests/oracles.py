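"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the package
(full enumeration, exact rational arithmetic, explicit regression, dense
grid search) so agreement is evidence, not tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


def hwe_pvalue_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE P by full enumeration with rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_ref + n_het
    nb = 2 * n_hom_alt + n_het
    if na == 0 or nb == 0:
        return 1.0
    denom = comb(2 * n, na)
    probs = {}
    for h in range(min(na, nb) % 2, min(na, nb) + 1, 2):
        n_aa = (na - h) // 2
        probs[h] = Fraction(comb(n, n_aa) * comb(n - n_aa, h) * 2**h, denom)
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def partial_correlation_regression(x, y, Z) -> float:
    """Partial correlation via explicit least-squares residualization."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones(len(x)), np.asarray(Z, float)])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def loci_enumeration(df: pd.DataFrame, p_strong=1e-4, p_weak=1e-3, half_window=100_000):
    """Exhaustive candidate-seed enumeration of the locus rule.

    Every SNP below the strong threshold is examined as a seed in
    increasing-P order; the qualification predicate is applied literally;
    members join at most one locus. Returns [(seed, frozenset(members))].
    """
    recs = df.sort_values(["p", "chrom", "pos", "snp_id"], kind="stable").to_dict("records")
    assigned: set = set()
    out = []
    for rec in recs:
        if rec["p"] >= p_strong or rec["snp_id"] in assigned:
            continue
        members = [
            r
            for r in recs
            if r["snp_id"] not in assigned
            and str(r["chrom"]) == str(rec["chrom"])
            and abs(r["pos"] - rec["pos"]) <= half_window
            and r["p"] < p_weak
        ]
        n_strong = sum(1 for r in members if r["p"] < p_strong)
        if n_strong >= 2 or (n_strong >= 1 and len(members) >= 4):
            out.append((rec["snp_id"], frozenset(r["snp_id"] for r in members)))
            assigned.update(r["snp_id"] for r in members)
    return out


def logistic_grid_search_rss(doses, viabilities, fix_c: bool = True) -> float:
    """Dense grid search over (b, ln e) with the asymptotes solved exactly.

    For fixed slope and midpoint the model is linear in (c, d), so the
    inner problem is solved in closed form; the outer grid is dense enough
    that the returned RSS is a tight upper bound on the global minimum.
    """
    log_x = np.log(np.asarray(doses, float))
    v = np.asarray(viabilities, float)
    best = np.inf
    b_grid = np.concatenate([np.linspace(0.1, 4.0, 80), np.linspace(-4.0, -0.1, 80)])
    le_grid = np.linspace(log_x.min() - 1, log_x.max() + 1, 240)
    for b in b_grid:
        for le in le_grid:
            s = 1.0 / (1.0 + np.exp(np.clip(b * (log_x - le), -700, 700)))
            if fix_c:
                denom = s @ s
                if denom <= 0:
                    continue
                d = (s @ v) / denom
                rss = float(((v - d * s) ** 2).sum())
            else:
                A = np.column_stack([1.0 - s, s])
                coef, *_ = np.linalg.lstsq(A, v, rcond=None)
                rss = float(((v - A @ coef) ** 2).sum())
            if rss < best:
                best = rss
    return best
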