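"""Partial correlations, Wald P-values, Storey q-values, scan driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from triadscan.association import (
    association_scan,
    partial_pearson,
    storey_pi0,
    storey_qvalues,
    wald_pvalue,
)
from triadscan.covariates import build_design, compute_eigenvectors
from triadscan.exceptions import CollinearityError, InsufficientDataError

from oracles import partial_correlation_regression


def test_affine_response_with_intercept_only_gives_r_one():
    x = np.arange(10.0)
    r, n = partial_pearson(x, 2 * x + 1, None)
    assert r == pytest.approx(1.0)
    assert n == 10


def test_response_equal_to_covariate_is_collinear():
    rng = np.random.default_rng(0)
    z = rng.normal(size=30)
    with pytest.raises(CollinearityError):
        partial_pearson(rng.normal(size=30), z, z[:, None])


def test_matches_explicit_residualization_oracle_to_1e10():
    rng = np.random.default_rng(7)
    Z = rng.normal(size=(30, 3))
    x = rng.normal(size=30) + Z @ [0.5, -0.2, 0.1]
    y = rng.normal(size=30) + Z @ [0.1, 0.4, -0.3] + 0.3 * x
    r, n = partial_pearson(x, y, Z)
    assert n == 30
    assert r == pytest.approx(partial_correlation_regression(x, y, Z), abs=1e-10)


def test_empty_adjustment_set_equals_textbook_pearson():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=50), rng.normal(size=50)
    r, _ = partial_pearson(x, y, None)
    assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


def test_complete_case_count_reflects_missingness():
    rng = np.random.default_rng(9)
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    x[:5] = np.nan
    y[5:8] = np.nan
    _, n = partial_pearson(x, y, None)
    assert n == 32


def test_too_few_samples_raise():
    with pytest.raises(InsufficientDataError):
        partial_pearson(np.arange(4.0), np.arange(4.0), np.random.default_rng(0).normal(size=(4, 2)))


def test_wald_null_center_and_monotonicity():
    t, p = wald_pvalue(0.0, 100, 3)
    assert t == 0.0 and p == pytest.approx(1.0)
    ps = [wald_pvalue(r, 100, 3)[1] for r in np.linspace(0.0, 0.9, 15)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_wald_matches_independent_t_tail_formula():
    # incomplete-beta form of the t tail, independent of stats.t.sf
    r, n, k = 0.391, 174, 8
    t, p = wald_pvalue(r, n, k)
    df = n - 2 - k
    p_oracle = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    assert p == pytest.approx(p_oracle, rel=1e-3)


def test_wald_at_k0_reproduces_classical_correlation_test():
    rng = np.random.default_rng(11)
    x, y = rng.normal(size=60), rng.normal(size=60)
    res = stats.pearsonr(x, y)
    r, n = partial_pearson(x, y, None)
    _, p = wald_pvalue(r, n, 0)
    assert p == pytest.approx(res.pvalue, rel=1e-9)


def test_perfect_correlation_clamped_with_warning():
    t, p = wald_pvalue(1.0, 50, 0)
    assert np.isinf(t) and 0 < p < 1e-300


def test_qvalues_with_pi0_one_reduce_to_benjamini_hochberg():
    rng = np.random.default_rng(13)
    p = rng.uniform(size=500)
    q = storey_qvalues(p, pi0=1.0)
    bh = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, bh, atol=1e-12)


def test_qvalues_degenerate_and_small_m():
    np.testing.assert_allclose(storey_qvalues(np.ones(200)), np.ones(200))
    # m < 100 falls back to pi0 = 1
    p = np.linspace(0.01, 0.99, 50)
    np.testing.assert_allclose(storey_qvalues(p), multipletests(p, method="fdr_bh")[1])


def test_uniform_null_pi0_near_one_and_large_min_q():
    rng = np.random.default_rng(17)
    p = rng.uniform(size=10_000)
    pi0 = storey_pi0(p)
    assert 0.9 <= pi0 <= 1.1
    assert storey_qvalues(p).min() > 0.2


@given(st.integers(0, 2**31 - 1))
def test_qvalues_invariant_to_input_order(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.001, 1.0, size=200)
    perm = rng.permutation(200)
    q = storey_qvalues(p)
    q_perm = storey_qvalues(p[perm])
    np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(19)
    p = rng.uniform(0.0001, 1.0, size=300)
    q = storey_qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_scan_empty_predictor_set_is_vacuous():
    out = association_scan(np.empty((20, 0)), np.random.default_rng(0).normal(size=20))
    assert len(out) == 0


def test_scan_handles_missing_predictors_and_skips_constant_ones():
    rng = np.random.default_rng(23)
    y = rng.normal(size=50)
    X = pd.DataFrame(
        {
            "clean": rng.normal(size=50),
            "gappy": np.where(rng.random(50) < 0.2, np.nan, rng.normal(size=50)),
            "constant": np.ones(50),
        }
    )
    out = association_scan(X, y)
    assert set(out["predictor_id"]) == {"clean", "gappy"}
    gappy_n = out.set_index("predictor_id").loc["gappy", "n"]
    assert gappy_n == np.isfinite(X["gappy"]).sum()


def test_scan_batch_path_agrees_with_per_column_path():
    rng = np.random.default_rng(29)
    y = rng.normal(size=60)
    X = rng.normal(size=(60, 5))
    Z = rng.normal(size=(60, 2))
    out = association_scan(X, y, Z, compute_q=False)
    for j in range(5):
        r, n = partial_pearson(X[:, j], y, Z)
        row = out.iloc[j]
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["n"] == n


def test_stratified_null_calibrated_with_eigenvectors_inflated_without(small_cohort):
    # population-structured genotypes, population-shifted phenotype:
    # adjusting for structure keeps type-I error at alpha; ignoring all
    # structure inflates it
    cohort = small_cohort
    rng = np.random.default_rng(31)
    pop_idx = cohort.covariates["population"].map({"CA": 0, "AA": 1, "HCA": 2}).to_numpy()
    y = np.array([0.4, 0.0, -0.4])[pop_idx] + rng.normal(0, 0.3, cohort.genotypes.n_samples)
    ev = compute_eigenvectors(cohort.genotypes, 5)
    design = build_design(cohort.covariates, ev, include_eigenvectors=True)
    X = pd.DataFrame(cohort.genotypes.calls, columns=cohort.genotypes.snp_ids)
    adj = association_scan(X, y, design, compute_q=False)
    raw = association_scan(X, y, None, compute_q=False)
    assert (adj["p"] < 0.05).mean() < 0.12
    assert (raw["p"] < 0.05).mean() > 2 * (adj["p"] < 0.05).mean()
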