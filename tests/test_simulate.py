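"""Generator behaviour: determinism, frequency model, planted structure."""

import numpy as np
import pandas as pd
import pytest

import triadscan as ts
from triadscan.exceptions import ConfigurationError
from triadscan.simulate import logistic_viability, simulate_genotypes


def test_same_seed_gives_identical_cohort():
    a = ts.simulate_cohort(ts.SimulationConfig(n_snps=60, n_probesets=8, seed=1))
    b = ts.simulate_cohort(ts.SimulationConfig(n_snps=60, n_probesets=8, seed=1))
    np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
    pd.testing.assert_frame_equal(a.expression, b.expression)
    pd.testing.assert_frame_equal(a.truth.true_log_ic50, b.truth.true_log_ic50)
    pd.testing.assert_frame_equal(a.dose_response, b.dose_response)
    assert a.truth.eqtl_map == b.truth.eqtl_map


def test_different_seeds_differ_but_shapes_match():
    a = ts.simulate_cohort(ts.SimulationConfig(n_snps=60, n_probesets=8, seed=1))
    b = ts.simulate_cohort(ts.SimulationConfig(n_snps=60, n_probesets=8, seed=2))
    assert a.genotypes.calls.shape == b.genotypes.calls.shape
    assert not np.array_equal(a.genotypes.calls, b.genotypes.calls, equal_nan=True)


def test_default_cohort_is_174_samples_in_three_populations():
    cohort = ts.simulate_cohort(ts.SimulationConfig(n_snps=30, n_probesets=6, seed=0))
    counts = cohort.covariates["population"].value_counts()
    assert cohort.genotypes.n_samples == 174
    assert counts["CA"] == 60 and counts["AA"] == 54 and counts["HCA"] == 60


def test_zero_snps_rejected():
    with pytest.raises(ConfigurationError):
        ts.simulate_cohort(ts.SimulationConfig(n_snps=0))


def test_sample_allele_frequency_tracks_ancestral_at_vanishing_fst():
    # one population, fst -> 0: sample frequency ~ Binomial(2n, p_anc)
    cfg = ts.SimulationConfig(
        n_per_population=(5000,), population_labels=("X",),
        n_snps=40, fst=1e-13, ld_copy_prob=0.0, ld_block_size=1,
        missing_rate=0.0, seed=3,
    )
    G, info = simulate_genotypes(cfg)
    f_hat = G.calls.mean(axis=0) / 2.0
    p = info["freq_anc"].to_numpy()
    se = np.sqrt(p * (1 - p) / (2 * 5000))
    assert (np.abs(f_hat - p) < 4.5 * se).all()


def test_zero_missing_rate_gives_complete_matrix():
    cfg = ts.SimulationConfig(n_snps=50, missing_rate=0.0, seed=5)
    G, _ = simulate_genotypes(cfg)
    assert not np.isnan(G.calls).any()


def test_positions_strictly_increasing_within_chromosome():
    _, info = simulate_genotypes(ts.SimulationConfig(n_snps=200, seed=0))
    for _, grp in info.groupby("chrom"):
        assert (np.diff(grp["pos"].to_numpy()) > 0).all()


def test_cis_plants_share_chromosome_trans_plants_do_not():
    cohort = ts.simulate_cohort(
        ts.SimulationConfig(n_snps=200, n_probesets=20, n_cis_eqtl=2, n_trans_eqtl=2, seed=11)
    )
    for s, p, _, label in cohort.truth.eqtl_map:
        snp = cohort.snp_info.iloc[s]
        probe = cohort.probe_annotation.iloc[p]
        if label == "cis":
            assert snp["chrom"] == probe["chromosome"]
            assert probe["start"] <= snp["pos"] <= probe["end"]
        else:
            assert snp["chrom"] != probe["chromosome"]


def test_expression_noiseless_limit_is_exactly_linear_in_genotype():
    cfg = ts.SimulationConfig(
        n_snps=40, n_probesets=6, sigma_expr=0.0, pop_expr_sd=0.0,
        sex_expr_sd=0.0, missing_rate=0.0, beta_eqtl=1.5, seed=9,
    )
    cohort = ts.simulate_cohort(cfg)
    s, p, beta, _ = cohort.truth.eqtl_map[0]
    g = cohort.genotypes.calls[:, s]
    expr = cohort.expression.iloc[p].to_numpy()
    # expression = baseline + beta * g exactly
    resid = expr - beta * g
    assert np.allclose(resid, resid[0])


def test_expression_group_means_shift_by_beta_per_allele():
    cfg = ts.SimulationConfig(
        n_snps=60, n_probesets=6, beta_eqtl=2.0, sigma_expr=0.1,
        pop_expr_sd=0.0, sex_expr_sd=0.0, missing_rate=0.0, seed=13,
    )
    cohort = ts.simulate_cohort(cfg)
    s, p, _, _ = cohort.truth.eqtl_map[0]
    g = cohort.genotypes.calls[:, s]
    expr = cohort.expression.iloc[p].to_numpy()
    slope = np.polyfit(g, expr, 1)[0]
    assert abs(slope - 2.0) < 0.05


def test_expression_variance_matches_residual_sd_without_effects():
    cfg = ts.SimulationConfig(
        n_snps=30, n_probesets=120, beta_eqtl=0.0, sigma_expr=1.0,
        pop_expr_sd=0.0, sex_expr_sd=0.0, gamma_expr=0.0, seed=17,
    )
    cohort = ts.simulate_cohort(cfg)
    per_probe_var = cohort.expression.var(axis=1, ddof=1)
    assert abs(per_probe_var.mean() - 1.0) < 0.05


def test_viability_midpoint_and_asymptote_and_slope_reflection():
    v_mid = logistic_viability(1.0, 0.0, b=1.0, c=0.2, d=1.0)
    assert np.isclose(v_mid, 0.6)  # (c + d) / 2
    v_low_dose = logistic_viability(1e-12, 0.0, b=1.0, c=0.2, d=1.0)
    assert np.isclose(v_low_dose, 1.0, atol=1e-6)  # upper asymptote
    x = np.array([0.01, 0.1, 1.0, 10.0])
    up = logistic_viability(x, 0.0, b=1.0, c=0.0, d=1.0)
    down = logistic_viability(x, 0.0, b=-1.0, c=0.0, d=1.0)
    np.testing.assert_allclose(up + down, np.ones_like(x))  # reflection about midpoint


def test_viability_clipped_at_zero_not_one():
    cfg = ts.SimulationConfig(n_snps=20, n_probesets=4, viability_noise_sd=0.5, seed=23)
    cohort = ts.simulate_cohort(cfg)
    v = cohort.dose_response["viability"]
    assert (v >= 0).all()
    assert (v > 1).any()  # readouts may exceed control


def test_planted_snps_are_common_and_in_distinct_blocks():
    cfg = ts.SimulationConfig(n_snps=300, n_probesets=10, seed=29)
    cohort = ts.simulate_cohort(cfg)
    special = [s for s, _ in cohort.truth.pgx_snps] + [s for s, _, _, _ in cohort.truth.eqtl_map]
    mafs = [ts.compute_maf(cohort.genotypes.calls[:, s]) for s in special]
    assert all(m >= 0.2 for m in mafs)
    for i, a in enumerate(special):
        for b in special[i + 1 :]:
            assert abs(a - b) >= 2 * cfg.ld_block_size
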