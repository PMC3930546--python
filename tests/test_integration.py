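"""Triad joins, cis/trans classification, dosage filtering, concordance, LD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import triadscan as ts
from triadscan.datasets import pigb_triad_legs
from triadscan.exceptions import JoinError, UnavailableValueError
from triadscan.integration import (
    DosagePanel,
    classify_cis_trans,
    filter_dosage_panel,
    imputation_concordance,
    ld_r2,
    summarize_triads,
    triad_analysis,
    validate_triads,
)
from triadscan.simulate import simulate_genotypes


# --- cis/trans -----------------------------------------------------------

@pytest.mark.parametrize(
    "snp_chrom,snp_pos,gene_chrom,start,end,expect",
    [
        ("1", 500_000, "1", 490_000, 510_000, "cis"),        # inside the gene
        ("1", 500_000, "2", 490_000, 510_000, "trans"),      # different chromosome
        ("1", 290_000, "1", 490_000, 510_000, "cis"),        # exactly 200 kb upstream
        ("1", 289_999, "1", 490_000, 510_000, "trans"),      # 1 bp beyond the window
        ("1", 710_000, "1", 490_000, 510_000, "cis"),        # exactly 200 kb downstream
        ("1", 500_000, "1", np.nan, np.nan, "unclassifiable"),
    ],
)
def test_cis_trans_window_rule(snp_chrom, snp_pos, gene_chrom, start, end, expect):
    assert classify_cis_trans(snp_chrom, snp_pos, gene_chrom, start, end) == expect


# --- triad joins ---------------------------------------------------------

def test_pigb_legs_join_back_to_the_published_rows():
    snp_assoc, snp_expr, expr_pheno = pigb_triad_legs()
    triads = triad_analysis(
        snp_assoc, snp_expr, expr_pheno,
        thresholds={"snp_ic50": 1e-3, "snp_expr": 1e-4, "expr_pheno": 1.0},
        same_gene_only=True,
    )
    assert len(triads) == 11
    assert triads["snp_id"].nunique() == 7
    assert validate_triads(triads, {"expr_pheno": 1.0})


def test_default_expression_leg_threshold_prunes_weak_probesets():
    snp_assoc, snp_expr, expr_pheno = pigb_triad_legs()
    triads = triad_analysis(snp_assoc, snp_expr, expr_pheno, same_gene_only=True)
    # only the probeset whose expression-IC50 P clears 1e-4 survives
    assert set(triads["probeset_id"]) == {"242760_x_at"}


def test_empty_snp_table_gives_empty_triads():
    snp_assoc, snp_expr, expr_pheno = pigb_triad_legs()
    out = triad_analysis(snp_assoc.iloc[0:0], snp_expr, expr_pheno)
    assert out.empty


def test_disjoint_identifiers_raise_join_error():
    snp_assoc, snp_expr, expr_pheno = pigb_triad_legs()
    bad = snp_expr.assign(snp_id=snp_expr["snp_id"] + "_other")
    with pytest.raises(JoinError):
        triad_analysis(snp_assoc, bad, expr_pheno)


def test_triads_invariant_to_input_row_order():
    snp_assoc, snp_expr, expr_pheno = pigb_triad_legs()
    kw = dict(thresholds={"expr_pheno": 1.0}, same_gene_only=True)
    a = triad_analysis(snp_assoc, snp_expr, expr_pheno, **kw)
    b = triad_analysis(
        snp_assoc.sample(frac=1, random_state=0),
        snp_expr.sample(frac=1, random_state=1),
        expr_pheno.sample(frac=1, random_state=2),
        **kw,
    )
    pd.testing.assert_frame_equal(a, b)


def test_locus_restriction_limits_triad_membership():
    snp_assoc, snp_expr, expr_pheno = pigb_triad_legs()
    from triadscan.loci import Locus

    one = Locus(
        seed_snp="rs2290344", chromosome="15",
        window=(53_307_088, 53_507_088), seed_pos=53_407_088,
        seed_p=1.75e-5, seed_r=0.339,
        members=["rs2290344"], member_ps=[1.75e-5], n_p4=1,
    )
    out = triad_analysis(
        snp_assoc, snp_expr, expr_pheno,
        thresholds={"expr_pheno": 1.0}, loci=[one], same_gene_only=True,
    )
    assert set(out["snp_id"]) == {"rs2290344"}
    summary = summarize_triads(out, [one])
    assert summary["n_loci"] == 1 and summary["n_snps"] == 1


# --- dosage panel --------------------------------------------------------

def _panel():
    rng = np.random.default_rng(0)
    dos = pd.DataFrame(
        rng.uniform(0, 2, size=(50, 4)), columns=["a", "b", "c", "d"]
    )
    dos["d"] = 0.005  # MAF ~ 0.0025, below threshold
    quality = pd.Series([0.29, 0.30, 0.95, 0.95], index=["a", "b", "c", "d"])
    return DosagePanel(dos, quality)


def test_dosage_filter_boundaries_and_planted_removals():
    kept = filter_dosage_panel(_panel())
    # a removed (quality 0.29 < 0.3), b kept (exactly 0.3), d removed (MAF)
    assert list(kept.dosages.columns) == ["b", "c"]


def test_dosage_panel_validates_ranges():
    with pytest.raises(ValueError):
        DosagePanel(pd.DataFrame({"a": [2.5]}), pd.Series({"a": 0.9}))
    with pytest.raises(ValueError):
        DosagePanel(pd.DataFrame({"a": [1.0]}), pd.Series({"a": 1.2}))


# --- concordance ---------------------------------------------------------

def test_concordance_exact_values():
    assert imputation_concordance([0, 1, 2], [0, 1, 2]) == 0.0
    assert imputation_concordance([0.9, 1.2], [1, 1]) == pytest.approx(0.025)
    with pytest.raises(UnavailableValueError):
        imputation_concordance([np.nan], [1])


def test_concordance_matches_moment_oracle_for_independent_inputs():
    rng = np.random.default_rng(3)
    n = 10_000
    d = rng.uniform(0, 2, n)
    g = rng.binomial(2, 0.5, n).astype(float)
    # E[(d-g)^2] = E[d^2] - 2 E[d] E[g] + E[g^2] = 4/3 - 2 + 3/2 = 5/6
    assert imputation_concordance(d, g) == pytest.approx(5 / 6, abs=0.05)


@given(st.lists(st.tuples(st.floats(0, 2), st.sampled_from([0.0, 1.0, 2.0])),
                min_size=1, max_size=50))
def test_concordance_symmetric_under_joint_allele_flip(pairs):
    d = np.array([a for a, _ in pairs])
    g = np.array([b for _, b in pairs])
    assert imputation_concordance(d, g) == pytest.approx(
        imputation_concordance(2 - d, 2 - g), abs=1e-12
    )


def test_concordance_harmonize_picks_better_orientation():
    d = np.array([0.0, 0.1, 0.05])
    g = np.array([2.0, 2.0, 2.0])
    with pytest.warns(UserWarning):
        v = imputation_concordance(d, g, harmonize=True)
    assert v == pytest.approx(np.mean((2 - d - g) ** 2))


# --- LD ------------------------------------------------------------------

def test_ld_of_snp_with_itself_is_one():
    g = np.array([0, 1, 2, 1, 0, 2, 1])
    assert ld_r2(g, g) == pytest.approx(1.0)


def test_ld_of_independent_snps_near_zero():
    rng = np.random.default_rng(9)
    g1 = rng.binomial(2, 0.5, 10_000)
    g2 = rng.binomial(2, 0.5, 10_000)
    assert ld_r2(g1, g2) < 0.001


def test_ld_monomorphic_is_unavailable():
    with pytest.raises(UnavailableValueError):
        ld_r2([1, 1, 1], [0, 1, 2])


def test_block_copied_pairs_match_generator_expectation():
    # adjacent SNPs within a block have genotype correlation ~ copy prob
    copy_prob = 0.9
    cfg = ts.SimulationConfig(
        n_per_population=(1000,), population_labels=("X",),
        n_snps=400, n_chromosomes=4, ld_copy_prob=copy_prob, ld_block_size=10,
        missing_rate=0.0, fst=0.02, seed=4,
    )
    G, info = simulate_genotypes(cfg)
    vals = []
    for j in range(1, 400):
        if (j % 10) != 0:  # same block as predecessor
            try:
                vals.append(ld_r2(G.calls[:, j - 1], G.calls[:, j]))
            except UnavailableValueError:
                pass
    assert np.mean(vals) == pytest.approx(copy_prob**2, abs=0.02)
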