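"""SNP and sample quality control for genotype matrices.

Implements the standard array-era filter set: per-sample call rate,
per-SNP call rate, an exact Hardy-Weinberg equilibrium test, and minor
allele frequency, applied in a fixed order (samples first, then SNP call
rate -> HWE -> MAF) so that a low-quality sample cannot drag down per-SNP
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import UnavailableValueError

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "QCThresholds",
    "compute_maf",
    "hwe_exact_test",
    "hwe_exact_pvalues",
    "apply_qc",
]


@dataclass
class GenotypeMatrix:
    """Sample x SNP alternate-allele counts.

    ``calls`` is a float array with values in {0, 1, 2} and ``nan`` for
    missing calls. Rows are samples, columns are SNPs.
    """

    calls: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D sample x SNP array")
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.snp_ids)} SNPs"
            )
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing (nan)")
        if len(set(self.snp_ids.tolist())) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def sample_call_rates(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.calls).mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        km = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
        return GenotypeMatrix(self.calls[np.ix_(sm, km)], self.sample_ids[sm], self.snp_ids[km])


def compute_maf(calls) -> float:
    """Minor allele frequency of one SNP from 0/1/2 calls.

    Missing calls (nan) are excluded from numerator and denominator; the
    alternate-allele frequency is folded into [0, 0.5]. Invariant to
    ref/alt relabelling (g -> 2 - g).
    """
    calls = np.asarray(calls, dtype=float)
    ok = ~np.isnan(calls)
    n = int(ok.sum())
    if n == 0:
        raise UnavailableValueError("all calls missing; MAF undefined")
    f = float(calls[ok].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def _maf_per_snp(calls: np.ndarray) -> np.ndarray:
    """Vectorised folded allele frequency per column; nan for all-missing."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(calls, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def _hwe_het_distribution(n_total: int, n_minor_alleles: int):
    """Exact distribution of heterozygote counts given fixed allele counts.

    Returns (het_values, probabilities) for the hypergeometric-type null in
    which 2*n_total alleles with n_minor_alleles copies of the minor allele
    are paired at random into genotypes.
    """
    na = n_minor_alleles
    nb = 2 * n_total - na
    h = np.arange(na % 2, min(na, nb) + 1, 2)
    n_aa = (na - h) // 2
    n_bb = (nb - h) // 2
    logp = (
        gammaln(n_total + 1)
        - gammaln(n_aa + 1)
        - gammaln(h + 1)
        - gammaln(n_bb + 1)
        + gammaln(na + 1)
        + gammaln(nb + 1)
        - gammaln(2 * n_total + 1)
        + h * np.log(2.0)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return h, p


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test P-value for one SNP's genotype counts.

    P is the total probability, under the fixed-allele-count null, of all
    heterozygote counts no more probable than the observed one (two-sided
    "no more probable" convention). Monomorphic SNPs return 1.0.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_ref = 2 * counts[0] + counts[1]
    n_alt = 2 * counts[2] + counts[1]
    if n_ref == 0 or n_alt == 0:
        return 1.0
    h, probs = _hwe_het_distribution(n, min(n_ref, n_alt))
    p_obs = probs[h == counts[1]]
    if p_obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("observed heterozygote count infeasible for allele counts")
    p = float(probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def hwe_exact_pvalues(calls: np.ndarray) -> np.ndarray:
    """Exact HWE P per column of a sample x SNP call matrix.

    Caches the null heterozygote-count distribution per (n, minor-allele
    count) pair, which makes genome-scale panels cheap.
    """
    calls = np.asarray(calls, dtype=float)
    n_hom_ref = np.nansum(calls == 0, axis=0).astype(int)
    n_het = np.nansum(calls == 1, axis=0).astype(int)
    n_hom_alt = np.nansum(calls == 2, axis=0).astype(int)
    out = np.ones(calls.shape[1])
    cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for j in range(calls.shape[1]):
        n = n_hom_ref[j] + n_het[j] + n_hom_alt[j]
        if n == 0:
            out[j] = np.nan
            continue
        n_ref = 2 * n_hom_ref[j] + n_het[j]
        n_alt = 2 * n_hom_alt[j] + n_het[j]
        if n_ref == 0 or n_alt == 0:
            continue
        key = (n, min(n_ref, n_alt))
        if key not in cache:
            cache[key] = _hwe_het_distribution(*key)
        h, probs = cache[key]
        p_obs = probs[h == n_het[j]][0]
        out[j] = min(1.0, float(probs[probs <= p_obs * (1.0 + 1e-12)].sum()))
    return out


@dataclass
class QCThresholds:
    snp_call_rate: float = 0.95
    hwe_p: float = 0.001
    maf: float = 0.05
    sample_call_rate: float = 0.95


@dataclass
class QCReport:
    """Per-sample and per-SNP statistics, pass flags, and failure reasons."""

    samples: pd.DataFrame
    snps: pd.DataFrame
    thresholds: QCThresholds
    empty_result: bool = False
    counts: dict = field(default_factory=dict)


def apply_qc(
    G: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    snp_info: pd.DataFrame | None = None,
):
    """Filter a genotype matrix by the standard sample/SNP QC cascade.

    Order of operations: (1) drop samples with call rate below threshold;
    (2) on remaining samples recompute per-SNP statistics and drop SNPs
    failing, in order, call rate, then HWE, then MAF. A SNP's recorded
    failure reason is the first filter it fails.

    Returns ``(filtered_matrix, report)`` or, when ``snp_info`` is given,
    ``(filtered_matrix, filtered_snp_info, report)``.
    """
    thr = thresholds or QCThresholds()
    sample_cr = G.sample_call_rates()
    sample_pass = sample_cr >= thr.sample_call_rate
    samples_df = pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "call_rate": sample_cr,
            "pass": sample_pass,
            "reason": np.where(sample_pass, "", "sample_call_rate"),
        }
    )

    G1 = G.subset(sample_mask=sample_pass)
    snp_cr = G1.snp_call_rates()
    maf = _maf_per_snp(G1.calls) if G1.n_samples else np.full(G1.n_snps, np.nan)
    hwe = hwe_exact_pvalues(G1.calls) if G1.n_samples else np.full(G1.n_snps, np.nan)

    reason = np.full(G1.n_snps, "", dtype=object)
    fail_cr = snp_cr < thr.snp_call_rate
    fail_hwe = ~fail_cr & (np.nan_to_num(hwe, nan=1.0) < thr.hwe_p)
    fail_maf = ~fail_cr & ~fail_hwe & (np.isnan(maf) | (maf < thr.maf))
    reason[fail_cr] = "snp_call_rate"
    reason[fail_hwe] = "hwe"
    reason[fail_maf] = "maf"
    snp_pass = reason == ""

    snps_df = pd.DataFrame(
        {
            "snp_id": G1.snp_ids,
            "call_rate": snp_cr,
            "maf": maf,
            "hwe_p": hwe,
            "pass": snp_pass,
            "reason": reason,
        }
    )

    G2 = G1.subset(snp_mask=snp_pass)
    report = QCReport(
        samples=samples_df,
        snps=snps_df,
        thresholds=thr,
        empty_result=(G2.n_samples == 0 or G2.n_snps == 0),
        counts={
            "samples_in": G.n_samples,
            "samples_out": G2.n_samples,
            "samples_removed": int((~sample_pass).sum()),
            "snps_in": G.n_snps,
            "snps_out": G2.n_snps,
            "snps_removed_call_rate": int(fail_cr.sum()),
            "snps_removed_hwe": int(fail_hwe.sum()),
            "snps_removed_maf": int(fail_maf.sum()),
        },
    )
    if snp_info is not None:
        kept = set(G2.snp_ids.tolist())
        info2 = snp_info[snp_info["snp_id"].isin(kept)].reset_index(drop=True)
        return G2, info2, report
    return G2, report
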