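"""Three-way SNP -> expression -> IC50 integration and related utilities.

A triad is a (SNP, probeset) pair whose three pairwise associations all
pass their thresholds: SNP vs IC50 (default P < 1e-3, optionally
restricted to qualifying locus members), SNP vs expression (P < 1e-4) and
expression vs IC50 (P < 1e-4). Each triad is classified cis when SNP and
gene sit on the same chromosome within +/-200 kb of the gene interval
(inclusive, gene boundary not TSS), else trans.

Also here: imputed-dosage panel filtering (dosage R^2 >= 0.3, MAF >=
0.01), imputation concordance (mean squared difference between dosage and
genotype allele counts), and composite LD r^2 from unphased genotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import JoinError, UnavailableValueError
from .loci import Locus

__all__ = [
    "TRIAD_THRESHOLDS",
    "DosagePanel",
    "triad_analysis",
    "validate_triads",
    "summarize_triads",
    "classify_cis_trans",
    "filter_dosage_panel",
    "imputation_concordance",
    "ld_r2",
]

logger = logging.getLogger(__name__)

TRIAD_THRESHOLDS = {"snp_ic50": 1e-3, "snp_expr": 1e-4, "expr_pheno": 1e-4}


@dataclass
class DosagePanel:
    """Continuous alternate-allele dosages with per-SNP imputation quality."""

    dosages: pd.DataFrame  # samples x SNPs, values in [0, 2]
    quality: pd.Series     # per-SNP dosage R^2 in [0, 1]

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = vals[~np.isnan(vals)]
        if ok.size and ((ok < 0) | (ok > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")
        q = self.quality.to_numpy(dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise ValueError("dosage R^2 quality must lie in [0, 1]")

    def maf(self) -> pd.Series:
        f = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)


def classify_cis_trans(
    snp_chrom,
    snp_pos,
    gene_chrom,
    gene_start,
    gene_end,
    cis_half_window: int = 200_000,
) -> str:
    """"cis" iff same chromosome and within the inclusive window of the gene.

    Distance is measured from the SNP to the gene interval (0 inside).
    Missing gene coordinates give "unclassifiable".
    """
    if gene_chrom is None or pd.isna(gene_start) or pd.isna(gene_end):
        return "unclassifiable"
    if str(snp_chrom) != str(gene_chrom):
        return "trans"
    pos = float(snp_pos)
    if pos < float(gene_start):
        dist = float(gene_start) - pos
    elif pos > float(gene_end):
        dist = pos - float(gene_end)
    else:
        dist = 0.0
    return "cis" if dist <= cis_half_window else "trans"


def _std_columns(df: pd.DataFrame, key_map: dict) -> pd.DataFrame:
    out = df.rename(columns=key_map)
    missing = [c for c in key_map.values() if c not in out.columns]
    if missing:
        raise ValueError(f"association table missing columns {missing}")
    return out


def triad_analysis(
    snp_assoc: pd.DataFrame,
    snp_expr_assoc: pd.DataFrame,
    expr_pheno_assoc: pd.DataFrame,
    thresholds: dict | None = None,
    loci: list[Locus] | None = None,
    snp_info: pd.DataFrame | None = None,
    probe_annotation: pd.DataFrame | None = None,
    same_gene_only: bool = False,
    cis_half_window: int = 200_000,
) -> pd.DataFrame:
    """Join the three association legs into qualifying triad records.

    Inputs (columns; extra columns are carried through):
      snp_assoc        snp_id, r, p            (SNP vs IC50)
      snp_expr_assoc   snp_id, probeset_id, r, p
      expr_pheno_assoc probeset_id, r, p
    ``thresholds`` overrides TRIAD_THRESHOLDS per leg; a threshold of 1.0
    disables that leg's filter. With ``loci`` given, SNPs must additionally
    belong to a qualifying locus. ``same_gene_only`` keeps only pairs whose
    probeset gene equals the SNP's annotated gene (columns ``snp_gene`` and
    ``gene_symbol``) — the cis-restricted mode. cis/trans labels are added
    when ``snp_info`` (snp_id, chrom, pos) and ``probe_annotation``
    (probeset_id, chromosome, start, end) are available.
    """
    thr = dict(TRIAD_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    s = _std_columns(snp_assoc, {"predictor_id": "snp_id"}).rename(
        columns={"r": "r_snp_ic50", "p": "p_snp_ic50"}
    )
    e = snp_expr_assoc.rename(columns={"r": "r_snp_expr", "p": "p_snp_expr"})
    x = expr_pheno_assoc.rename(
        columns={"predictor_id": "probeset_id", "r": "r_expr_ic50", "p": "p_expr_ic50"}
    )
    for df, cols in ((s, ["snp_id", "p_snp_ic50"]), (e, ["snp_id", "probeset_id", "p_snp_expr"]), (x, ["probeset_id", "p_expr_ic50"])):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"association table missing columns {missing}")

    if len(s) and len(e) and not (set(s["snp_id"]) & set(e["snp_id"])):
        raise JoinError(
            f"no shared SNP ids between legs; examples: {sorted(set(s['snp_id']))[:3]} vs "
            f"{sorted(set(e['snp_id']))[:3]}"
        )
    if len(e) and len(x) and not (set(e["probeset_id"]) & set(x["probeset_id"])):
        raise JoinError("no shared probeset ids between the expression legs")

    s = s[s["p_snp_ic50"] < thr["snp_ic50"]]
    if loci is not None:
        allowed = {snp for L in loci for snp in L.members}
        s = s[s["snp_id"].isin(allowed)]
    e = e[e["p_snp_expr"] < thr["snp_expr"]]
    x = x[x["p_expr_ic50"] < thr["expr_pheno"]]

    merged = s.merge(e, on="snp_id", how="inner", suffixes=("", "_expr_leg"))
    merged = merged.merge(x, on="probeset_id", how="inner", suffixes=("", "_pheno_leg"))

    if same_gene_only:
        if "snp_gene" not in merged.columns or "gene_symbol" not in merged.columns:
            raise ValueError("same_gene_only requires snp_gene and gene_symbol columns")
        merged = merged[merged["snp_gene"] == merged["gene_symbol"]]

    if snp_info is not None and probe_annotation is not None and len(merged):
        si = snp_info.set_index("snp_id")
        pa = probe_annotation.set_index("probeset_id")
        labels = []
        for _, row in merged.iterrows():
            snp = si.loc[row["snp_id"]]
            if row["probeset_id"] in pa.index:
                probe = pa.loc[row["probeset_id"]]
                labels.append(
                    classify_cis_trans(
                        snp["chrom"], snp["pos"], probe["chromosome"],
                        probe["start"], probe["end"], cis_half_window,
                    )
                )
            else:
                labels.append("unclassifiable")
        merged["cis_flag"] = labels
        n_uncls = int((merged["cis_flag"] == "unclassifiable").sum())
        if n_uncls:
            logger.warning("%d triads lack probeset coordinates (unclassifiable)", n_uncls)
    elif len(merged):
        merged["cis_flag"] = "unclassifiable"

    return merged.sort_values(
        ["p_snp_ic50", "snp_id", "probeset_id"], kind="stable"
    ).reset_index(drop=True)


def validate_triads(triads: pd.DataFrame, thresholds: dict | None = None) -> bool:
    """Independent re-check of the three per-row thresholds."""
    thr = dict(TRIAD_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if triads.empty:
        return True
    return bool(
        (triads["p_snp_ic50"] < thr["snp_ic50"]).all()
        and (triads["p_snp_expr"] < thr["snp_expr"]).all()
        and (triads["p_expr_ic50"] < thr["expr_pheno"]).all()
    )


def summarize_triads(triads: pd.DataFrame, loci: list[Locus] | None = None) -> dict:
    """Distinct SNP / probeset / gene / locus counts over a triad table."""
    out = {
        "n_triads": int(len(triads)),
        "n_snps": int(triads["snp_id"].nunique()) if len(triads) else 0,
        "n_probesets": int(triads["probeset_id"].nunique()) if len(triads) else 0,
    }
    if "gene_symbol" in triads.columns and len(triads):
        out["n_genes"] = int(triads["gene_symbol"].nunique())
    if "cis_flag" in triads.columns and len(triads):
        out["n_cis"] = int((triads["cis_flag"] == "cis").sum())
        out["n_trans"] = int((triads["cis_flag"] == "trans").sum())
    if loci is not None and len(triads):
        snps = set(triads["snp_id"])
        out["n_loci"] = sum(1 for L in loci if snps & set(L.members))
    return out


def filter_dosage_panel(panel: DosagePanel, min_r2: float = 0.3, min_maf: float = 0.01) -> DosagePanel:
    """Drop imputed SNPs with dosage R^2 < min_r2 or MAF < min_maf.

    Both bounds are inclusive on the keep side (quality exactly 0.3 is
    retained, matching the strict "less than" exclusion rule).
    """
    keep = (panel.quality >= min_r2) & (panel.maf() >= min_maf)
    kept = keep[keep].index
    return DosagePanel(panel.dosages[kept], panel.quality[kept])


def imputation_concordance(dosages, genotypes, harmonize: bool = False) -> float:
    """Mean squared difference between imputed dosage and genotype calls.

    Computed over paired non-missing entries; lies in [0, 4]; smaller
    means better concordance. With ``harmonize=True`` the allele
    orientation is unknown and the orientation (d vs 2-d) minimizing the
    metric is used, with a warning. Symmetric under a simultaneous allele
    flip of both inputs.
    """
    d = np.asarray(dosages, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    ok = np.isfinite(d) & np.isfinite(g)
    if not ok.any():
        raise UnavailableValueError("no overlapping non-missing dosage/genotype pairs")
    d, g = d[ok], g[ok]
    msd = float(np.mean((d - g) ** 2))
    if harmonize:
        flipped = float(np.mean(((2.0 - d) - g) ** 2))
        if flipped < msd:
            warnings.warn("allele orientation flipped to minimize discordance")
            return flipped
    return msd


def ld_r2(g1, g2) -> float:
    """Composite LD: squared Pearson correlation of paired 0/1/2 dosages.

    Phase-free; requires >= 2 complete pairs and both SNPs polymorphic in
    the complete-case subset.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise UnavailableValueError("need >= 2 complete genotype pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise UnavailableValueError("monomorphic SNP in complete-case subset")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
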