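"""Published summary tables bundled with the package.

These are the printed locus and triad summary tables from the cytidine-
analogue lymphoblastoid-cell-line study the pipeline re-implements: the
top gemcitabine and AraC SNP-locus tables, and the PIGB cis-triad table.
They serve as fixed worked-example inputs for the locus-comparison and
triad-join operations; the underlying cohort data were never deposited,
so these row-level summaries are the only machine-checkable anchors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .loci import Locus

__all__ = [
    "load_gemcitabine_loci",
    "load_arac_loci",
    "load_pigb_triads",
    "published_loci_as_locus_list",
    "pigb_triad_legs",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("triadscan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_gemcitabine_loci() -> pd.DataFrame:
    """Top 11 gemcitabine SNP loci (seed SNP, lowest r/P, nearby gene...)."""
    return _load("gemcitabine_loci.tsv")


def load_arac_loci() -> pd.DataFrame:
    """Top AraC SNP loci in the same layout as the gemcitabine table."""
    return _load("arac_loci.tsv")


def load_pigb_triads() -> pd.DataFrame:
    """The PIGB cis-triad rows: seven SNPs x two probesets, three legs each."""
    return _load("pigb_triads.tsv")


def published_loci_as_locus_list(df: pd.DataFrame, half_window: int = 100_000) -> list[Locus]:
    """Adapt a published locus summary table to Locus objects.

    Only seed-level information is printed, so each Locus carries its seed
    as the sole explicit member; windows and nearby genes are faithful.
    """
    out = []
    for _, row in df.iterrows():
        pos = int(row["position"])
        out.append(
            Locus(
                seed_snp=str(row["top_snp"]),
                chromosome=str(row["chr"]),
                window=(pos - half_window, pos + half_window),
                seed_pos=pos,
                seed_p=float(row["lowest_p"]),
                seed_r=float(row["lowest_r"]),
                members=[str(row["top_snp"])],
                member_ps=[float(row["lowest_p"])],
                n_p4=1,
                nearby_gene=str(row["nearby_gene"]),
                region=str(row["region"]),
            )
        )
    return out


def pigb_triad_legs():
    """Split the PIGB triad table into the three association legs.

    Returns (snp_assoc, snp_expr_assoc, expr_pheno_assoc) shaped for
    triad_analysis, with ``snp_gene``/``gene_symbol`` columns so the
    same-gene (cis-restricted) mode can be exercised.
    """
    df = load_pigb_triads()
    snp_assoc = (
        df[["snp_id", "snp_chr", "snp_pos", "region", "maf", "r_snp_ic50", "p_snp_ic50"]]
        .drop_duplicates("snp_id")
        .rename(columns={"r_snp_ic50": "r", "p_snp_ic50": "p", "snp_chr": "chrom", "snp_pos": "pos"})
        .assign(snp_gene="PIGB")
        .reset_index(drop=True)
    )
    snp_expr = (
        df[["snp_id", "probeset_id", "gene_symbol", "probeset_chr", "r_snp_expr", "p_snp_expr"]]
        .rename(columns={"r_snp_expr": "r", "p_snp_expr": "p"})
        .reset_index(drop=True)
    )
    expr_pheno = (
        df[["probeset_id", "r_expr_ic50", "p_expr_ic50"]]
        .drop_duplicates("probeset_id")
        .rename(columns={"r_expr_ic50": "r", "p_expr_ic50": "p"})
        .reset_index(drop=True)
    )
    return snp_assoc, snp_expr, expr_pheno
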