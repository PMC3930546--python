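"""File-format readers and writers for every pipeline artifact.

Interchange conventions: TSV with a header line and stable column order
between stages; 1-based inclusive coordinates everywhere (VCF
convention); genotype matrices as either VCF (GT field, one ALT per
record) or sample x SNP dosage TSV with an annotation sidecar.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_genotypes",
    "write_snp_info",
    "read_snp_info",
    "write_expression",
    "read_expression",
    "write_table",
    "read_table",
    "read_dose_response",
]

logger = logging.getLogger(__name__)


def write_vcf(G: GenotypeMatrix, snp_info: pd.DataFrame, path) -> None:
    """Emit a minimal VCF 4.2 with GT-only genotype fields."""
    path = Path(path)
    info = snp_info.set_index("snp_id").loc[G.snp_ids]
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(info["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, G.sample_ids)) + "\n")
        for j, snp_id in enumerate(G.snp_ids):
            row = info.iloc[j]
            gts = "\t".join(gt_strings.get(v, "./.") for v in G.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row.get('ref', 'A')}\t"
                f"{row.get('alt', 'G')}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF into (GenotypeMatrix, snp_info).

    Biallelic records only: multiallelic records are skipped and counted
    (the count is logged); duplicate rsIDs raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    calls_cols, ids, chroms, poss, refs, alts = [], [], [], [], [], []
    n_multi = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
        calls_cols.append(remap[np.asarray(v.gt_types)])
    if n_multi:
        logger.warning("skipped %d multiallelic records", n_multi)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rsIDs in VCF")
    calls = np.column_stack(calls_cols) if calls_cols else np.empty((len(samples), 0))
    info = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return GenotypeMatrix(calls, samples, np.asarray(ids)), info


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.calls, index=pd.Index(G.sample_ids, name="sample_id"), columns=G.snp_ids)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    return GenotypeMatrix(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy())


def read_genotypes(path, fmt: str | None = None, snp_info_path=None):
    """Dispatch on format: "vcf" or "dosage-tsv" (inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return read_vcf(path)
    G = read_genotypes_tsv(path)
    info = read_snp_info(snp_info_path) if snp_info_path else None
    return G, info


def write_snp_info(info: pd.DataFrame, path) -> None:
    info.to_csv(path, sep="\t", index=False)


def read_snp_info(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_expression(expr: pd.DataFrame, path) -> None:
    """Probeset x sample matrix, probeset_id as the index column."""
    expr.to_csv(path, sep="\t", index_label="probeset_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probeset_id")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_dose_response(path) -> pd.DataFrame:
    """Long-format viability CSV: sample_id, drug, dose, viability."""
    df = pd.read_csv(path)
    required = {"sample_id", "drug", "dose", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns {sorted(missing)}")
    return df
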