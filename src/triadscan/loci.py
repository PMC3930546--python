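"""SNP-locus aggregation and between-drug locus comparison.

A locus is a +/-100 kb closed window around a seed SNP that qualifies by
containing either (a) at least 2 SNPs with P < 1e-4, or (b) 1 SNP with
P < 1e-4 plus at least 3 additional SNPs with P < 1e-3 (SNPs below 1e-4
count toward the 3 a fortiori). Seeding is greedy best-first: the
unassigned SNP with the smallest P among those below the strong threshold
seeds the next window; members are assigned to at most one locus, which
makes locus counts well-defined and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "define_loci",
    "validate_locus",
    "annotate_nearest_gene",
    "common_loci",
    "loci_table",
]

logger = logging.getLogger(__name__)


@dataclass
class Locus:
    seed_snp: str
    chromosome: str
    window: tuple  # closed interval [seed_pos - half_window, seed_pos + half_window]
    seed_pos: int
    seed_p: float
    seed_r: float | None
    members: list  # snp ids, seed included
    member_ps: list
    n_p4: int      # members with p < strong threshold
    nearby_gene: str | None = None
    region: str | None = None
    gene_distance: int | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)


def _prepare(assoc: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    df = assoc.rename(columns={"predictor_id": "snp_id"}) if "predictor_id" in assoc.columns else assoc
    if {"chrom", "pos"}.issubset(df.columns):
        merged = df
    else:
        merged = df.merge(snps[["snp_id", "chrom", "pos"]], on="snp_id", how="inner")
    # deterministic ordering regardless of input row order
    return merged.sort_values(["p", "chrom", "pos", "snp_id"], kind="stable").reset_index(drop=True)


def define_loci(
    assoc: pd.DataFrame,
    snps: pd.DataFrame,
    p_strong: float = 1e-4,
    p_weak: float = 1e-3,
    half_window: int = 100_000,
) -> list[Locus]:
    """Greedy window-based aggregation of an association scan into loci.

    ``assoc`` needs columns snp_id (or predictor_id) and p (r optional);
    ``snps`` maps snp_id to chrom and pos. Candidate seeds are taken in
    increasing-P order; a seed that fails the qualification predicate is
    retired as a seed but remains available as a member of a later locus.
    """
    if p_strong > p_weak:
        raise ValueError("p_strong must be <= p_weak")
    df = _prepare(assoc, snps)
    if df.empty:
        return []
    p = df["p"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    snp_id = df["snp_id"].to_numpy()
    r = df["r"].to_numpy() if "r" in df.columns else np.full(len(df), np.nan)

    assigned = np.zeros(len(df), dtype=bool)
    loci: list[Locus] = []
    for i in np.nonzero(p < p_strong)[0]:  # rows are already sorted by p
        if assigned[i]:
            continue
        in_window = (
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= half_window)
            & (p < p_weak)
        )
        members = np.nonzero(in_window)[0]
        n_p4 = int((p[members] < p_strong).sum())
        qualifies = n_p4 >= 2 or (n_p4 >= 1 and len(members) >= 4)
        if not qualifies:
            continue  # retire the seed; members stay available
        assigned[members] = True
        loci.append(
            Locus(
                seed_snp=str(snp_id[i]),
                chromosome=str(chrom[i]),
                window=(int(pos[i]) - half_window, int(pos[i]) + half_window),
                seed_pos=int(pos[i]),
                seed_p=float(p[i]),
                seed_r=float(r[i]) if np.isfinite(r[i]) else None,
                members=[str(s) for s in snp_id[members]],
                member_ps=[float(v) for v in p[members]],
                n_p4=n_p4,
            )
        )
    loci.sort(key=lambda L: (L.seed_p, L.chromosome, L.seed_pos))
    return loci


def validate_locus(locus: Locus, p_strong: float = 1e-4, p_weak: float = 1e-3) -> bool:
    """Independent post-hoc check of the qualification predicate."""
    ps = np.asarray(locus.member_ps)
    if locus.seed_snp not in locus.members:
        return False
    if locus.seed_p > ps.min():
        return False
    if (ps >= p_weak).any():
        return False
    n_p4 = int((ps < p_strong).sum())
    return n_p4 >= 2 or (n_p4 >= 1 and len(ps) >= 4)


def annotate_nearest_gene(locus: Locus, genes: pd.DataFrame) -> Locus:
    """Attach the nearest gene (by distance from seed to gene interval).

    ``genes`` needs columns gene_symbol, chromosome, start, end (strand
    optional; plus-strand convention when absent). Region class is
    "within" when the seed lies inside the interval, else "upstream" /
    "downstream" relative to gene orientation. Ties go to the
    lexicographically smaller symbol and are logged.
    """
    g = genes[genes["chromosome"].astype(str) == str(locus.chromosome)]
    if g.empty:
        locus.nearby_gene = None
        locus.region = "unannotated"
        return locus
    start = g["start"].to_numpy()
    end = g["end"].to_numpy()
    pos = locus.seed_pos
    dist = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
    best = dist.min()
    cand = g.iloc[np.nonzero(dist == best)[0]].sort_values("gene_symbol")
    if len(cand) > 1:
        logger.info(
            "nearest-gene tie at %s: %s; choosing %s",
            locus.seed_snp,
            list(cand["gene_symbol"]),
            cand["gene_symbol"].iloc[0],
        )
    row = cand.iloc[0]
    strand = row.get("strand", "+") if hasattr(row, "get") else "+"
    locus.nearby_gene = str(row["gene_symbol"])
    locus.gene_distance = int(best)
    if best == 0:
        locus.region = "within"
    else:
        before = pos < row["start"]
        if strand == "-":
            locus.region = "downstream" if before else "upstream"
        else:
            locus.region = "upstream" if before else "downstream"
    return locus


def common_loci(loci_a: list[Locus], loci_b: list[Locus]) -> dict:
    """Genes and windows shared between two annotated locus lists.

    Returns ``shared_genes`` (symbols appearing as nearby_gene in both
    lists, sorted) and ``overlapping_pairs`` (index pairs whose windows
    overlap on the same chromosome).
    """
    genes_a = {L.nearby_gene for L in loci_a if L.nearby_gene}
    genes_b = {L.nearby_gene for L in loci_b if L.nearby_gene}
    shared = sorted(genes_a & genes_b)
    pairs = []
    for i, La in enumerate(loci_a):
        for j, Lb in enumerate(loci_b):
            if La.chromosome == Lb.chromosome and (
                La.window[0] <= Lb.window[1] and Lb.window[0] <= La.window[1]
            ):
                pairs.append((i, j))
    return {"shared_genes": shared, "overlapping_pairs": pairs}


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Flat per-locus summary (one row per locus, seed-P sorted)."""
    return pd.DataFrame(
        [
            {
                "seed_snp": L.seed_snp,
                "seed_r": L.seed_r,
                "seed_p": L.seed_p,
                "nearby_gene": L.nearby_gene,
                "chrom": L.chromosome,
                "pos": L.seed_pos,
                "region": L.region,
                "n_members": L.n_members,
                "n_p_strong": L.n_p4,
                "members": ";".join(L.members),
            }
            for L in loci
        ]
    )
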