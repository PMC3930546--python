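"""End-to-end pipeline driver: IC50 fitting through triad integration.

Stage order: ic50 -> phenotype transform -> genotype QC -> eigenvectors ->
association scans (SNP-phenotype, SNP-expression, expression-phenotype)
-> locus aggregation -> triad integration. Every stage writes its TSV
artifact and logs input/output counts, so a flow-diagram of SNPs in /
passing / loci / triads can be reconstructed from the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .association import association_scan
from .covariates import build_design, compute_eigenvectors
from .dose_response import fit_all_curves, transform_phenotype
from .integration import TRIAD_THRESHOLDS, summarize_triads, triad_analysis
from .loci import define_loci, loci_table
from .qc import QCThresholds, apply_qc
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and the drug -> transform mapping for one run."""

    genotypes: str = ""
    snp_info: str = ""
    expression: str = ""
    probe_annotation: str = ""
    curves: str = ""
    covariates: str = ""
    out_dir: str = "results"

    qc: QCThresholds = field(default_factory=QCThresholds)
    n_eigenvectors: int = 5
    locus_p_strong: float = 1e-4
    locus_p_weak: float = 1e-3
    locus_half_window: int = 100_000
    triad_thresholds: dict = field(default_factory=lambda: dict(TRIAD_THRESHOLDS))
    cis_half_window: int = 200_000
    drug_transforms: dict = field(default_factory=lambda: {"gemcitabine": "log10", "AraC": "vdw"})
    restrict_triads_to_loci: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCThresholds(**raw["qc"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class PipelineResult:
    ic50_fits: pd.DataFrame
    phenotypes: pd.DataFrame          # samples x drugs (transformed)
    qc_samples: pd.DataFrame
    qc_snps: pd.DataFrame
    eigenvectors: pd.DataFrame
    snp_assoc: dict                   # drug -> DataFrame
    snp_expr_assoc: dict
    expr_pheno_assoc: dict
    loci: dict                        # drug -> list[Locus]
    triads: dict
    summary: dict


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict:
    """Write every artifact of a simulated cohort; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.vcf",
        "genotypes_tsv": out / "genotypes.tsv",
        "snp_info": out / "snp_info.tsv",
        "expression": out / "expression.tsv",
        "probe_annotation": out / "probe_annotation.tsv",
        "covariates": out / "covariates.tsv",
        "curves": out / "dose_response.csv",
        "truth": out / "truth.tsv",
    }
    tio.write_vcf(cohort.genotypes, cohort.snp_info, paths["genotypes"])
    tio.write_genotypes_tsv(cohort.genotypes, paths["genotypes_tsv"])
    tio.write_snp_info(cohort.snp_info, paths["snp_info"])
    tio.write_expression(cohort.expression, paths["expression"])
    tio.write_table(cohort.probe_annotation, paths["probe_annotation"])
    tio.write_table(cohort.covariates, paths["covariates"])
    cohort.dose_response.to_csv(paths["curves"], index=False)
    tio.write_table(cohort.truth.to_frame(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def _phenotypes_from_fits(fits: pd.DataFrame, drug_transforms: dict) -> pd.DataFrame:
    wide = fits.pivot(index="sample_id", columns="drug", values="ic50")
    out = {}
    for drug in wide.columns:
        method = drug_transforms.get(drug, "log10")
        out[drug] = transform_phenotype(wide[drug], method).to_numpy()
    return pd.DataFrame(out, index=wide.index)


def run_pipeline(config: RunConfig, cohort: SimulatedCohort | None = None) -> PipelineResult:
    """Execute the full analysis and write stage artifacts under out_dir.

    Inputs come either from ``config`` paths or directly from an
    in-memory simulated cohort. All tabular outputs are deterministic
    given (inputs, config, seed), including row order.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is not None:
        curves = cohort.dose_response
        G, snp_info = cohort.genotypes, cohort.snp_info
        expression = cohort.expression
        probes = cohort.probe_annotation
        covars = cohort.covariates
    else:
        curves = tio.read_dose_response(config.curves)
        G, snp_info = tio.read_genotypes(config.genotypes, snp_info_path=config.snp_info or None)
        if snp_info is None:
            snp_info = tio.read_snp_info(config.snp_info)
        expression = tio.read_expression(config.expression)
        probes = tio.read_table(config.probe_annotation, dtype={"chromosome": str})
        covars = tio.read_table(config.covariates)

    # stage 1-2: dose-response fits and transformed phenotypes
    fits = fit_all_curves(curves, model="auto")
    n_fail = int((~fits["converged"]).sum())
    logger.info("ic50: %d curves fitted, %d non-converged (excluded)", len(fits), n_fail)
    tio.write_table(fits, out / "ic50_fits.tsv")
    phenotypes = _phenotypes_from_fits(fits, config.drug_transforms)
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index_label="sample_id")

    # stage 3: genotype QC
    G2, snp_info2, qc_report = apply_qc(G, config.qc, snp_info=snp_info)
    logger.info(
        "qc: %d/%d samples, %d/%d SNPs retained",
        G2.n_samples, G.n_samples, G2.n_snps, G.n_snps,
    )
    tio.write_table(qc_report.samples, out / "qc_samples.tsv")
    tio.write_table(qc_report.snps, out / "qc_snps.tsv")
    if qc_report.empty_result:
        logger.warning("qc: empty matrix after filtering; downstream tables will be empty")

    # stage 4: stratification eigenvectors
    k_ev = min(config.n_eigenvectors, max(min(G2.n_samples, G2.n_snps) - 1, 0))
    ev = (
        compute_eigenvectors(G2, k_ev)
        if not qc_report.empty_result and k_ev > 0
        else np.zeros((G2.n_samples, 0))
    )
    ev_df = pd.DataFrame(
        ev, index=pd.Index(G2.sample_ids, name="sample_id"),
        columns=[f"EV{i + 1}" for i in range(ev.shape[1])],
    )
    ev_df.to_csv(out / "eigenvectors.tsv", sep="\t")

    # stage 5: designs aligned to QC-passed sample order
    covars_aligned = covars.set_index("sample_id").loc[G2.sample_ids].reset_index()
    design_snp = build_design(covars_aligned, ev, include_eigenvectors=True)
    design_expr = build_design(covars_aligned, None, include_eigenvectors=False)
    expr_aligned = expression[G2.sample_ids]

    snp_assoc, snp_expr_assoc, expr_pheno_assoc, loci_by_drug, triads_by_drug = {}, {}, {}, {}, {}
    summary = {"qc": qc_report.counts, "n_curves": len(fits), "n_curves_failed": n_fail}

    geno_df = pd.DataFrame(G2.calls, columns=G2.snp_ids)
    for drug in phenotypes.columns:
        y = phenotypes[drug].reindex(G2.sample_ids).to_numpy()

        assoc = association_scan(geno_df, y, design_snp, response_id=f"{drug}_ic50")
        assoc = assoc.merge(
            snp_info2[["snp_id", "chrom", "pos"]],
            left_on="predictor_id", right_on="snp_id", how="left",
        ).drop(columns="snp_id")
        tio.write_table(assoc, out / f"assoc_{drug}.tsv")

        drug_loci = define_loci(
            assoc, snp_info2,
            p_strong=config.locus_p_strong,
            p_weak=config.locus_p_weak,
            half_window=config.locus_half_window,
        )
        tio.write_table(loci_table(drug_loci), out / f"loci_{drug}.tsv")

        # SNP-expression leg, restricted to the integrated-analysis entry set
        candidates = assoc.loc[assoc["p"] < config.triad_thresholds["snp_ic50"], "predictor_id"]
        cand = candidates.tolist()
        eqtl_frames = []
        if cand:
            sub = geno_df[cand]
            for probeset_id, row in expr_aligned.iterrows():
                scan = association_scan(
                    sub, row.to_numpy(), design_snp,
                    response_id=str(probeset_id), compute_q=False,
                )
                eqtl_frames.append(scan)
        eqtl = (
            pd.concat(eqtl_frames, ignore_index=True)
            if eqtl_frames
            else pd.DataFrame(columns=["predictor_id", "response_id", "n", "k", "r", "t", "p"])
        )
        eqtl = eqtl.rename(columns={"predictor_id": "snp_id", "response_id": "probeset_id"})
        tio.write_table(eqtl, out / f"snp_expr_{drug}.tsv")

        ep = association_scan(expr_aligned.T, y, design_expr, response_id=f"{drug}_ic50")
        ep = ep.rename(columns={"predictor_id": "probeset_id"})
        ep = ep.merge(
            probes[["probeset_id", "gene_symbol"]], on="probeset_id", how="left"
        )
        tio.write_table(ep, out / f"expr_pheno_{drug}.tsv")

        triads = triad_analysis(
            assoc.rename(columns={"predictor_id": "snp_id"}),
            eqtl,
            ep,
            thresholds=config.triad_thresholds,
            loci=drug_loci if config.restrict_triads_to_loci else None,
            snp_info=snp_info2,
            probe_annotation=probes,
            cis_half_window=config.cis_half_window,
        )
        tio.write_table(triads, out / f"triads_{drug}.tsv")

        snp_assoc[drug] = assoc
        snp_expr_assoc[drug] = eqtl
        expr_pheno_assoc[drug] = ep
        loci_by_drug[drug] = drug_loci
        triads_by_drug[drug] = triads
        summary[drug] = {
            "n_snps_tested": int(len(assoc)),
            "n_snps_p_weak": int((assoc["p"] < config.locus_p_weak).sum()),
            "n_snps_p_strong": int((assoc["p"] < config.locus_p_strong).sum()),
            "n_loci": len(drug_loci),
            **summarize_triads(triads, drug_loci),
        }
        logger.info("%s: %s", drug, summary[drug])

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return PipelineResult(
        ic50_fits=fits,
        phenotypes=phenotypes,
        qc_samples=qc_report.samples,
        qc_snps=qc_report.snps,
        eigenvectors=ev_df,
        snp_assoc=snp_assoc,
        snp_expr_assoc=snp_expr_assoc,
        expr_pheno_assoc=expr_pheno_assoc,
        loci=loci_by_drug,
        triads=triads_by_drug,
        summary=summary,
    )
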