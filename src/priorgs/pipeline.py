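"""End-to-end orchestration: QC -> adjust -> GWAS -> weighted kinships -> CV.

Runs the full prior-weighted genomic selection analysis for each trait in
the phenotype file: quality control, per-individual adjusted phenotypes, the
iterative GWAS, top-k% prior partitions, subset variance estimation, the
weighted kinship Gt, a genetic-parameter table and a cross-validated
accuracy summary. Every output file carries the tool version, a config hash
and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import DEFAULT_FACTORS, adjust_phenotypes
from .genotypes import GenotypeMatrix
from .grm import blend, vanraden, weight_combine
from .gs_eval import run_scenarios
from .gwas import BlinkConfig, blink, select_top_fraction
from .io import read_genotypes, read_phenotypes, write_kinship
from .qc import filter_genotypes, remove_phenotype_outliers
from .varcomp import estimate_subset_variances, fit_repeatability_model

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and switches of one pipeline run."""

    geno_path: str = ""
    pheno_path: str = ""
    out_dir: str = "priorgs_out"
    # QC
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    snp_call_min: float = 0.90
    ind_call_min: float = 0.90
    outlier_sd: float = 3.0
    # adjustment / model
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    # GWAS
    ld_r2_max: float = 0.7
    max_pseudo_qtns: int = 20
    max_iterations: int = 10
    bic_penalty_form: str = "doubled"
    # prior sets / kinship
    fractions: list = field(default_factory=lambda: [0.05, 0.10, 0.15, 0.20])
    blend_beta: float = 0.01
    subset_mode: str = "separate"
    # cross-validation
    k_folds: int = 5
    seed: int = 42
    comparator: str = "adjusted_mean"
    reestimate_vc: bool = True

    def __post_init__(self) -> None:
        fr = sorted(set(self.fractions))
        if fr != list(self.fractions):
            self.fractions = fr
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0,1]")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"priorgs {__version__} config={self.config_hash()} seed={self.seed}"


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: PipelineConfig,
    geno: GenotypeMatrix | None = None,
    records: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage; returns the output bundle as a dict.

    ``geno``/``records`` may be passed in memory; otherwise they are read
    from the configured paths. Any stage failure aborts with the stage name
    while earlier artifacts stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = config.header()
    bundle: dict = {"config": config}
    stage = "read"
    try:
        t0 = time.time()
        if geno is None:
            geno = read_genotypes(config.geno_path)
        if records is None:
            records = read_phenotypes(config.pheno_path)
        log.info("read: %d individuals x %d SNPs, %d records",
                 geno.n_individuals, geno.n_snps, len(records))

        stage = "qc"
        geno_qc, geno_report = filter_genotypes(
            geno, config.maf_min, config.hwe_p_min, config.snp_call_min, config.ind_call_min
        )
        records_qc, pheno_report = remove_phenotype_outliers(records, config.outlier_sd)
        # reconcile ids across genotypes and phenotypes
        known = set(geno_qc.ids)
        unmatched = ~records_qc["id"].isin(known)
        if unmatched.any():
            log.warning("dropping %d records of individuals without genotypes", int(unmatched.sum()))
            records_qc = records_qc[~unmatched].reset_index(drop=True)
        geno_report.n_records_removed_outlier = pheno_report.n_records_removed_outlier
        _write_table(geno_report.to_frame(), out / "qc_report.csv", hdr)
        log.info("qc: %d SNPs retained of %d", geno_qc.n_snps, geno.n_snps)

        stage = "adjust"
        adjusted = adjust_phenotypes(records_qc, config.factors)
        _write_table(adjusted, out / "adjusted_phenotypes.csv", hdr)

        stage = "kinship-all"
        G_all = blend(vanraden(geno_qc), config.blend_beta)
        write_kinship(G_all, out / "G_all.txt", hdr)

        bundle.update(geno=geno_qc, records=records_qc, adjusted=adjusted, G_all=G_all,
                      qc_report=geno_report, traits={})
        blink_cfg = BlinkConfig(
            ld_r2_max=config.ld_r2_max,
            max_pseudo_qtns=config.max_pseudo_qtns,
            max_iterations=config.max_iterations,
            bic_penalty_form=config.bic_penalty_form,
        )

        for trait in adjusted["trait"].unique():
            stage = f"gwas[{trait}]"
            adj_t = adjusted[adjusted["trait"] == trait]
            rec_t = records_qc[records_qc["trait"] == trait]
            assoc = blink(geno_qc, adj_t, blink_cfg)
            _write_table(assoc.results, out / f"gwas_{trait}.csv", hdr)

            stage = f"varcomp[{trait}]"
            fit_all = fit_repeatability_model(rec_t, G_all, config.factors)
            param_rows = [_param_row("All", "G", fit_all, None)]
            kinships = {"All": G_all}
            for frac in config.fractions:
                label = f"Top {int(round(frac * 100))}%"
                prior_ids = select_top_fraction(assoc, frac)
                rest_ids = [i for i in geno_qc.snps["id"] if i not in set(prior_ids)]
                G1 = blend(vanraden(geno_qc, prior_ids, kind="prior"), config.blend_beta)
                G2 = blend(vanraden(geno_qc, rest_ids, kind="remainder"), config.blend_beta)
                var1, var2, fits = estimate_subset_variances(
                    rec_t, G1, G2, config.factors, mode=config.subset_mode
                )
                wk = weight_combine(G1, G2, var1, var2)
                fit_t = fit_repeatability_model(rec_t, wk.Gt, config.factors)
                kinships[label] = wk.Gt
                if "G1" in fits:
                    param_rows.append(_param_row(label, "G1", fits["G1"], wk.omega))
                    param_rows.append(_param_row(label, "G2", fits["G2"], 1 - wk.omega))
                param_rows.append(_param_row(label, "Gt", fit_t, None))
            params = pd.DataFrame(param_rows)
            _write_table(params, out / f"parameters_{trait}.csv", hdr)

            stage = f"cv[{trait}]"
            reports = run_scenarios(
                rec_t, kinships, config.factors, config.k_folds, config.seed,
                comparator=config.comparator, reestimate=config.reestimate_vc,
            )
            summary = pd.DataFrame([r.summary_row() for r in reports.values()])
            _write_table(summary, out / f"cv_{trait}.csv", hdr)
            bundle["traits"][trait] = dict(
                assoc=assoc, parameters=params, cv=reports, fit_all=fit_all
            )
        log.info("pipeline finished in %.1f s", time.time() - t0)
        return bundle
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _param_row(prior: str, matrix: str, fit, weight) -> dict:
    return {
        "prior": prior,
        "matrix": matrix,
        "sigma2_a": fit.sigma2_a,
        "se_a": fit.se_a,
        "sigma2_pe": fit.sigma2_pe,
        "se_pe": fit.se_pe,
        "sigma2_e": fit.sigma2_e,
        "se_e": fit.se_e,
        "h2": round(fit.h2, 2),
        "rep": round(fit.rep, 2),
        "weight": None if weight is None else round(weight, 2),
    }
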