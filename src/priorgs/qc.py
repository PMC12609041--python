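"""Genotype quality control and phenotype outlier exclusion.

Filters follow common PLINK practice: per-individual call rate (``--mind``),
per-SNP call rate (``--geno``), minor allele frequency (``--maf``) and a
Hardy-Weinberg conditional exact test (``--hwe``), applied in that fixed
order so every removed SNP is attributed to exactly one filter. Surviving
missing dosages are mean-imputed (2 * sample allele frequency), which the
VanRaden relationship matrix requires and which leaves allele frequencies
unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["QCReport", "EmptyPanelError", "hwe_exact_test", "filter_genotypes", "remove_phenotype_outliers"]


class EmptyPanelError(RuntimeError):
    """Raised when a filter leaves no SNPs (or individuals) in the panel."""


@dataclass
class QCReport:
    n_snps_in: int = 0
    n_snps_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    removed_by_ind_callrate: int = 0
    removed_by_snp_callrate: int = 0
    removed_by_maf: int = 0
    removed_by_hwe: int = 0
    n_records_removed_outlier: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.__dict__.items() if not isinstance(v, dict)]
        rows += [(f"outliers_removed[{t}]", n) for t, n in self.n_records_removed_outlier.items()]
        return pd.DataFrame(rows, columns=["metric", "count"])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (two-sided by probability mass, the PLINK
    convention). Returns 1.0 for degenerate tables with a fixed outcome.
    """
    if n_AA < 0 or n_Aa < 0 or n_aa < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = 2 * min(n_AA, n_aa) + n_Aa
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    # unnormalized log-probabilities: P(het) ∝ rare!common!n! / (...)
    # computed via lgamma for stability, then normalized
    common = 2 * n - rare
    logp = []
    for het in het_values:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        if hom_c < 0:
            logp.append(-math.inf)
            continue
        lp = (
            het * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_c + 1)
        )
        logp.append(lp)
    logp = np.array(logp)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[het_values.index(n_Aa)]
    # tolerance guards ties against floating-point noise
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(column)
    g = np.rint(column[ok]).astype(int)
    return int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0))


def filter_genotypes(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    snp_call_min: float = 0.90,
    ind_call_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply call-rate, MAF and HWE filters; impute surviving missing calls.

    Filter order: individual call rate -> SNP call rate -> MAF -> HWE.
    Removal counts partition the removed SNP set (each SNP is attributed to
    the first filter that excludes it).
    """
    for name, val in [("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                      ("snp_call_min", snp_call_min), ("ind_call_min", ind_call_min)]:
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must be in (0,1), got {val}")

    report = QCReport(n_snps_in=geno.n_snps, n_individuals_in=geno.n_individuals)

    keep_ind = geno.individual_call_rate() >= ind_call_min
    report.removed_by_ind_callrate = 0  # attributed to individuals, not SNPs
    if not keep_ind.any():
        raise EmptyPanelError("individual call-rate filter removed every individual")
    g = geno.subset_individuals(np.flatnonzero(keep_ind))
    n_ind_removed = geno.n_individuals - g.n_individuals
    report.n_individuals_out = g.n_individuals
    report.removed_by_ind_callrate = n_ind_removed

    alive = np.ones(g.n_snps, dtype=bool)

    cr = g.snp_call_rate()
    fail = alive & (cr < snp_call_min)
    report.removed_by_snp_callrate = int(fail.sum())
    alive &= ~fail
    if not alive.any():
        raise EmptyPanelError("SNP call-rate filter removed every SNP")

    maf = g.maf()
    fail = alive & ((maf < maf_min) | np.isnan(maf))
    report.removed_by_maf = int(fail.sum())
    alive &= ~fail
    if not alive.any():
        raise EmptyPanelError("MAF filter removed every SNP")

    hwe_fail = 0
    for j in np.flatnonzero(alive):
        nAA, nAa, naa = _genotype_counts(g.dosages[:, j])
        if nAA + nAa + naa == 0:
            continue
        if hwe_exact_test(nAA, nAa, naa) < hwe_p_min:
            alive[j] = False
            hwe_fail += 1
    report.removed_by_hwe = hwe_fail
    if not alive.any():
        raise EmptyPanelError("HWE filter removed every SNP")

    out = g.subset_snps(np.flatnonzero(alive))
    # mean-impute: preserves 2*p-hat exactly
    p = out.allele_freqs()
    miss = np.isnan(out.dosages)
    if miss.any():
        fill = np.broadcast_to(2.0 * p, out.dosages.shape)
        out.dosages[miss] = fill[miss]
        out._freq_cache = None
    report.n_snps_out = out.n_snps
    return out, report


def remove_phenotype_outliers(
    records: pd.DataFrame, k_sd: float = 3.0
) -> tuple[pd.DataFrame, QCReport]:
    """Drop records beyond ``mean +/- k_sd * SD`` of their trait.

    Single pass per trait: the mean and SD are those of the input records,
    not recomputed after removals. A zero-SD trait loses no records.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    records = records.reset_index(drop=True)
    report = QCReport()
    keep = np.ones(len(records), dtype=bool)
    for trait, sub in records.groupby("trait"):
        if len(sub) < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 records")
        mu = sub["value"].mean()
        sd = sub["value"].std(ddof=1)
        if sd == 0:
            report.n_records_removed_outlier[trait] = 0
            continue
        bad = (sub["value"] - mu).abs() > k_sd * sd
        keep[sub.index[bad]] = False
        report.n_records_removed_outlier[trait] = int(bad.sum())
    if not keep.all():
        warnings.warn(f"removed {int((~keep).sum())} outlier records", stacklevel=2)
    return records.loc[keep].reset_index(drop=True), report
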