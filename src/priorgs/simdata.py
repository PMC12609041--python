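"""Synthetic genotypes and repeated-record phenotypes.

The generator mirrors the design of a fleece-trait genomic selection study in
a cashmere goat population: a few thousand individuals genotyped on a dense
SNP panel, one to eight repeated records per individual collected over years,
and herd / measurement-year / sex / age acting as categorical environmental
factors. Phenotypes decompose as

    value = mean + breeding value + permanent environment + factor effects + residual

with variance components set by a narrow-sense heritability ``h2_true`` and a
repeatability ``rep_true`` on a unit-total-variance convention, so recovery
targets are unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import GenotypeMatrix

__all__ = ["TraitSpec", "TruthSet", "simulate_genotypes", "simulate_phenotypes"]

DEFAULT_FACTOR_LEVELS = {"year": 6, "herd": 4, "sex": 2, "age": 8}


@dataclass
class TraitSpec:
    """Generative description of one quantitative trait.

    Attributes
    ----------
    h2_true : float
        Narrow-sense heritability on the observed scale, in [0, 1].
    rep_true : float
        Repeatability; must satisfy ``h2_true <= rep_true <= 1``. The
        permanent environmental variance is ``rep_true - h2_true`` times the
        total variance.
    n_qtl : int
        Number of causal SNPs drawn from the panel.
    qtl_effect_dist : tuple
        ``("normal", sd)`` or ``("gamma", shape)``; gamma effects get random
        signs. Effects are rescaled afterwards, so only the shape matters.
    records_per_individual : tuple
        ``(min, max, mean)`` of the per-individual record count; counts are
        drawn as ``min + Binomial(max - min, (mean - min)/(max - min))``.
    factor_levels : dict
        Level counts for the categorical factors year/herd/sex/age.
    factor_sd : float or dict
        Standard deviation of the level effects of each factor, in units of
        the phenotypic SD.
    phenotype_mean, phenotype_sd : float
        Location and scale of the observed values; all variance components
        are fractions of ``phenotype_sd ** 2``.
    age_year_confounding : float
        Fraction of individuals whose age progresses with the record year
        (longitudinal sampling); the rest get age drawn independently.
    """

    h2_true: float = 0.3
    rep_true: float = 0.45
    n_qtl: int = 100
    qtl_effect_dist: tuple = ("normal", 1.0)
    records_per_individual: tuple = (1, 8, 4.26)
    factor_levels: dict = field(default_factory=lambda: dict(DEFAULT_FACTOR_LEVELS))
    factor_sd: float | dict = 0.5
    phenotype_mean: float = 0.0
    phenotype_sd: float = 1.0
    age_year_confounding: float = 0.5
    name: str = "trait"

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= self.rep_true <= 1.0:
            raise ValueError(
                f"need 0 <= h2_true <= rep_true <= 1, got h2={self.h2_true}, rep={self.rep_true}"
            )
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        rmin, rmax, rmean = self.records_per_individual
        if rmin < 1 or rmax < rmin or not rmin <= rmean <= rmax:
            raise ValueError(f"bad records_per_individual descriptor {self.records_per_individual}")

    def variances(self) -> tuple[float, float, float]:
        """(sigma2_a, sigma2_pe, sigma2_e) implied by h2, rep and the scale."""
        tot = self.phenotype_sd**2
        return (
            self.h2_true * tot,
            (self.rep_true - self.h2_true) * tot,
            (1.0 - self.rep_true) * tot,
        )

    def sd_of(self, factor: str) -> float:
        if isinstance(self.factor_sd, dict):
            return float(self.factor_sd.get(factor, 0.0))
        return float(self.factor_sd)


@dataclass
class TruthSet:
    """Ground truth saved by the generator for recovery tests."""

    true_breeding_values: pd.Series
    true_pe_values: pd.Series
    qtl_ids: list
    true_variances: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.true_breeding_values.index,
                "tbv": self.true_breeding_values.to_numpy(),
                "pe": self.true_pe_values.to_numpy(),
            }
        )


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    n_chrom: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    ld_rho: float = 0.0,
    ld_block_size: int = 20,
) -> GenotypeMatrix:
    """Draw a biallelic SNP panel with no missing calls.

    Each SNP's allele frequency is uniform on ``maf_range`` and dosages are
    binomial(2, p), i.e. linkage equilibrium and Hardy-Weinberg proportions.
    With ``ld_rho > 0`` the two gametes are drawn from an AR(1) Gaussian
    copula within windows of ``ld_block_size`` adjacent SNPs, producing
    local linkage disequilibrium for testing LD-aware steps.

    Markers are split near-evenly over ``n_chrom`` chromosomes with strictly
    increasing positions.
    """
    if n_individuals <= 0 or n_snps <= 0 or n_chrom <= 0:
        raise ValueError("n_individuals, n_snps and n_chrom must be positive")
    if n_snps < n_chrom:
        raise ValueError("need at least one SNP per chromosome")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1)")

    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)

    if ld_rho == 0.0:
        dosages = rng.binomial(2, p, size=(n_individuals, n_snps)).astype(np.float64)
    else:
        thresh = norm.ppf(p)
        dosages = np.zeros((n_individuals, n_snps))
        for _gamete in range(2):
            z = np.empty((n_individuals, n_snps))
            for start in range(0, n_snps, ld_block_size):
                stop = min(start + ld_block_size, n_snps)
                eps = rng.standard_normal((n_individuals, stop - start))
                z[:, start] = eps[:, 0]
                for j in range(start + 1, stop):
                    z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * eps[:, j - start]
            dosages += z < thresh
    # chromosome labels and increasing positions
    chrom = np.repeat(np.arange(1, n_chrom + 1), np.diff(np.linspace(0, n_snps, n_chrom + 1).astype(int)))
    pos = np.empty(n_snps, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        k = int(np.sum(chrom == c))
        pos[chrom == c] = 1000 * (1 + np.arange(k))
    snps = pd.DataFrame(
        {
            "id": [f"snp{j+1}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }
    )
    ids = np.array([f"ind{i+1}" for i in range(n_individuals)], dtype=object)
    return GenotypeMatrix(dosages, ids, snps)


def _draw_record_counts(rng: np.random.Generator, n: int, descriptor: tuple) -> np.ndarray:
    rmin, rmax, rmean = descriptor
    rmin, rmax = int(rmin), int(rmax)
    if rmax == rmin:
        return np.full(n, rmin, dtype=int)
    prob = (rmean - rmin) / (rmax - rmin)
    return rmin + rng.binomial(rmax - rmin, prob, size=n)


def _draw_effects(rng: np.random.Generator, n: int, dist: tuple) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(0.0, dist[1], size=n)
    if kind == "gamma":
        mag = rng.gamma(dist[1], 1.0, size=n)
        return mag * rng.choice([-1.0, 1.0], size=n)
    raise ValueError(f"unknown effect distribution {dist!r}")


def simulate_phenotypes(
    geno: GenotypeMatrix, spec: TraitSpec, seed: int = 0
) -> tuple[pd.DataFrame, TruthSet]:
    """Generate long-format repeated records for one trait.

    Returns a record table with columns ``id, trait, value, year, herd, sex,
    age`` and the :class:`TruthSet` used to generate it. Breeding values are
    QTL-dosage sums rescaled so their sample variance equals the target
    additive variance exactly; permanent environmental deviations and
    residuals are i.i.d. normal at their target variances.
    """
    if spec.n_qtl > geno.n_snps:
        raise ValueError(f"n_qtl={spec.n_qtl} exceeds panel size {geno.n_snps}")
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    s2a, s2pe, s2e = spec.variances()

    qtl_cols = np.sort(rng.choice(geno.n_snps, size=spec.n_qtl, replace=False))
    qtl_ids = geno.snps["id"].iloc[qtl_cols].tolist()
    effects = _draw_effects(rng, spec.n_qtl, spec.qtl_effect_dist)
    g = geno.dosages[:, qtl_cols] @ effects
    g = g - g.mean()
    sd = g.std()
    if s2a > 0 and sd > 0:
        g *= np.sqrt(s2a) / sd
    else:
        g = np.zeros(n)
    pe = rng.normal(0.0, np.sqrt(s2pe), size=n) if s2pe > 0 else np.zeros(n)

    counts = _draw_record_counts(rng, n, spec.records_per_individual)
    levels = spec.factor_levels
    n_year, n_herd, n_sex, n_age = (levels[k] for k in ("year", "herd", "sex", "age"))
    level_effects = {
        f: rng.normal(0.0, spec.sd_of(f), size=levels[f]) for f in ("year", "herd", "sex", "age")
    }

    herd_of = rng.integers(0, n_herd, size=n)
    sex_of = rng.integers(0, n_sex, size=n)
    longitudinal = rng.random(n) < spec.age_year_confounding

    rows_id, rows_year, rows_herd, rows_sex, rows_age, rows_val = [], [], [], [], [], []
    for i in range(n):
        k = counts[i]
        start = rng.integers(0, max(1, n_year - k + 1))
        years = (start + np.arange(k)).clip(max=n_year - 1)
        if longitudinal[i]:
            ages = np.minimum(1 + np.arange(k), n_age)
        else:
            ages = rng.integers(1, n_age + 1, size=k)
        resid = rng.normal(0.0, np.sqrt(s2e), size=k) if s2e > 0 else np.zeros(k)
        vals = (
            spec.phenotype_mean
            + g[i]
            + pe[i]
            + level_effects["year"][years]
            + level_effects["herd"][herd_of[i]]
            + level_effects["sex"][sex_of[i]]
            + level_effects["age"][ages - 1]
            + resid
        )
        rows_id.extend([geno.ids[i]] * k)
        rows_year.extend((2015 + years).tolist())
        rows_herd.extend([herd_of[i] + 1] * k)
        rows_sex.extend([sex_of[i] + 1] * k)
        rows_age.extend(ages.tolist())
        rows_val.extend(vals.tolist())

    records = pd.DataFrame(
        {
            "id": rows_id,
            "trait": spec.name,
            "value": rows_val,
            "year": rows_year,
            "herd": rows_herd,
            "sex": rows_sex,
            "age": rows_age,
        }
    )
    truth = TruthSet(
        true_breeding_values=pd.Series(g, index=geno.ids),
        true_pe_values=pd.Series(pe, index=geno.ids),
        qtl_ids=qtl_ids,
        true_variances=(s2a, s2pe, s2e),
    )
    return records, truth
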