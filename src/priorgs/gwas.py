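"""Iterative fixed-effect GWAS with pseudo-QTN conditioning (BLINK-style).

Each iteration runs a single-marker ordinary-least-squares scan of the
adjusted phenotype conditioned on the current pseudo-QTN set, then reselects
pseudo-QTNs: candidates are taken in order of ascending p-value, mutually
filtered on linkage disequilibrium (squared dosage correlation), and the
retained prefix length is chosen by an information criterion. Iteration
stops when the pseudo-QTN set is stable or the iteration cap is reached.
The per-SNP p-values of the final conditioned scan rank markers for the
top-k% prior sets used downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "BlinkConfig",
    "AssocResult",
    "single_marker_scan",
    "select_pseudo_qtns",
    "blink",
    "select_top_fraction",
]

_VAR_TOL = 1e-12


@dataclass
class BlinkConfig:
    """Settings of the iterative scan.

    ld_r2_max : squared-correlation ceiling for mutual pseudo-QTN filtering.
    max_pseudo_qtns : cap on the candidate set size.
    max_iterations : scan/reselect rounds before giving up.
    bic_penalty_form : "doubled" (-2LL + 2K ln n, the default) or
        "standard" (-2LL + K ln n), K = number of pseudo-QTNs fitted.
    """

    ld_r2_max: float = 0.7
    max_pseudo_qtns: int = 20
    max_iterations: int = 10
    bic_penalty_form: str = "doubled"

    def __post_init__(self) -> None:
        if not 0.0 < self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max must be in (0,1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.bic_penalty_form not in ("doubled", "standard"):
            raise ValueError(f"unknown bic_penalty_form {self.bic_penalty_form!r}")

    def penalty(self, k: int, n: int) -> float:
        base = k * math.log(n)
        return 2.0 * base if self.bic_penalty_form == "doubled" else base


@dataclass
class AssocResult:
    """Final conditioned scan plus the converged pseudo-QTN set."""

    results: pd.DataFrame  # columns chrom, pos, id, effect, stat, p (genome order)
    pseudo_qtns: list = field(default_factory=list)
    pseudo_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_iterations: int = 0
    converged: bool = True

    @property
    def n_snps(self) -> int:
        return len(self.results)


def _align(geno: GenotypeMatrix, pheno: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype vector and matching genotype rows, in phenotype order."""
    if isinstance(pheno, pd.Series):
        pheno = pheno.rename("adjusted_value").rename_axis("id").reset_index()
    idx = pd.Series(np.arange(geno.n_individuals), index=geno.ids)
    unknown = set(pheno["id"]) - set(geno.ids)
    if unknown:
        raise ValueError(f"phenotyped individuals missing from genotypes: {sorted(unknown)[:5]}")
    rows = idx.loc[pheno["id"]].to_numpy()
    return pheno["adjusted_value"].to_numpy(dtype=float), rows


def _conditional_ols(y: np.ndarray, S: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS effect/t/p of each column of S, given covariates C (with intercept)."""
    n = len(y)
    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    RS = S - Q @ (Q.T @ S)
    ss = np.einsum("ij,ij->j", RS, RS)
    sy = RS.T @ ry
    df = n - C.shape[1] - 1
    testable = ss > _VAR_TOL * n
    effect = np.zeros(S.shape[1])
    tstat = np.zeros(S.shape[1])
    pval = np.ones(S.shape[1])
    if df > 0 and testable.any():
        b = sy[testable] / ss[testable]
        rss = (ry @ ry) - b * sy[testable]
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 / ss[testable])
            t = np.where(se > 0, b / se, np.sign(b) * np.inf)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        effect[testable] = b
        tstat[testable] = t
        pval[testable] = p
    return effect, tstat, pval


def single_marker_scan(
    geno: GenotypeMatrix, pheno: pd.DataFrame, covariate_qtns: list | None = None
) -> pd.DataFrame:
    """Per-SNP OLS of the adjusted phenotype on [intercept, pseudo-QTNs, SNP].

    A pseudo-QTN in ``covariate_qtns`` is itself tested against the
    remaining covariates. Monomorphic SNPs and SNPs collinear with the
    covariates get effect 0 and p = 1 (the latter with a logged warning).

    Returns a DataFrame ``chrom, pos, id, effect, stat, p`` in genome order.
    """
    covariate_qtns = list(covariate_qtns or [])
    y, rows = _align(geno, pheno)
    S = geno.dosages[rows]
    n = len(y)
    cov_cols = geno.marker_indices(covariate_qtns) if covariate_qtns else np.array([], dtype=int)
    C_full = np.column_stack([np.ones(n)] + [S[:, c] for c in cov_cols])

    effect, tstat, pval = _conditional_ols(y, S, C_full)
    # covariate SNPs: retest each against the other covariates only
    for k, c in enumerate(cov_cols):
        C_minus = np.delete(C_full, k + 1, axis=1)
        e, t, p = _conditional_ols(y, S[:, [c]], C_minus)
        effect[c], tstat[c], pval[c] = e[0], t[0], p[0]

    collinear = (pval == 1.0) & (np.nanstd(S, axis=0) > _VAR_TOL)
    if covariate_qtns and collinear.any():
        log.warning("%d SNPs collinear with covariates; tests skipped (p=1)", int(collinear.sum()))

    res = geno.snps[["chrom", "pos", "id"]].copy()
    res["effect"] = effect
    res["stat"] = tstat
    res["p"] = pval
    order = np.lexsort((res["pos"].to_numpy(), res["chrom"].to_numpy()))
    return res.iloc[order].reset_index(drop=True)


def _criterion(y: np.ndarray, X: np.ndarray, k: int, cfg: BlinkConfig) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, _VAR_TOL)
    ll = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    return -2.0 * ll + cfg.penalty(k, n)


def select_pseudo_qtns(
    scan: pd.DataFrame,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    cfg: BlinkConfig | None = None,
) -> list:
    """LD-filtered, information-criterion-sized pseudo-QTN list.

    Candidates are SNPs in ascending p-value order (genome order breaking
    ties), greedily retained only if their squared dosage correlation with
    every retained candidate stays below ``cfg.ld_r2_max``, capped at
    ``cfg.max_pseudo_qtns``. The returned list is the candidate prefix whose
    phenotype regression minimizes the information criterion (ties favor
    fewer pseudo-QTNs).
    """
    cfg = cfg or BlinkConfig()
    y, rows = _align(geno, pheno)
    S = geno.dosages[rows]

    order = scan.sort_values(["p", "chrom", "pos"], kind="mergesort")
    candidates: list[int] = []
    cand_ids: list = []
    col_of = pd.Series(np.arange(geno.n_snps), index=geno.snps["id"].to_numpy())
    for _, row in order.iterrows():
        if len(candidates) >= cfg.max_pseudo_qtns:
            break
        c = int(col_of[row["id"]])
        x = S[:, c]
        if np.std(x) <= _VAR_TOL:
            continue
        ok = True
        for kept in candidates:
            r = np.corrcoef(x, S[:, kept])[0, 1]
            if r * r >= cfg.ld_r2_max:
                ok = False
                break
        if ok:
            candidates.append(c)
            cand_ids.append(row["id"])

    best_t, best_crit = 0, math.inf
    for t in range(len(candidates) + 1):
        X = np.column_stack([np.ones(len(y))] + [S[:, c] for c in candidates[:t]])
        crit = _criterion(y, X, t, cfg)
        if crit < best_crit - 1e-12:
            best_crit, best_t = crit, t
    return cand_ids[:best_t]


def blink(
    geno: GenotypeMatrix, pheno: pd.DataFrame, cfg: BlinkConfig | None = None
) -> AssocResult:
    """Iterate scan -> pseudo-QTN selection until the set stabilizes.

    The reported per-SNP statistics come from the final scan conditioned on
    the converged pseudo-QTN set; pseudo-QTN effects are from the joint OLS
    fit of the phenotype on the selected markers.
    """
    cfg = cfg or BlinkConfig()
    qtns: list = []
    scan = single_marker_scan(geno, pheno, qtns)
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iterations + 1):
        new_qtns = select_pseudo_qtns(scan, geno, pheno, cfg)
        if set(new_qtns) == set(qtns):
            converged = True  # no new pseudo-QTNs identified
            break
        qtns = new_qtns
        if n_iter < cfg.max_iterations:
            scan = single_marker_scan(geno, pheno, qtns)

    if qtns:
        y, rows = _align(geno, pheno)
        cols = geno.marker_indices(qtns)
        X = np.column_stack([np.ones(len(y)), geno.dosages[rows][:, cols]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        effects = beta[1:]
    else:
        effects = np.zeros(0)
    return AssocResult(
        results=scan,
        pseudo_qtns=list(qtns),
        pseudo_effects=np.asarray(effects),
        n_iterations=n_iter,
        converged=converged,
    )


def select_top_fraction(assoc: AssocResult, fraction: float) -> list:
    """Ids of the floor(fraction * m) smallest-p markers, in genome order.

    P-value ties are broken by genome position for determinism.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0,1]")
    m = assoc.n_snps
    if m == 0:
        raise ValueError("empty association result")
    k = math.floor(fraction * m)
    if k == 0:
        raise ValueError(f"fraction {fraction} of {m} markers selects none")
    ranked = assoc.results.sort_values(["p", "chrom", "pos"], kind="mergesort").head(k)
    chosen = ranked.sort_values(["chrom", "pos"], kind="mergesort")
    return chosen["id"].tolist()
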