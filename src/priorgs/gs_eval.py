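"""GEBV prediction, cross-validated accuracy, promotion and lettering.

Genomic estimated breeding values (GEBV) solve the repeatability-model
equations at fixed variance ratios; individuals without records receive
predictions through their genomic relationship with recorded individuals.
Accuracy is the Pearson correlation r between validation-fold GEBV and the
per-individual observed phenotype summary, averaged over a 5-fold
individual-level cross-validation. "Promotion" is the percent gain of a
prior-weighted scenario's mean accuracy over the no-prior baseline, and
scenario differences are lettered from a one-way ANOVA + Tukey HSD on the
fold accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .adjust import adjust_phenotypes
from .design import DEFAULT_FACTORS, design_matrix
from .grm import KinshipMatrix
from .varcomp import VCEstimate, fit_repeatability_model

log = logging.getLogger(__name__)

__all__ = [
    "CVReport",
    "predict_gebv",
    "accuracy",
    "cross_validate",
    "promotion",
    "compare_scenarios",
    "run_scenarios",
]


@dataclass
class CVReport:
    """Cross-validation outcome for one kinship scenario."""

    scenario: str
    fold_assignments: pd.Series  # individual -> fold in 1..k
    fold_accuracies: np.ndarray
    mean_accuracy: float
    promotion_pct: float | None = None
    letters: str | None = None
    fold_vcs: list = field(default_factory=list)

    def summary_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "accuracy": round(self.mean_accuracy, 3),
            "promotion": self.promotion_pct,
            "letters": self.letters or "",
        }


def predict_gebv(
    records: pd.DataFrame,
    K: KinshipMatrix,
    fixed_factors: list[str] | None = None,
    vc: VCEstimate | tuple | None = None,
) -> pd.Series:
    """GEBV for every individual in K from the given (training) records.

    ``records`` should contain reference individuals' records only —
    validation individuals are predicted purely through kinship. Solves
    u_hat = sigma2_a K[., train] Z' V^{-1} (y - X b_hat) with V built from
    the training records at the supplied variance components.
    """
    if fixed_factors is None:
        fixed_factors = list(DEFAULT_FACTORS)
    if vc is None:
        raise ValueError("variance components are required (fit them on the training fold)")
    s2a, s2pe, s2e = vc.components() if isinstance(vc, VCEstimate) else tuple(vc)

    records = records.reset_index(drop=True)
    train_ids = pd.unique(records["id"])
    missing = set(train_ids) - set(K.ids)
    if missing:
        raise ValueError(f"individuals absent from kinship: {sorted(map(str, missing))[:5]}")
    Ktt = K.reorder(train_ids)
    pos = {v: i for i, v in enumerate(Ktt.ids)}
    ind_idx = np.array([pos[i] for i in records["id"]])
    n = Ktt.n
    y = records["value"].to_numpy(dtype=float)
    X = design_matrix(records, fixed_factors).to_numpy()
    N = len(y)

    if s2a <= 0:
        return pd.Series(np.zeros(K.n), index=K.ids, name="gebv")

    d = np.bincount(ind_idx, minlength=n).astype(float)
    A = s2a * Ktt.values + s2pe * np.eye(n)
    B = scipy.linalg.solve(s2e * np.eye(n) + A * d[None, :], A)

    def vinv(v):
        zt = np.zeros((n,) + v.shape[1:])
        np.add.at(zt, ind_idx, v)
        return (v - (B @ zt)[ind_idx]) / s2e

    VinvX = vinv(X)
    Vinvy = vinv(y)
    beta = scipy.linalg.solve(X.T @ VinvX, X.T @ Vinvy, assume_a="sym")
    r = Vinvy - VinvX @ beta
    ztr = np.bincount(ind_idx, weights=r, minlength=n)

    full_pos = {v: i for i, v in enumerate(K.ids)}
    train_cols = np.array([full_pos[i] for i in Ktt.ids])
    u_all = s2a * (K.values[:, train_cols] @ ztr)
    return pd.Series(u_all, index=K.ids, name="gebv")


def accuracy(gebv: pd.Series | np.ndarray, pheno: pd.Series | np.ndarray) -> float:
    """Pearson correlation between GEBV and observed phenotype summaries."""
    a = np.asarray(gebv, dtype=float)
    p = np.asarray(pheno, dtype=float)
    if len(a) != len(p):
        raise ValueError("GEBV and phenotype vectors differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired individuals")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, p)[0, 1])


def assign_folds(ids: np.ndarray, k_folds: int, seed: int) -> pd.Series:
    """Balanced random fold assignment (sizes differ by at most one)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k_folds), start=1):
        folds[chunk] = f
    return pd.Series(folds, index=ids, name="fold")


def _comparator_values(records: pd.DataFrame, comparator: str, factors: list[str]) -> pd.Series:
    """Per-individual observed phenotype summary used as the accuracy target."""
    if comparator == "adjusted_mean":
        adj = adjust_phenotypes(records, factors)
        return adj.set_index("id")["adjusted_value"]
    if comparator == "raw_mean":
        return records.groupby("id")["value"].mean()
    if comparator == "first_record":
        return records.groupby("id")["value"].first()
    raise ValueError(f"unknown comparator {comparator!r}")


def cross_validate(
    records: pd.DataFrame,
    K: KinshipMatrix,
    fixed_factors: list[str] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    comparator: str = "adjusted_mean",
    reestimate: bool = True,
    vc: VCEstimate | None = None,
    scenario: str = "All",
    fold_assignments: pd.Series | None = None,
) -> CVReport:
    """K-fold cross-validated prediction accuracy for one kinship.

    Individuals (not records) are randomized to folds; each fold in turn is
    masked, variance components are re-estimated on the remaining reference
    records (unless ``reestimate=False`` with a global ``vc``), the fold's
    GEBV are predicted through kinship, and r is computed against the
    per-individual phenotype summary (adjusted-record mean by default).
    """
    if fixed_factors is None:
        fixed_factors = list(DEFAULT_FACTORS)
    ids = pd.unique(records["id"])
    if len(ids) < k_folds:
        raise ValueError(f"{len(ids)} phenotyped individuals for {k_folds} folds")
    if fold_assignments is None:
        fold_assignments = assign_folds(ids, k_folds, seed)
    target = _comparator_values(records, comparator, fixed_factors)

    rs, fold_vcs = [], []
    start = None
    for f in range(1, k_folds + 1):
        val_ids = fold_assignments.index[fold_assignments == f]
        train = records[~records["id"].isin(set(val_ids))]
        if reestimate or vc is None:
            vcf = fit_repeatability_model(train, K, fixed_factors, start=start)
            start = vcf.components()  # warm start across folds
        else:
            vcf = vc
        fold_vcs.append(vcf)
        gebv = predict_gebv(train, K, fixed_factors, vcf)
        try:
            r = accuracy(gebv.loc[val_ids], target.loc[val_ids])
        except ValueError as err:
            raise ValueError(f"fold {f}: {err}") from err
        rs.append(r)
    rs = np.array(rs)
    return CVReport(
        scenario=scenario,
        fold_assignments=fold_assignments,
        fold_accuracies=rs,
        mean_accuracy=float(rs.mean()),
        fold_vcs=fold_vcs,
    )


def promotion(acc: float, baseline: float) -> float:
    """Percent improvement of a scenario over the no-prior baseline (2 dp)."""
    if baseline <= 0:
        raise ValueError("baseline accuracy must be positive")
    return round(100.0 * (acc - baseline) / baseline, 2)


def compare_scenarios(fold_accuracies: dict, alpha: float = 0.05) -> dict:
    """Compact letter display from ANOVA + Tukey HSD on fold accuracies.

    Scenarios sharing no letter differ significantly at ``alpha``. Letters
    are assigned in descending-mean order; with equal replicate counts the
    Tukey non-significance pattern is contiguous in that order, so maximal
    non-significant runs become the letter groups.
    """
    names = list(fold_accuracies)
    if len(names) == 0:
        raise ValueError("no scenarios to compare")
    if len(names) == 1:
        return {names[0]: "a"}
    sizes = {len(v) for v in fold_accuracies.values()}
    if len(sizes) != 1:
        raise ValueError("scenarios must have equal replicate counts")

    values = np.concatenate([np.asarray(fold_accuracies[s], dtype=float) for s in names])
    groups = np.concatenate([[s] * len(fold_accuracies[s]) for s in names])
    if np.ptp(values) == 0:
        return {s: "a" for s in names}

    tuk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    sig = {}
    for _, row in frame.iterrows():
        key = frozenset((row["group1"], row["group2"]))
        sig[key] = bool(row["reject"])

    order = sorted(names, key=lambda s: -float(np.mean(fold_accuracies[s])))
    runs = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and not sig[frozenset((order[i], order[j + 1]))]:
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters = {s: "" for s in names}
    for letter_idx, (i, j) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx)
        for s in order[i : j + 1]:
            letters[s] += ch
    return letters


def run_scenarios(
    records: pd.DataFrame,
    kinships: dict,
    fixed_factors: list[str] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    baseline: str = "All",
    comparator: str = "adjusted_mean",
    reestimate: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Cross-validate every scenario on identical folds; fill promotion/letters.

    ``kinships`` maps scenario labels (e.g. "All", "Top 5%") to kinship
    matrices; the baseline label's mean accuracy anchors the promotions, so
    differences are paired across scenarios.
    """
    ids = pd.unique(records["id"])
    folds = assign_folds(ids, k_folds, seed)
    reports = {
        label: cross_validate(
            records, K, fixed_factors, k_folds, seed, comparator,
            reestimate=reestimate, scenario=label, fold_assignments=folds,
        )
        for label, K in kinships.items()
    }
    if baseline in reports:
        base = reports[baseline].mean_accuracy
        for label, rep in reports.items():
            rep.promotion_pct = promotion(rep.mean_accuracy, base)
    letters = compare_scenarios({k: v.fold_accuracies for k, v in reports.items()}, alpha)
    for label, rep in reports.items():
        rep.letters = letters[label]
    return reports
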