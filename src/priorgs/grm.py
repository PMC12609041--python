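"""VanRaden genomic relationship matrices and the trait-weighted combination.

``G = Z Z' / (2 * sum_i p_i (1 - p_i))`` with Z the column-centered dosage
matrix (method 1, observed sample allele frequencies). A prior-marker matrix
G1 and a remainder matrix G2 built from disjoint SNP subsets are merged into
the trait-specific kinship

    Gt = omega * G1 + (1 - omega) * G2,
    omega = var_G1 / (var_G1 + var_G2),

where the two variances are the additive genetic variances each subset
captures for the trait. A small identity blend keeps the matrices invertible
for the REML solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "WeightedKinship", "vanraden", "blend", "weight_combine"]


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix over an ordered individual set."""

    ids: np.ndarray
    values: np.ndarray
    kind: str = "all"  # one of all / prior / remainder / weighted
    n_markers_used: int = 0
    blend_beta: float = 0.0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship shape {self.values.shape} for {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids) -> "KinshipMatrix":
        """Submatrix over the given ids, in that order."""
        pos = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"individuals absent from kinship: {missing[:5]}")
        rows = np.array([pos[i] for i in ids])
        return KinshipMatrix(
            np.asarray(list(ids), dtype=object),
            self.values[np.ix_(rows, rows)],
            self.kind,
            self.n_markers_used,
            self.blend_beta,
        )


@dataclass
class WeightedKinship:
    Gt: KinshipMatrix
    omega: float
    var_G1: float
    var_G2: float


def vanraden(geno: GenotypeMatrix, subset=None, kind: str = "all") -> KinshipMatrix:
    """VanRaden method-1 relationship matrix over a marker subset.

    Centering uses the observed allele frequencies of the analyzed sample.
    Monomorphic markers contribute nothing (zero column, zero heterozygosity)
    and are warned about; an all-monomorphic subset is an error because the
    denominator vanishes.
    """
    if subset is not None:
        cols = geno.marker_indices(subset)
        if len(cols) == 0:
            raise ValueError("empty marker subset")
        g = geno.subset_snps(cols)
    else:
        g = geno
    if np.isnan(g.dosages).any():
        raise ValueError("kinship requires a complete (imputed) dosage matrix")
    p = g.allele_freqs()
    het = 2.0 * np.sum(p * (1.0 - p))
    n_mono = int(np.sum((p == 0) | (p == 1)))
    if n_mono:
        log.warning("%d monomorphic markers contribute zero to the kinship", n_mono)
    if het <= 0:
        raise ValueError("all markers in the subset are monomorphic (zero denominator)")
    Z = g.dosages - 2.0 * p
    G = (Z @ Z.T) / het
    G = 0.5 * (G + G.T)
    return KinshipMatrix(g.ids, G, kind=kind, n_markers_used=g.n_snps)


def blend(K: KinshipMatrix, beta: float = 0.01) -> KinshipMatrix:
    """Shrink toward the identity: (1 - beta) K + beta I.

    Standard conditioning step guaranteeing positive definiteness before the
    matrix enters the mixed-model equations.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0,1)")
    if beta == 0.0:
        return K
    V = (1.0 - beta) * K.values + beta * np.eye(K.n)
    return KinshipMatrix(K.ids, V, K.kind, K.n_markers_used, blend_beta=beta)


def weight_combine(
    G1: KinshipMatrix, G2: KinshipMatrix, var_G1: float, var_G2: float
) -> WeightedKinship:
    """Variance-weighted kinship Gt = omega G1 + (1 - omega) G2.

    omega is the prior subset's share of the total additive variance,
    var_G1 / (var_G1 + var_G2).
    """
    if var_G1 < 0 or var_G2 < 0:
        raise ValueError("variances must be nonnegative")
    if var_G1 + var_G2 <= 0:
        raise ValueError("var_G1 + var_G2 must be positive")
    if len(G1.ids) != len(G2.ids) or not (G1.ids == G2.ids).all():
        raise ValueError("G1 and G2 must share the same ordered individuals")
    omega = var_G1 / (var_G1 + var_G2)
    Gt = KinshipMatrix(
        G1.ids,
        omega * G1.values + (1.0 - omega) * G2.values,
        kind="weighted",
        n_markers_used=G1.n_markers_used + G2.n_markers_used,
        blend_beta=max(G1.blend_beta, G2.blend_beta),
    )
    return WeightedKinship(Gt=Gt, omega=omega, var_G1=var_G1, var_G2=var_G2)
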