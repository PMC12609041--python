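"""In-memory genotype container shared by every pipeline stage.

Dosages are stored individuals x SNPs as float64 counts of the A1 allele
(0/1/2), with NaN marking missing calls. Marker metadata (chromosome,
position, alleles) travels alongside in a pandas DataFrame in file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with marker metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_individuals, n_snps)
        A1-allele counts in {0, 1, 2}; NaN encodes a missing call.
    ids : sequence of str
        Individual identifiers, one per row.
    snps : DataFrame
        Marker table with columns ``id, chrom, pos, a1, a2`` in matrix
        column order.
    """

    dosages: np.ndarray
    ids: np.ndarray
    snps: pd.DataFrame
    _freq_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs matrix")
        n, m = self.dosages.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} dosage rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} marker rows for {m} dosage columns")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns: {missing_cols}")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Sample frequency of the counted (A1) allele per SNP.

        Computed over non-missing calls; a fully missing column yields NaN.
        """
        if self._freq_cache is None:
            with np.errstate(invalid="ignore"):
                self._freq_cache = np.nanmean(self.dosages, axis=0) / 2.0
        return self._freq_cache

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def marker_indices(self, marker_ids) -> np.ndarray:
        """Column indices of the given marker ids (order preserved)."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.snps["id"].to_numpy())
        marker_ids = list(marker_ids)
        missing = [m for m in marker_ids if m not in lookup.index]
        if missing:
            raise KeyError(f"unknown marker ids: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return lookup.loc[marker_ids].to_numpy()

    def subset_snps(self, columns: np.ndarray) -> "GenotypeMatrix":
        columns = np.asarray(columns)
        return GenotypeMatrix(
            self.dosages[:, columns],
            self.ids,
            self.snps.iloc[columns].reset_index(drop=True),
        )

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.dosages[rows], self.ids[rows], self.snps.copy()
        )

    def genome_order(self) -> np.ndarray:
        """Column permutation sorting markers by (chromosome, position)."""
        return np.lexsort((self.snps["pos"].to_numpy(), self.snps["chrom"].to_numpy()))
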