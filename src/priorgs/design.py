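"""Reference-coded design matrices for categorical environmental factors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = ["DEFAULT_FACTORS", "design_matrix"]

DEFAULT_FACTORS = ["year", "herd", "sex", "age"]


def design_matrix(records: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Intercept plus drop-first dummy columns for each factor.

    Raises ValueError naming the aliased columns when the factors are
    confounded (rank-deficient after reference coding).
    """
    X = pd.DataFrame({"Intercept": np.ones(len(records))}, index=records.index)
    for f in factors:
        dummies = pd.get_dummies(
            records[f].astype("category"), prefix=f, drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(A.shape[1]) if abs(R[i, i]) <= tol]
        raise ValueError(f"confounded factor columns (rank {rank} < {A.shape[1]}): {bad}")
    return X
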