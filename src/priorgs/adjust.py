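"""Per-individual adjusted phenotypes for use as the GWAS response.

Repeated records are adjusted for categorical environmental factors
(measurement year, herd, sex, age) with a linear mixed model — factors fixed,
individual as a random intercept, fitted by the package's REML engine — and
collapsed to one value per animal. Two exports are available:

``residual_mean`` (default)
    intercept + mean over the individual's records of (value - fitted fixed
    factor effects); shrinkage-free, stays on the observed scale.
``blup``
    intercept + the model's shrunken random-intercept prediction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .design import DEFAULT_FACTORS, design_matrix

log = logging.getLogger(__name__)

__all__ = ["adjust_phenotypes", "DEFAULT_FACTORS"]


def _fit_factor_model(sub: pd.DataFrame, factors: list[str]):
    """GLS fixed-factor estimates under a random individual intercept.

    Returns (beta, Series of shrunken individual effects). Falls back to OLS
    when no individual has a repeated record (the intercept variance is then
    unidentifiable).
    """
    from .varcomp import _RemlWorkspace, _reml_maximize  # deferred: avoids cycle at import

    X = design_matrix(sub, factors).to_numpy()
    y = sub["value"].to_numpy(dtype=float)
    ids = pd.unique(sub["id"])
    pos = {v: i for i, v in enumerate(ids)}
    ind_idx = np.array([pos[i] for i in sub["id"]])

    if np.bincount(ind_idx).max() == 1:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta, pd.Series(np.zeros(len(ids)), index=ids)

    varp = float(np.var(y, ddof=1))
    floor = 1e-10 * varp
    ws = _RemlWorkspace(y, X, ind_idx, [np.eye(len(ids))])
    theta, _, _, converged, _ = _reml_maximize(
        ws, np.array([0.5, 0.5]) * varp, np.array([True, True]), floor
    )
    if not converged:
        log.warning("random-intercept REML did not converge while adjusting phenotypes")
    dec = ws.decompose(theta)
    u = theta[0] * ws._zt(dec["Py"])  # BLUP of the individual intercepts
    return dec["beta"], pd.Series(u, index=ids)


def adjust_phenotypes(
    records: pd.DataFrame,
    factors: list[str] | None = None,
    method: str = "residual_mean",
) -> pd.DataFrame:
    """Collapse repeated records to one adjusted value per (individual, trait).

    Parameters
    ----------
    records : DataFrame
        Long-format records with columns ``id, trait, value`` plus every
        factor named in ``factors``.
    factors : list of str
        Categorical fixed factors to remove; defaults to year, herd, sex, age.
    method : {"residual_mean", "blup"}
        Export form of the per-individual value (see module docstring).

    Returns
    -------
    DataFrame with columns ``id, trait, adjusted_value, n_records_used``.
    """
    if factors is None:
        factors = list(DEFAULT_FACTORS)
    if method not in ("residual_mean", "blup"):
        raise ValueError(f"unknown method {method!r}")
    missing = [f for f in factors if f not in records.columns]
    if missing:
        raise ValueError(f"factors absent from records: {missing}")

    out = []
    for trait, sub in records.groupby("trait", sort=False):
        sub = sub.reset_index(drop=True)
        beta, ranef = _fit_factor_model(sub, factors)
        X = design_matrix(sub, factors)
        intercept = float(beta[0])
        resid = sub["value"].to_numpy(dtype=float) - X.to_numpy() @ beta
        sub = sub.assign(_resid=resid)
        agg = sub.groupby("id", sort=False).agg(
            n_records_used=("_resid", "size"), _rmean=("_resid", "mean")
        )
        if method == "residual_mean":
            adjusted = intercept + agg["_rmean"]
        else:
            adjusted = intercept + ranef.loc[agg.index]
        vals = np.asarray(adjusted, dtype=float)
        log.info(
            "trait %s: adjusted distribution skew=%.3f excess-kurtosis=%.3f",
            trait, stats.skew(vals), stats.kurtosis(vals),
        )
        out.append(
            pd.DataFrame(
                {
                    "id": agg.index,
                    "trait": trait,
                    "adjusted_value": vals,
                    "n_records_used": agg["n_records_used"].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
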