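"""REML variance components for the repeatability animal model.

The model for repeated records is

    y = Xb + Zu + Wp + e,   u ~ N(0, K sigma2_a),  p ~ N(0, I sigma2_pe),
                            e ~ N(0, I sigma2_e),  W = Z,

with X the fixed-factor incidence (herd, year, sex, age), Z mapping records
to individuals and K a genomic relationship matrix. Estimation maximizes the
REML log-likelihood by average-information (AI) updates with multiplicative
EM fallback steps and boundary pinning; standard errors come from the
inverse AI matrix at the optimum.

All linear algebra runs in individual space: with A = sigma2_a K +
sigma2_pe I the phenotypic covariance is V = Z A Z' + sigma2_e I, and the
Woodbury identity V^{-1} = (I - Z B Z') / sigma2_e with
B = (sigma2_e I + A D)^{-1} A, D = Z'Z, reduces every solve to n x n.
Heritability is h2 = sigma2_a / total and repeatability
rep = (sigma2_a + sigma2_pe) / total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .design import DEFAULT_FACTORS, design_matrix
from .grm import KinshipMatrix

log = logging.getLogger(__name__)

__all__ = [
    "VCEstimate",
    "fit_repeatability_model",
    "genetic_parameters",
    "estimate_subset_variances",
]


@dataclass
class VCEstimate:
    """Variance components with derived genetic parameters."""

    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float
    se_a: float
    se_pe: float
    se_e: float
    h2: float
    rep: float
    loglik: float
    converged: bool
    n_iterations: int

    def components(self) -> tuple[float, float, float]:
        return (self.sigma2_a, self.sigma2_pe, self.sigma2_e)


def genetic_parameters(vc) -> tuple[float, float]:
    """(h2, repeatability) from raw components (sigma2_a, sigma2_pe, sigma2_e)."""
    s2a, s2pe, s2e = vc
    if min(s2a, s2pe, s2e) < 0:
        raise ValueError("variance components must be nonnegative")
    total = s2a + s2pe + s2e
    if total <= 0:
        raise ValueError("total variance must be positive")
    return s2a / total, (s2a + s2pe) / total


class _RemlWorkspace:
    """REML quantities for V = Z (sum_k theta_k M_k) Z' + sigma2_e I.

    ``Ms`` are n x n covariance structures of individual-level random
    effects (e.g. [K] or [K, I] or [K1, K2, I]); the last variance parameter
    is always the record-level residual.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, ind_idx: np.ndarray, Ms: list[np.ndarray]):
        self.y = y
        self.X = X
        self.ind_idx = ind_idx
        self.Ms = Ms
        self.N = len(y)
        self.n = Ms[0].shape[0]
        self.f = X.shape[1]
        self.d = np.bincount(ind_idx, minlength=self.n).astype(float)
        self.n_par = len(Ms) + 1

    def _zt(self, v: np.ndarray) -> np.ndarray:
        """Z' v for a record-level vector or matrix."""
        if v.ndim == 1:
            return np.bincount(self.ind_idx, weights=v, minlength=self.n)
        out = np.zeros((self.n, v.shape[1]))
        np.add.at(out, self.ind_idx, v)
        return out

    def decompose(self, theta: np.ndarray) -> dict | None:
        """Factorize V at theta; returns None when V is not usable."""
        *struct, s2e = theta
        if s2e <= 0:
            return None
        A = sum(t * M for t, M in zip(struct, self.Ms))
        Mmat = s2e * np.eye(self.n) + A * self.d[None, :]
        try:
            lu, piv = scipy.linalg.lu_factor(Mmat)
        except scipy.linalg.LinAlgError:
            return None
        diag = np.diag(lu)
        if np.any(diag == 0):
            return None
        logdet_M = float(np.sum(np.log(np.abs(diag))))
        B = scipy.linalg.lu_solve((lu, piv), A)
        B = 0.5 * (B + B.T)
        logdet_V = (self.N - self.n) * math.log(s2e) + logdet_M

        def vinv(v: np.ndarray) -> np.ndarray:
            return (v - (B @ self._zt(v))[self.ind_idx]) / s2e

        VinvX = vinv(self.X)
        C = self.X.T @ VinvX
        try:
            cho = scipy.linalg.cho_factor(C)
        except scipy.linalg.LinAlgError:
            return None
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        Vinvy = vinv(self.y)
        beta = scipy.linalg.cho_solve(cho, self.X.T @ Vinvy)
        Py = Vinvy - VinvX @ beta
        yPy = float(self.y @ Py)
        if not np.isfinite(yPy) or yPy < 0:
            return None
        ll = -0.5 * (logdet_V + logdet_C + yPy + (self.N - self.f) * math.log(2.0 * math.pi))
        if not np.isfinite(ll):
            return None
        return dict(theta=theta, s2e=s2e, B=B, vinv=vinv, VinvX=VinvX, cho=cho,
                    Py=Py, beta=beta, ll=ll)

    def loglik(self, theta: np.ndarray) -> float:
        dec = self.decompose(theta)
        return -math.inf if dec is None else dec["ll"]

    def _proj(self, dec: dict, v: np.ndarray) -> np.ndarray:
        """P v = V^{-1} v - V^{-1} X (X'V^{-1}X)^{-1} X'V^{-1} v."""
        return dec["vinv"](v) - dec["VinvX"] @ scipy.linalg.cho_solve(dec["cho"], dec["VinvX"].T @ v)

    def score_and_ai(self, dec: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Returns (score, AI, trPV, quad) over the n_par parameters."""
        s2e, B, Py, VinvX = dec["s2e"], dec["B"], dec["Py"], dec["VinvX"]
        d = self.d
        T = (np.diag(d) - (d[:, None] * B) * d[None, :]) / s2e  # Z'V^{-1}Z
        U = self._zt(VinvX)  # n x f

        trPV = np.empty(self.n_par)
        quad = np.empty(self.n_par)
        Vi_Py = []
        ZtPy = self._zt(Py)
        for k, M in enumerate(self.Ms):
            tr1 = float(np.sum(M * T))
            S = U.T @ (M @ U)
            tr2 = float(np.trace(scipy.linalg.cho_solve(dec["cho"], S)))
            trPV[k] = tr1 - tr2
            v = (M @ ZtPy)[self.ind_idx]
            Vi_Py.append(v)
            quad[k] = float(Py @ v)
        # residual component
        tr1 = (self.N - float(np.sum(np.diag(B) * d))) / s2e
        tr2 = float(np.trace(scipy.linalg.cho_solve(dec["cho"], VinvX.T @ VinvX)))
        trPV[-1] = tr1 - tr2
        Vi_Py.append(Py)
        quad[-1] = float(Py @ Py)

        score = -0.5 * (trPV - quad)
        P_ViPy = [self._proj(dec, v) for v in Vi_Py]
        AI = np.empty((self.n_par, self.n_par))
        for i in range(self.n_par):
            for j in range(i, self.n_par):
                AI[i, j] = AI[j, i] = 0.5 * float(Vi_Py[i] @ P_ViPy[j])
        return score, AI, trPV, quad


def _reml_maximize(
    ws: _RemlWorkspace,
    theta0: np.ndarray,
    active: np.ndarray,
    floor: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """AI-REML with EM fallback; returns (theta, se, loglik, converged, iters)."""
    theta = theta0.copy()
    theta[~active] = floor
    dec = ws.decompose(theta)
    if dec is None:
        raise RuntimeError(
            "non-finite REML likelihood at the starting values "
            "(singular mixed-model coefficient matrix); try a larger kinship blend beta"
        )
    scale = float(np.mean(theta0[active])) if active.any() else 1.0
    converged = False
    it = 0
    AI_last = None
    for it in range(1, max_iter + 1):
        score, AI, trPV, quad = ws.score_and_ai(dec)
        AI_last = AI
        idx = np.flatnonzero(active)
        # minimum-norm solve: AI can be singular (e.g. two identical kinships)
        step = np.zeros(ws.n_par)
        sol, *_ = np.linalg.lstsq(AI[np.ix_(idx, idx)], score[idx], rcond=1e-10)
        step[idx] = sol

        improved = False
        frac = 1.0
        for _ in range(12):  # step halving keeps the likelihood ascending
            cand = theta + frac * step
            cand[idx] = np.maximum(cand[idx], floor)
            cand[~active] = floor
            dec_new = ws.decompose(cand)
            if dec_new is not None and dec_new["ll"] > dec["ll"] - 1e-12:
                improved = True
                break
            frac *= 0.5
        if not improved:
            # EM-style multiplicative fallback: guaranteed feasible
            cand = theta.copy()
            for k in idx:
                if trPV[k] > 0 and quad[k] > 0:
                    cand[k] = max(theta[k] * quad[k] / trPV[k], floor)
            dec_new = ws.decompose(cand)
            if dec_new is None or dec_new["ll"] < dec["ll"] - 1e-10:
                converged = True  # no ascent direction left
                break

        dll = dec_new["ll"] - dec["ll"]
        dtheta = np.max(np.abs(dec_new["theta"] - theta)) / max(scale, 1e-300)
        theta, dec = dec_new["theta"], dec_new
        if abs(dll) < tol or dtheta < tol:
            converged = True
            break

    se = np.zeros(ws.n_par)
    if AI_last is not None:
        idx = np.flatnonzero(active)
        try:
            cov = scipy.linalg.inv(AI_last[np.ix_(idx, idx)])
            se[idx] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except scipy.linalg.LinAlgError:
            log.warning("AI matrix singular at the optimum; SEs unavailable")
    return theta, se, dec["ll"], converged, it


def _prepare(records: pd.DataFrame, K: KinshipMatrix, fixed_factors: list[str]):
    """Response, design, record->individual map and kinship over recorded ids."""
    records = records.reset_index(drop=True)
    present = pd.unique(records["id"])
    Ksub = K.reorder(present)
    pos = {v: i for i, v in enumerate(Ksub.ids)}
    ind_idx = np.array([pos[i] for i in records["id"]])
    y = records["value"].to_numpy(dtype=float)
    X = design_matrix(records, fixed_factors).to_numpy()
    return y, X, ind_idx, Ksub


def fit_repeatability_model(
    records: pd.DataFrame,
    K: KinshipMatrix,
    fixed_factors: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: tuple[float, float, float] | None = None,
) -> VCEstimate:
    """AI-REML fit of (sigma2_a, sigma2_pe, sigma2_e) with kinship K.

    With no repeated records at all, sigma2_pe is not identifiable and is
    pinned at (effectively) zero with a logged note. Components that hit the
    boundary are pinned at a floor of 1e-10 x phenotypic variance.
    """
    if fixed_factors is None:
        fixed_factors = list(DEFAULT_FACTORS)
    y, X, ind_idx, Ksub = _prepare(records, K, fixed_factors)
    varp = float(np.var(y, ddof=1))
    if varp <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-10 * varp

    n = Ksub.n
    Ms = [Ksub.values, np.eye(n)]
    ws = _RemlWorkspace(y, X, ind_idx, Ms)
    has_repeats = (ws.d >= 2).sum() >= 2
    active = np.array([True, has_repeats, True])
    if not has_repeats:
        log.info("no repeated records: sigma2_pe pinned at 0 (single-record GBLUP)")

    theta0 = np.array(start) if start is not None else np.array([0.3, 0.1, 0.6]) * varp
    theta0 = np.maximum(theta0, floor)
    theta, se, ll, converged, iters = _reml_maximize(ws, theta0, active, floor, max_iter, tol)

    h2, rep = genetic_parameters(theta)
    return VCEstimate(
        sigma2_a=float(theta[0]),
        sigma2_pe=float(theta[1]),
        sigma2_e=float(theta[2]),
        se_a=float(se[0]),
        se_pe=float(se[1]),
        se_e=float(se[2]),
        h2=h2,
        rep=rep,
        loglik=ll,
        converged=converged,
        n_iterations=iters,
    )


def estimate_subset_variances(
    records: pd.DataFrame,
    G1: KinshipMatrix,
    G2: KinshipMatrix,
    fixed_factors: list[str] | None = None,
    mode: str = "separate",
) -> tuple[float, float, dict]:
    """Additive variances captured by the prior (G1) and remainder (G2) sets.

    mode="separate" (default): two independent single-kinship repeatability
    fits; each fit's sigma2_a is that subset's variance. This is the
    arithmetic that feeds the kinship weight omega.
    mode="joint": one model with two additive effects u1 ~ (0, G1 s1) and
    u2 ~ (0, G2 s2) plus permanent environment and residual.
    """
    if fixed_factors is None:
        fixed_factors = list(DEFAULT_FACTORS)
    if mode == "separate":
        fit1 = fit_repeatability_model(records, G1, fixed_factors)
        fit2 = fit_repeatability_model(records, G2, fixed_factors)
        return fit1.sigma2_a, fit2.sigma2_a, {"G1": fit1, "G2": fit2}
    if mode != "joint":
        raise ValueError(f"unknown mode {mode!r}")

    y, X, ind_idx, K1 = _prepare(records, G1, fixed_factors)
    K2 = G2.reorder(K1.ids)
    varp = float(np.var(y, ddof=1))
    floor = 1e-10 * varp
    n = K1.n
    ws = _RemlWorkspace(y, X, ind_idx, [K1.values, K2.values, np.eye(n)])
    has_repeats = (ws.d >= 2).sum() >= 2
    active = np.array([True, True, has_repeats, True])
    theta0 = np.array([0.15, 0.15, 0.1, 0.6]) * varp
    theta, se, ll, converged, iters = _reml_maximize(ws, theta0, active, floor)
    s1, s2, s2pe, s2e = theta
    h2, rep = genetic_parameters((s1 + s2, s2pe, s2e))
    joint = VCEstimate(
        sigma2_a=float(s1 + s2),
        sigma2_pe=float(s2pe),
        sigma2_e=float(s2e),
        se_a=float(np.hypot(se[0], se[1])),
        se_pe=float(se[2]),
        se_e=float(se[3]),
        h2=h2,
        rep=rep,
        loglik=ll,
        converged=converged,
        n_iterations=iters,
    )
    return float(s1), float(s2), {"joint": joint}
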