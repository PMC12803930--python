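"""REML fitting of linear mixed models with a single random intercept.

The per-gene spatial model shares one design across thousands of genes:
``y = X b + u_patient + eps`` with ``u ~ N(0, sigma_u^2)`` per patient and
independent residuals. For this structure V = sigma_e^2 (I + lambda Z Z')
is block-diagonal over patients, and an orthonormal rotation whose first
basis vector within each patient block is the constant vector diagonalizes
it exactly: rotated "between" rows have variance sigma_e^2 (1 + lambda n_i)
and "within" rows have variance sigma_e^2. The rotation depends only on the
grouping, so it is precomputed once and every gene reduces to a cheap 1-d
profiled REML optimization in log lambda followed by weighted least squares.

Degrees of freedom for contrasts use the Satterthwaite approximation:
df = 2 f(theta)^2 / (g' Var(theta) g) with f the contrast variance as a
function of theta = (sigma_u^2, sigma_e^2), g its numerical gradient, and
Var(theta) the inverse observed REML information (numerical Hessian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DataError

_LOGLAM_LO, _LOGLAM_HI = -18.0, 12.0
_SINGULAR_LAM = 1e-6


@dataclass
class MixedFitResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    df_resid: int
    singular: bool
    converged: bool


class PatientBlockLMM:
    """Precomputed REML machinery for one design shared across genes."""

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n <= p:
            raise DataError(f"{n} observations cannot identify {p} fixed effects")
        if np.linalg.matrix_rank(X) < p:
            raise DataError("fixed-effect design is rank-deficient")
        self.n, self.p = n, p
        rot = np.zeros((n, n))
        m_row = np.zeros(n)
        groups = np.asarray(groups)
        row = 0
        self._order = []
        for g in pd_unique(groups):
            idx = np.flatnonzero(groups == g)
            k = idx.size
            Q = _block_rotation(k)
            for j in range(k):
                rot[row + j, idx] = Q[j]
            m_row[row] = k  # first rotated row is the between-patient row
            self._order.extend(idx.tolist())
            row += k
        self.rot = rot
        self.m = m_row
        self.Xr = rot @ X

    # -- profiled REML in lambda ------------------------------------------
    def _wls(self, yr: np.ndarray, v: np.ndarray):
        w = 1.0 / v
        Xw = self.Xr * w[:, None]
        XtWX = self.Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        r = yr - self.Xr @ beta
        rss = float((r * r * w).sum())
        return beta, XtWX, rss

    def _neg2_reml_profiled(self, loglam: float, yr: np.ndarray) -> float:
        lam = np.exp(loglam)
        v = 1.0 + lam * self.m
        beta, XtWX, rss = self._wls(yr, v)
        sign, logdet = np.linalg.slogdet(XtWX)
        return float(np.log(v).sum() + logdet + (self.n - self.p) * np.log(rss))

    def _neg2_reml_theta(self, theta: np.ndarray, yr: np.ndarray) -> float:
        su2, se2 = theta
        if se2 <= 0 or su2 < 0:
            return np.inf
        v = se2 + su2 * self.m
        beta, XtWX, rss = self._wls(yr, v)
        sign, logdet = np.linalg.slogdet(XtWX)
        return float(np.log(v).sum() + logdet + rss)

    def fit(self, y: np.ndarray) -> MixedFitResult:
        yr = self.rot @ np.asarray(y, dtype=float)
        res = optimize.minimize_scalar(
            self._neg2_reml_profiled,
            bounds=(_LOGLAM_LO, _LOGLAM_HI),
            args=(yr,),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        singular = lam < _SINGULAR_LAM
        if singular:
            lam = 0.0
        v = 1.0 + lam * self.m
        beta, XtWX, rss = self._wls(yr, v)
        sigma_e2 = rss / (self.n - self.p)
        cov_beta = sigma_e2 * np.linalg.inv(XtWX)
        return MixedFitResult(
            beta=beta,
            cov_beta=cov_beta,
            sigma_u2=lam * sigma_e2,
            sigma_e2=sigma_e2,
            df_resid=self.n - self.p,
            singular=singular,
            converged=bool(res.success),
        )

    # -- Satterthwaite -----------------------------------------------------
    def _contrast_var(self, theta: np.ndarray, c: np.ndarray) -> float:
        su2, se2 = theta
        v = se2 + su2 * self.m
        w = 1.0 / v
        XtWX = self.Xr.T @ (self.Xr * w[:, None])
        return float(c @ np.linalg.solve(XtWX, c))

    def contrast(self, fit: MixedFitResult, c: np.ndarray, y: np.ndarray):
        """Estimate, SE, Satterthwaite df and p-value for c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ fit.beta)
        var = float(c @ fit.cov_beta @ c)
        se = np.sqrt(var)
        if fit.singular:
            df = float(fit.df_resid)
        else:
            df = self._satterthwaite_df(fit, c, y)
        p = 2.0 * stats.t.sf(abs(est) / se, df) if se > 0 else np.nan
        return est, se, float(df), float(p)

    def _satterthwaite_df(self, fit: MixedFitResult, c: np.ndarray, y: np.ndarray) -> float:
        yr = self.rot @ np.asarray(y, dtype=float)
        theta = np.array([fit.sigma_u2, fit.sigma_e2])
        f0 = self._contrast_var(theta, c)
        # gradient of the contrast variance
        g = np.zeros(2)
        for i in range(2):
            h = max(1e-8, 1e-4 * theta[i])
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] = max(tm[i] - h, 0.0 if i == 0 else 1e-12)
            g[i] = (self._contrast_var(tp, c) - self._contrast_var(tm, c)) / (tp[i] - tm[i])
        # observed REML information (Hessian of 0.5 * neg2loglik)
        H = np.zeros((2, 2))
        hs = [max(1e-7, 1e-4 * theta[i]) for i in range(2)]

        def nll(t):
            return 0.5 * self._neg2_reml_theta(t, yr)

        base = nll(theta)
        for i in range(2):
            for j in range(i, 2):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += hs[i]; tpp[j] += hs[j]
                tpm[i] += hs[i]; tpm[j] -= hs[j]
                tmp[i] -= hs[i]; tmp[j] += hs[j]
                tmm[i] -= hs[i]; tmm[j] -= hs[j]
                if min(tpm[0], tmp[0], tmm[0]) < 0 or min(tpm[1], tmp[1], tmm[1]) <= 0:
                    # one-sided at the boundary
                    if i == j:
                        H[i, j] = (nll(tpp) - 2 * nll(_shift(theta, i, hs[i])) + base) / hs[i] ** 2
                    else:
                        H[i, j] = (
                            nll(tpp) - nll(_shift(theta, i, hs[i])) - nll(_shift(theta, j, hs[j])) + base
                        ) / (hs[i] * hs[j])
                else:
                    H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * hs[i] * hs[j])
                H[j, i] = H[i, j]
        try:
            var_theta = np.linalg.inv(H)
            denom = float(g @ var_theta @ g)
        except np.linalg.LinAlgError:
            denom = np.nan
        if not np.isfinite(denom) or denom <= 0:
            return float(fit.df_resid)  # z-like fallback for degenerate information
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, fit.df_resid))


def _shift(theta: np.ndarray, i: int, h: float) -> np.ndarray:
    t = theta.copy()
    t[i] += h
    return t


def _block_rotation(k: int) -> np.ndarray:
    """Orthonormal k x k matrix whose first row is the constant vector."""
    if k == 1:
        return np.ones((1, 1))
    Q, _ = np.linalg.qr(np.ones((k, 1)), mode="complete")
    if Q[0, 0] < 0:
        Q[:, 0] = -Q[:, 0]
    return Q.T


def pd_unique(values: np.ndarray) -> np.ndarray:
    """First-appearance-order unique values (stable across runs)."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]
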