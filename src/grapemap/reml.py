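"""REML estimation of variance components for small mixed models.

The models used here have one or two crossed random factors (genotype, and
genotype-by-year) on top of arbitrary fixed effects:

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),  e ~ N(0, s2_e I)

The restricted log-likelihood

    -2 l_R = log|V| + log|X' V^-1 X| + (y - Xb)' V^-1 (y - Xb) + const,
    V = s2_e I + sum_k s2_k Z_k Z_k'

is minimized over log-variances with L-BFGS-B (the log scale keeps the
parameters unconstrained; a component collapsing to zero shows up as a large
negative log-variance and is clamped and reported, not an error).  All
V-solves go through the Woodbury identity, so each evaluation costs one
Cholesky in the total random-effect dimension q = sum_k q_k rather than n:
with U = [Z_1 .. Z_K] and L = diag of the per-column variances,

    V^-1 = (I - U B^-1 U') / s2_e,   B = U'U + s2_e L^-1
    log|V| = n log s2_e + log|B| - sum_j log(s2_e / l_j).

BLUPs follow from the mixed-model equations:
u_k = s2_k Z_k' V^-1 (y - X b_hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

__all__ = ["VarianceComponentModel", "RemlResult"]

_BOUNDARY = 1e-12


@dataclass
class RemlResult:
    variances: dict[str, float]  # per random factor, plus "residual"
    fixed_effects: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    boundary: list[str] = field(default_factory=list)


class _WoodburyWorkspace:
    """Cross-products that stay fixed while the variances move."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: list[np.ndarray]):
        self.n, self.p = X.shape
        self.U = np.hstack(Z)
        self.block = np.concatenate(
            [np.full(z.shape[1], k) for k, z in enumerate(Z)]
        )  # factor index per U column
        self.UtU = self.U.T @ self.U
        self.UtX = self.U.T @ X
        self.Uty = self.U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def neg2_reml(self, log_s2: np.ndarray) -> float:
        val = self._core(log_s2)
        return val[0] if val is not None else 1e30

    def _core(self, log_s2: np.ndarray):
        s2 = np.exp(log_s2)
        s2e = s2[-1]
        lam = s2[self.block]  # variance per U column
        B = self.UtU + np.diag(s2e / lam)
        try:
            cB, low = linalg.cho_factor(B, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetB = 2.0 * np.log(np.diag(cB)).sum()
        logdetV = self.n * np.log(s2e) + logdetB - np.log(s2e / lam).sum()
        Bi_UtX = linalg.cho_solve((cB, low), self.UtX, check_finite=False)
        Bi_Uty = linalg.cho_solve((cB, low), self.Uty, check_finite=False)
        XtViX = (self.XtX - self.UtX.T @ Bi_UtX) / s2e
        XtViy = (self.Xty - self.UtX.T @ Bi_Uty) / s2e
        ytViy = (self.yty - self.Uty @ Bi_Uty) / s2e
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return None
        yPy = ytViy - XtViy @ beta
        return float(logdetV + logdetXVX + yPy), beta, (cB, low), s2

    def solve_blups(self, log_s2: np.ndarray, y: np.ndarray, X: np.ndarray, Z: list[np.ndarray]):
        out = self._core(log_s2)
        if out is None:
            raise RuntimeError("REML solution is numerically singular")
        neg2, beta, (cB, low), s2 = out
        s2e = s2[-1]
        r = y - X @ beta
        Utr = self.U.T @ r
        Vi_r_scaled = r - self.U @ linalg.cho_solve((cB, low), Utr, check_finite=False)
        Vi_r = Vi_r_scaled / s2e
        blups = {}
        for k, z in enumerate(Z):
            blups[k] = s2[k] * (z.T @ Vi_r)
        return neg2, beta, blups


class VarianceComponentModel(BaseEstimator):
    """REML fit of a mixed model with independent random factors.

    Parameters
    ----------
    random_names : names of the random factors (order matches the Z list
        passed to :meth:`fit`).
    max_iter : optimizer iteration cap.

    Attributes (after ``fit``)
    --------------------------
    variances_ : dict factor -> variance (includes ``"residual"``)
    fixed_effects_ : GLS estimates of the fixed coefficients
    blups_ : dict factor -> BLUP vector (one entry per factor level)
    loglik_ : restricted log-likelihood at the optimum
    converged_ : bool
    boundary_ : factors whose variance was pinned at (near) zero
    """

    def __init__(self, random_names: tuple[str, ...] = ("genotype",), max_iter: int = 200):
        self.random_names = random_names
        self.max_iter = max_iter

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        Z: list[np.ndarray],
        start: dict[str, float] | None = None,
        fixed_variances: dict[str, float] | None = None,
    ) -> "VarianceComponentModel":
        """Fit by REML.

        ``Z`` is one indicator (or general design) matrix per random factor,
        in the order of ``random_names``.  ``fixed_variances`` skips
        optimization and evaluates GLS/BLUPs at the given components (useful
        for analytic shrinkage checks).
        """
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on n")
        if len(Z) != len(self.random_names):
            raise ValueError("one Z per random factor required")
        Z = [np.asarray(z, dtype=float) for z in Z]
        ws = _WoodburyWorkspace(y, X, Z)

        if fixed_variances is not None:
            s2 = np.array(
                [fixed_variances[nm] for nm in self.random_names] + [fixed_variances["residual"]]
            )
            log_s2 = np.log(np.clip(s2, _BOUNDARY, None))
            converged, n_iter = True, 0
        else:
            vary = float(np.var(y)) or 1.0
            k = len(Z) + 1
            if start is None:
                s0 = np.full(k, vary / k)
            else:
                s0 = np.array([start[nm] for nm in self.random_names] + [start["residual"]])
            x0 = np.log(np.clip(s0, 1e-8, None))
            res = optimize.minimize(
                ws.neg2_reml,
                x0,
                method="L-BFGS-B",
                bounds=[(np.log(_BOUNDARY), np.log(vary * 1e4))] * k,
                options={"maxiter": self.max_iter, "ftol": 1e-14, "gtol": 1e-10},
            )
            polish = optimize.minimize(
                ws.neg2_reml,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 400},
            )
            log_s2 = polish.x if polish.fun <= res.fun else res.x
            converged = bool(res.success or polish.success) or min(res.fun, polish.fun) <= ws.neg2_reml(x0) + 1e-6
            n_iter = int(res.nit + polish.nit)
            if not converged:
                raise RuntimeError(f"REML did not converge: {res.message}")

        neg2, beta, blups = ws.solve_blups(log_s2, y, X, Z)
        s2 = np.exp(log_s2)
        boundary = [
            nm for nm, v in zip(list(self.random_names) + ["residual"], s2) if v <= _BOUNDARY * 10
        ]
        self.variances_ = {nm: float(v) for nm, v in zip(self.random_names, s2[:-1])}
        self.variances_["residual"] = float(s2[-1])
        self.fixed_effects_ = beta
        self.blups_ = {nm: blups[k] for k, nm in enumerate(self.random_names)}
        self.loglik_ = -0.5 * neg2
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.boundary_ = boundary
        if boundary:
            warnings.warn(f"variance component(s) at zero boundary: {boundary}")
        return self

    def result_(self) -> RemlResult:
        return RemlResult(
            variances=dict(self.variances_),
            fixed_effects=self.fixed_effects_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            boundary=list(self.boundary_),
        )
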