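"""Restricted-maximum-likelihood engine for the two study designs.

Model: y = X b + sum_g Z_g u_g + e with u_g ~ N(0, s2_g I) and residuals
e ~ N(0, s2_e C(rho)), where C is block-diagonal AR(1) correlation over
declared observation series (cow x period x day traces) — or the identity
when no serial correlation is requested.

The restricted log-likelihood is evaluated through the Woodbury identity:
with W = C^-1,

    V^-1 = (W - W Z M^-1 Z' W) / s2_e,   M = Z'WZ + s2_e G^-1,

so only Gram matrices of [X y Z] are needed.  For order-based AR(1) the
inverse correlation is tridiagonal with three fixed coefficient patterns,

    W = (S0 - rho * S1 + rho^2 * S2) / (1 - rho^2),

(S0 identity, S1 within-series neighbour adjacency, S2 interior-point
diagonal), so the Grams are precomputed once and every likelihood
evaluation costs O(K^3) with K the number of random-effect levels.  The
continuous-time variant (correlation rho^|dt|) rebuilds the blocked inverse
per evaluation and is kept for unequally spaced schedules.

Optimisation is bounded L-BFGS-B on (log variances, atanh rho) from a fixed
lattice of deterministic restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the best point found."""

    def __init__(self, message: str, best_params=None, best_loglik=None, grad_norm=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_loglik = best_loglik
        self.grad_norm = grad_norm


@dataclass
class REMLResult:
    """Fitted mixed model: GLS fixed effects at the REML variance optimum."""

    beta: np.ndarray
    cov_beta: np.ndarray
    varcomp: dict
    rho: float | None
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    rank_x: int


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class MixedModel:
    """One REML problem: response, design, random groups, residual series.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effects design, full column rank.
    groups : dict name -> (n,) integer level codes, one entry per random
        component (e.g. {'cow': ..., 'day': ...}).
    series : (n,) integer codes of the AR(1) residual series, or None for
        independent residuals.  Observations are ordered within series by
        ``order`` (defaults to input order).
    order : (n,) sort key within series (e.g. sampling time).
    correlation : 'order' (rho^|index gap|, the default) or 'time'
        (rho^|dt| with dt from ``order`` values).
    """

    def __init__(self, y, X, groups=None, series=None, order=None,
                 correlation: str = "order"):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("y must be 1-D and match X rows")
        if correlation not in ("order", "time"):
            raise ValueError("correlation must be 'order' or 'time'")
        self.correlation = correlation
        self.n = y.size
        self.p = X.shape[1]
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("fixed-effects design X is rank deficient")

        groups = groups or {}
        self.group_names = list(groups)
        self.ar1 = series is not None

        # sort observations by (series, order) so blocks are contiguous
        if series is not None:
            series = np.asarray(series)
            key = np.arange(self.n, dtype=float) if order is None else np.asarray(order, float)
            perm = np.lexsort((key, series))
        else:
            perm = np.arange(self.n)
        self.X = X[perm]
        # centring y improves Gram-matrix conditioning; with an intercept
        # column the restricted likelihood is exactly invariant and the
        # intercept estimate is restored after GLS
        self._has_intercept = bool(np.all(X[:, 0] == 1.0))
        self._ybar = float(np.mean(y)) if self._has_intercept else 0.0
        self.y = y[perm] - self._ybar
        self._order_vals = None if order is None else np.asarray(order, float)[perm]

        Zs, self.group_sizes = [], []
        for name in self.group_names:
            codes = np.asarray(groups[name])[perm]
            levels, codes = np.unique(codes, return_inverse=True)
            Zs.append(_one_hot(codes, levels.size))
            self.group_sizes.append(levels.size)
        self.Z = np.hstack(Zs) if Zs else np.zeros((self.n, 0))
        self.K = self.Z.shape[1]
        #: per-column group index into variance components
        self._zgroup = np.repeat(np.arange(len(self.group_sizes)),
                                 self.group_sizes) if self.K else np.array([], int)

        if self.ar1:
            s = np.asarray(series)[perm]
            change = np.flatnonzero(s[1:] != s[:-1]) + 1
            self._block_starts = np.concatenate(([0], change, [self.n]))
            self.n_blocks = self._block_starts.size - 1
        else:
            self.n_blocks = self.n

        self._precompute_grams()
        vy = float(np.var(self.y, ddof=1)) if self.n > 1 else 0.0
        self._vy = vy if vy > 0 else 1.0
        self._degenerate = vy == 0.0

    # -- structure ---------------------------------------------------------

    def _neighbour_apply(self, U: np.ndarray) -> np.ndarray:
        """S1 @ U: within-block sum of the two index neighbours."""
        out = np.zeros_like(U)
        for b in range(self.n_blocks):
            i, j = self._block_starts[b], self._block_starts[b + 1]
            if j - i < 2:
                continue
            blk = U[i:j]
            out[i:j - 1] += blk[1:]
            out[i + 1:j] += blk[:-1]
        return out

    def _interior_mask(self) -> np.ndarray:
        m = np.zeros(self.n)
        for b in range(self.n_blocks):
            i, j = self._block_starts[b], self._block_starts[b + 1]
            if j - i > 2:
                m[i + 1:j - 1] = 1.0
        return m

    def _precompute_grams(self) -> None:
        S = np.hstack([self.X, self.y[:, None], self.Z])
        self._m = S.shape[1]
        self._G0 = S.T @ S
        if self.ar1 and self.correlation == "order":
            self._G1 = S.T @ self._neighbour_apply(S)
            self._G2 = (S * self._interior_mask()[:, None]).T @ S
        else:
            self._G1 = self._G2 = None
        self._S = S if (self.ar1 and self.correlation == "time") else None

    def _weighted_grams(self, rho: float | None):
        """(S' C^-1 S, log|C|) at the given rho."""
        if not self.ar1 or rho is None or rho == 0.0:
            return self._G0, 0.0
        if self.correlation == "order":
            G = (self._G0 - rho * self._G1 + rho**2 * self._G2) / (1.0 - rho**2)
            logdet_c = (self.n - self.n_blocks) * np.log(1.0 - rho**2)
            return G, logdet_c
        # continuous-time: gap-specific correlations r_k = rho^|dt_k|
        S = self._S
        WS = np.zeros_like(S)
        logdet_c = 0.0
        sgn = np.sign(rho)
        for b in range(self.n_blocks):
            i, j = self._block_starts[b], self._block_starts[b + 1]
            m = j - i
            if m == 1:
                WS[i:j] = S[i:j]
                continue
            dt = np.abs(np.diff(self._order_vals[i:j]))
            r = sgn ** dt * np.abs(rho) ** dt if sgn < 0 else np.abs(rho) ** dt
            # AR(1) product-correlation inverse is tridiagonal
            q = 1.0 - r**2
            diag = np.ones(m)
            diag[:-1] += r**2 / q
            diag[1:] += r**2 / q
            off = -r / q
            blk = S[i:j]
            out = diag[:, None] * blk
            out[:-1] += off[:, None] * blk[1:]
            out[1:] += off[:, None] * blk[:-1]
            WS[i:j] = out
            logdet_c += float(np.sum(np.log(q)))
        return S.T @ WS, logdet_c

    # -- restricted likelihood --------------------------------------------

    def loglik(self, variances, rho: float | None = None) -> float:
        """Restricted log-likelihood (constants dropped).

        ``variances`` lists the random-component variances in ``group_names``
        order followed by the residual variance.
        """
        v = np.asarray(variances, float)
        if v.size != len(self.group_sizes) + 1:
            raise ValueError("expected one variance per random group plus residual")
        if np.any(v[:-1] < 0) or v[-1] <= 0:
            return -np.inf
        if rho is not None and not -1 < rho < 1:
            return -np.inf
        s2e = v[-1]
        G, logdet_c = self._weighted_grams(rho)
        p, K = self.p, self.K
        XtWX = G[:p, :p]
        XtWy = G[:p, p]
        ytWy = G[p, p]
        logdet_v = self.n * np.log(s2e) + logdet_c

        if K:
            s2g = np.maximum(v[:-1], 1e-300)[self._zgroup]
            ZtWZ = G[p + 1:, p + 1:]
            ZtWX = G[p + 1:, :p]
            ZtWy = G[p + 1:, p]
            M = ZtWZ + np.diag(s2e / s2g)
            try:
                cM = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet_v += 2.0 * float(np.sum(np.log(np.diag(cM))))
            logdet_v += float(np.sum(np.log(s2g / s2e)))
            MiZtWX = np.linalg.solve(M, ZtWX)
            MiZtWy = np.linalg.solve(M, ZtWy)
            XtVX = (XtWX - ZtWX.T @ MiZtWX) / s2e
            XtVy = (XtWy - ZtWX.T @ MiZtWy) / s2e
            ytVy = (ytWy - ZtWy @ MiZtWy) / s2e
        else:
            XtVX, XtVy, ytVy = XtWX / s2e, XtWy / s2e, ytWy / s2e

        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return -np.inf
        ypy = ytVy - XtVy @ beta
        return float(-0.5 * (logdet_v + logdet_xvx + max(ypy, 0.0)))

    def _gls(self, variances, rho):
        """beta and its covariance at fixed variance parameters."""
        v = np.asarray(variances, float)
        s2e = v[-1]
        G, _ = self._weighted_grams(rho)
        p = self.p
        XtWX, XtWy = G[:p, :p], G[:p, p]
        if self.K:
            s2g = np.maximum(v[:-1], 1e-300)[self._zgroup]
            M = G[p + 1:, p + 1:] + np.diag(s2e / s2g)
            ZtWX, ZtWy = G[p + 1:, :p], G[p + 1:, p]
            MiZtWX = np.linalg.solve(M, ZtWX)
            XtVX = (XtWX - ZtWX.T @ MiZtWX) / s2e
            XtVy = (XtWy - ZtWX.T @ np.linalg.solve(M, ZtWy)) / s2e
        else:
            XtVX, XtVy = XtWX / s2e, XtWy / s2e
        beta = np.linalg.solve(XtVX, XtVy)
        if self._has_intercept:
            beta = beta.copy()
            beta[0] += self._ybar
        return beta, np.linalg.inv(XtVX)

    # -- optimisation ------------------------------------------------------

    def _starts(self):
        vy = self._vy
        ngrp = len(self.group_sizes)
        if self.ar1:
            fracs = [
                ([0.3] * ngrp, 0.0), ([0.3] * ngrp, 0.5),
                ([0.05] * ngrp, 0.0), ([0.6] * ngrp, 0.5),
                ([0.3] * ngrp, -0.3),
            ]
        else:
            fracs = [([0.5] * ngrp, None), ([0.1] * ngrp, None), ([0.8] * ngrp, None)]
        starts = []
        for gf, rho in fracs:
            gsum = sum(gf)
            resid = max(1.0 - gsum, 0.1)
            v = [max(f, 1e-4) * vy for f in gf] + [resid * vy]
            x = list(np.log(v))
            if self.ar1:
                x.append(np.arctanh(rho))
            starts.append(np.array(x))
        return starts

    def fit(self, maxiter: int = 300) -> REMLResult:
        """REML fit with deterministic multi-start L-BFGS-B."""
        ngrp = len(self.group_sizes)
        if self._degenerate:
            # constant response: variances at zero, OLS fixed effects
            beta, _ = self._gls([0.0] * ngrp + [1.0], None)
            vc = {name: 0.0 for name in self.group_names}
            vc["residual"] = 0.0
            return REMLResult(beta=beta, cov_beta=np.zeros((self.p, self.p)),
                              varcomp=vc, rho=0.0 if self.ar1 else None,
                              loglik=np.nan, converged=True, boundary=True,
                              n_obs=self.n, rank_x=self.p)

        vy = self._vy
        lo, hi = np.log(vy * 1e-8), np.log(vy * 1e4)
        zmax = np.arctanh(0.98)
        bounds = [(lo, hi)] * (ngrp + 1)
        if self.ar1:
            bounds.append((-zmax, zmax))

        def unpack(x):
            v = np.exp(x[:ngrp + 1])
            rho = float(np.tanh(x[ngrp + 1])) if self.ar1 else None
            return v, rho

        def nll(x):
            v, rho = unpack(x)
            ll = self.loglik(v, rho)
            return -ll if np.isfinite(ll) else 1e12

        best = None
        any_success = False
        for x0 in self._starts():
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
            any_success = any_success or bool(res.success)

        gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
        v, rho = unpack(best.x)
        ll = -best.fun
        if not any_success and gnorm > 1e-2 * (1.0 + abs(ll)):
            raise ConvergenceError(
                f"REML optimisation did not converge (projected gradient {gnorm:.3g})",
                best_params=(v, rho), best_loglik=ll, grad_norm=gnorm)

        boundary = bool(
            np.any(np.abs(best.x[:ngrp + 1] - lo) < 1e-6)
            or np.any(np.abs(best.x[:ngrp + 1] - hi) < 1e-6)
            or (self.ar1 and abs(abs(best.x[ngrp + 1]) - zmax) < 1e-6)
        )
        beta, cov = self._gls(v, rho)
        vc = {name: float(v[i]) for i, name in enumerate(self.group_names)}
        # variances indistinguishable from the floor report as zero
        for name in vc:
            if vc[name] <= vy * 2e-8:
                vc[name] = 0.0
        vc["residual"] = float(v[-1])
        return REMLResult(beta=beta, cov_beta=cov, varcomp=vc, rho=rho,
                          loglik=ll, converged=any_success, boundary=boundary,
                          n_obs=self.n, rank_x=self.p)
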