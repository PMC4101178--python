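"""REML estimation for linear mixed models with independent variance components.

The model is

    y = X beta + sum_i Z_i u_i + e,   u_i ~ N(0, sigma2_i I),  e ~ N(0, sigma2_e I)

which covers every layout of the two-step trial analysis: replication and
block effects within an environment (step 1), and environment plus
genotype-by-environment effects across environments (step 2), with genotype
either fixed (BLUEs) or random (variance components).

Estimation maximizes the restricted likelihood on error contrasts
K'y with K an orthonormal basis of the null space of X', using
average-information (AI) updates with EM fallback steps whenever an AI
proposal leaves the parameter space or decreases the restricted
log-likelihood.  Negative proposals are clamped to the zero boundary and
flagged.  Convergence: relative change of the restricted log-likelihood
below ``rtol`` (default 1e-8), at most ``maxiter`` (default 200) iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _as_design(z, n: int) -> np.ndarray:
    """Coerce a random term to an n x q indicator/design matrix.

    1-D input is interpreted as a factor (level labels); 2-D input is used
    as the design matrix itself.
    """
    if isinstance(z, pd.Series):
        z = z.to_numpy()
    z = np.asarray(z)
    if z.ndim == 1:
        if len(z) != n:
            raise ValueError("factor length does not match data")
        levels, codes = np.unique(z, return_inverse=True)
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), codes] = 1.0
        return Z
    Z = z.astype(float)
    if Z.shape[0] != n:
        raise ValueError("design rows do not match data")
    return Z


@dataclass
class VarianceComponentsResults:
    """Fitted REML estimates: fixed-effect GLS solutions, variance
    components, BLUPs and the optimizer trace."""

    model: "VarianceComponentsModel"
    fe_params: np.ndarray
    cov_fe_params: np.ndarray
    vcomp: dict[str, float]
    llf: float
    trace: list[float]
    n_iter: int
    converged: bool
    pinned: set[str] = field(default_factory=set)
    _blups: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.fe_params

    def blup(self, name: str) -> np.ndarray:
        return self._blups[name]

    def summary(self) -> str:
        lines = ["Variance-components REML fit",
                 "=" * 38,
                 f"n obs: {self.model.nobs}   fixed params: {len(self.fe_params)}",
                 f"restricted loglik: {self.llf:.6f}   iterations: {self.n_iter}"
                 f"   converged: {self.converged}",
                 "-" * 38,
                 "variance components:"]
        for k, v in self.vcomp.items():
            flag = "  (at zero boundary)" if k in self.pinned else ""
            lines.append(f"  {k:<20s} {v:12.6g}{flag}")
        se = np.sqrt(np.diag(self.cov_fe_params))
        lines.append("-" * 38)
        lines.append("fixed effects (first 10):")
        for i, (b, s) in enumerate(zip(self.fe_params[:10], se[:10])):
            lines.append(f"  beta[{i}] {b:12.6g}  se {s:.6g}")
        return "\n".join(lines)


class VarianceComponentsModel:
    """Linear mixed model with iid random effects per term.

    Parameters
    ----------
    endog : array-like, length n
    exog : array-like (n x p) or None
        Fixed-effect design; ``None`` means intercept only.
    vc : dict
        Random terms: name -> either a factor (1-D labels) or an explicit
        n x q design matrix.  Each term gets one variance component; the
        residual component is always included.
    """

    def __init__(self, endog, exog=None, vc: dict | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        n = len(self.endog)
        if np.isnan(self.endog).any():
            raise ValueError("endog contains missing values")
        if exog is None:
            exog = np.ones((n, 1))
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if self.exog.shape[0] != n:
            raise ValueError("exog rows do not match endog")
        self.vc_names = list((vc or {}).keys())
        self.vc_designs = {k: _as_design(z, n) for k, z in (vc or {}).items()}
        for k, Z in self.vc_designs.items():
            if Z.shape[1] < 2:
                raise ValueError(f"random term {k!r} has fewer than 2 levels")
        self.nobs = n

    # -- restricted likelihood machinery on error contrasts ---------------

    def _contrasts(self):
        X = self.exog
        n = self.nobs
        q, r, _ = sla.qr(X, mode="full", pivoting=True)
        tol = np.abs(r).max() * max(X.shape) * np.finfo(float).eps if r.size else 0.0
        rank = int((np.abs(np.diag(r)) > tol).sum()) if r.size else 0
        K = q[:, rank:]
        return K, rank

    def fit(self, start: dict | None = None, maxiter: int = 200,
            rtol: float = 1e-8) -> VarianceComponentsResults:
        y = self.endog
        K, rank = self._contrasts()
        m = K.shape[1]
        if m == 0:
            raise ValueError("model saturated: no error contrasts remain")
        yk = K.T @ y
        names = self.vc_names
        A = [ (K.T @ self.vc_designs[k]) for k in names ]
        A = [Mi @ Mi.T for Mi in A]
        qdims = [self.vc_designs[k].shape[1] for k in names]

        total = float(yk @ yk) / m
        if total <= 0.0:
            # degenerate data: all variation removed by the fixed effects
            return self._finalize(dict.fromkeys(names, 0.0), 0.0,
                                  trace=[0.0], n_iter=0, converged=True)

        floor = 1e-10 * total
        k = len(names)
        theta = np.full(k + 1, total / (k + 1))  # [components..., residual]

        def build(th):
            V = th[-1] * np.eye(m)
            for t, Ai in zip(th[:k], A):
                if t > 0:
                    V += t * Ai
            return V

        def loglik(th):
            V = build(th)
            c, low = sla.cho_factor(V, lower=True)
            u = sla.cho_solve((c, low), yk)
            ll = -0.5 * (2.0 * np.sum(np.log(np.diag(c))) + yk @ u)
            return ll, (c, low), u

        ll, chol, u = loglik(theta)
        trace = [ll]
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            Vinv = sla.cho_solve(chol, np.eye(m))
            s = [Ai @ u for Ai in A] + [u]
            tr = [float(np.einsum("ij,ji->", Vinv, Ai)) for Ai in A] + [float(np.trace(Vinv))]
            score = np.array([-0.5 * (tr[i] - u @ s[i]) for i in range(k + 1)])
            S = np.column_stack(s) if s else np.empty((m, 0))
            VS = Vinv @ S
            AI = 0.5 * (S.T @ VS)
            AI += 1e-10 * np.eye(k + 1) * max(1.0, np.trace(AI))

            accepted = False

            def try_ai(active: np.ndarray):
                """AI step restricted to the active components (others
                pinned at zero); step-halving; returns accepted proposal."""
                idx = np.flatnonzero(active)
                if len(idx) == 0:
                    return None
                try:
                    delta = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
                except np.linalg.LinAlgError:
                    return None
                step = 1.0
                for _ in range(6):
                    prop = np.where(active, theta, 0.0)
                    prop[idx] = theta[idx] + step * delta
                    clipped = prop[:k] < 0
                    prop[:k] = np.maximum(prop[:k], 0.0)
                    prop[-1] = max(prop[-1], floor)
                    try:
                        out = loglik(prop)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if out[0] >= ll - 1e-12 * (1.0 + abs(ll)):
                        return prop, out, clipped
                    step *= 0.5
                return None

            active = np.ones(k + 1, dtype=bool)
            active[:k] = (theta[:k] > 0) | (score[:k] > 0)
            fallback = None
            for _ in range(k + 1):
                res = try_ai(active)
                if res is None:
                    break
                prop, (ll_new, chol_new, u_new), clipped = res
                if not clipped.any():
                    accepted = True
                    break
                # a component was driven negative: remember the clamped
                # proposal, pin the component at zero and re-solve the AI
                # system for the remaining ones
                fallback = (prop, (ll_new, chol_new, u_new))
                active[:k] &= ~clipped
            if not accepted and fallback is not None:
                prop, (ll_new, chol_new, u_new) = fallback
                accepted = True
            if not accepted:
                # EM fallback: monotone in the restricted likelihood
                prop = theta.copy()
                for i in range(k):
                    if theta[i] > 0:
                        prop[i] = theta[i] + theta[i] ** 2 * (u @ s[i] - tr[i]) / qdims[i]
                prop[-1] = theta[-1] + theta[-1] ** 2 * (u @ u - tr[-1]) / m
                prop[:k] = np.maximum(prop[:k], 0.0)
                prop[-1] = max(prop[-1], floor)
                ll_new, chol_new, u_new = loglik(prop)

            done = abs(ll_new - ll) <= rtol * (1.0 + abs(ll))
            theta, ll, chol, u = prop, ll_new, chol_new, u_new
            trace.append(ll)
            if done:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {maxiter} iterations", trace)

        vcomp = {nm: float(max(t, 0.0)) for nm, t in zip(names, theta[:k])}
        resid = float(theta[-1] if theta[-1] > floor * 2 else 0.0)
        return self._finalize(vcomp, resid, trace=trace, n_iter=it, converged=True)

    def _finalize(self, vcomp: dict, resid: float, trace, n_iter,
                  converged) -> VarianceComponentsResults:
        n = self.nobs
        X = self.exog
        y = self.endog
        Vfull = resid * np.eye(n)
        for nm in self.vc_names:
            t = vcomp[nm]
            if t > 0:
                Z = self.vc_designs[nm]
                Vfull += t * (Z @ Z.T)
        if resid <= 0 and all(v <= 0 for v in vcomp.values()):
            Vfull = np.eye(n)  # degenerate: OLS
        c, low = sla.cho_factor(Vfull, lower=True)
        ViX = sla.cho_solve((c, low), X)
        Viy = sla.cho_solve((c, low), y)
        XtViX = X.T @ ViX
        beta, *_ = np.linalg.lstsq(XtViX, X.T @ Viy, rcond=None)
        cov = np.linalg.pinv(XtViX)
        r = y - X @ beta
        Vir = sla.cho_solve((c, low), r)
        blups = {}
        for nm in self.vc_names:
            t = vcomp[nm]
            blups[nm] = t * (self.vc_designs[nm].T @ Vir) if t > 0 else \
                np.zeros(self.vc_designs[nm].shape[1])
        out = dict(vcomp)
        out["residual"] = resid
        pinned = {nm for nm, v in out.items() if v == 0.0}
        return VarianceComponentsResults(
            model=self, fe_params=beta, cov_fe_params=cov, vcomp=out,
            llf=trace[-1], trace=list(trace), n_iter=n_iter,
            converged=converged, pinned=pinned, _blups=blups)
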