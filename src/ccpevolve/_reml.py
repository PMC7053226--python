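"""Small REML engine for variance-component mixed models.

Fits y = X beta + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k I) by profiled
REML over the variance ratios gamma_k = sigma2_k/sigma2_e, using the
Woodbury identity so every solve is q x q (q = total random levels).
Denominator degrees of freedom for contrasts use the Satterthwaite
approximation: df = 2 Var(c'beta)^2 / Var_hat(Var(c'beta)), with the
gradient of Var(c'beta) w.r.t. the variance parameters taken numerically
and the variance-parameter covariance from the numerical REML Hessian.

Components whose fitted ratio collapses (gamma < 1e-6) are dropped and the
model refit -- the singular-fit fallback; dropped names are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_GAMMA_FLOOR = 1e-6


@dataclass
class MixedFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: dict[str, float]          # per-component variances + "residual"
    reml_neg2loglik: float
    n: int
    p: int
    dropped: list[str] = field(default_factory=list)
    _state: dict = field(default_factory=dict, repr=False)

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """(estimate, se, Satterthwaite df) for the linear contrast c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        df = _satterthwaite_df(self, c, var)
        return est, float(np.sqrt(max(var, 0.0))), df

    def f_test(self, c: np.ndarray) -> tuple[float, float, float]:
        """Single-contrast F test: (F, denominator df, p-value)."""
        est, se, df = self.contrast(c)
        if se == 0.0:
            return (np.inf, df, 0.0) if est != 0.0 else (0.0, df, 1.0)
        f = (est / se) ** 2
        return float(f), df, float(stats.f.sf(f, 1, df))


def _design(X, z_blocks):
    U = np.hstack(list(z_blocks.values())) if z_blocks else np.zeros((X.shape[0], 0))
    sizes = [z.shape[1] for z in z_blocks.values()]
    return U, sizes


def _profiled_pieces(gamma, sizes, UtU, UtX, Uty, XtX, Xty, yty, n, p):
    """Return (neg2reml, sigma2_e, beta, A) at the given variance ratios."""
    g = np.repeat(gamma, sizes)
    if g.size:
        sq = np.sqrt(g)
        K = np.eye(g.size) + (sq[:, None] * UtU * sq[None, :])
        cf = np.linalg.cholesky(K)
        logdetK = 2.0 * np.sum(np.log(np.diag(cf)))
        W = sq[:, None] * UtX          # (q, p)
        wy = sq * Uty
        KiW = np.linalg.solve(K, W)
        Kiwy = np.linalg.solve(K, wy)
        A = XtX - W.T @ KiW
        Xvy = Xty - W.T @ Kiwy
        yvy = yty - wy @ Kiwy
    else:
        logdetK = 0.0
        A = XtX
        Xvy = Xty
        yvy = yty
    Ac = np.linalg.cholesky(A)
    logdetA = 2.0 * np.sum(np.log(np.diag(Ac)))
    beta = np.linalg.solve(A, Xvy)
    rvr = max(yvy - beta @ Xvy, 1e-300)
    sigma2_e = rvr / (n - p)
    neg2 = (n - p) * np.log(sigma2_e) + logdetK + logdetA
    return neg2, sigma2_e, beta, A


def fit_reml(y: np.ndarray, X: np.ndarray,
             random_effects: dict[str, np.ndarray]) -> MixedFit:
    """REML fit; ``random_effects`` maps component name -> indicator matrix."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")
    names = list(random_effects)
    dropped: list[str] = []
    while True:
        blocks = {k: random_effects[k] for k in names}
        U, sizes = _design(X, blocks)
        UtU = U.T @ U
        UtX = U.T @ X
        Uty = U.T @ y
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)
        k = len(names)

        def obj(logg):
            try:
                val, *_ = _profiled_pieces(np.exp(logg), sizes, UtU, UtX, Uty,
                                           XtX, Xty, yty, n, p)
            except np.linalg.LinAlgError:
                return 1e12
            return val

        if k:
            best = None
            for start in (np.zeros(k), np.full(k, np.log(0.05))):
                res = optimize.minimize(obj, start, method="L-BFGS-B",
                                        bounds=[(-25.0, 12.0)] * k)
                if best is None or res.fun < best.fun:
                    best = res
            gamma = np.exp(best.x)
            small = [names[i] for i in range(k) if gamma[i] < _GAMMA_FLOOR]
            if small:
                dropped.extend(small)
                names = [nm for nm in names if nm not in small]
                continue
        else:
            gamma = np.zeros(0)
        neg2, s2e, beta, A = _profiled_pieces(gamma, sizes, UtU, UtX, Uty,
                                              XtX, Xty, yty, n, p)
        sigma2 = {nm: float(g * s2e) for nm, g in zip(names, gamma)}
        sigma2["residual"] = float(s2e)
        cov_beta = s2e * np.linalg.inv(A)
        state = {"X": X, "y": y, "blocks": blocks, "sizes": sizes,
                 "UtU": UtU, "UtX": UtX, "Uty": Uty, "XtX": XtX,
                 "Xty": Xty, "yty": yty, "names": names}
        return MixedFit(beta=beta, cov_beta=cov_beta, sigma2=sigma2,
                        reml_neg2loglik=float(neg2), n=n, p=p,
                        dropped=dropped, _state=state)


def _var_cb(fit: MixedFit, c: np.ndarray, theta: np.ndarray) -> float:
    """Var(c'beta) as a function of theta = (sigma2_1..k, sigma2_e)."""
    st = fit._state
    s2e = theta[-1]
    gamma = theta[:-1] / s2e
    _, _, _, A = _profiled_pieces(
        np.maximum(gamma, 0.0), st["sizes"], st["UtU"], st["UtX"], st["Uty"],
        st["XtX"], st["Xty"], st["yty"], fit.n, fit.p,
    )
    return float(s2e * (c @ np.linalg.solve(A, c)))


def _reml_neg2_theta(fit: MixedFit, theta: np.ndarray) -> float:
    st = fit._state
    s2e = theta[-1]
    gamma = np.maximum(theta[:-1] / s2e, 0.0)
    neg2_prof, s2_prof, _, A = _profiled_pieces(
        gamma, st["sizes"], st["UtU"], st["UtX"], st["Uty"],
        st["XtX"], st["Xty"], st["yty"], fit.n, fit.p,
    )
    # undo the profiling of sigma2_e: plug the supplied value back in
    n, p = fit.n, fit.p
    rvr = s2_prof * (n - p)
    logdets = neg2_prof - (n - p) * np.log(s2_prof)
    return logdets + (n - p) * np.log(s2e) + rvr / s2e - (n - p)


def _satterthwaite_df(fit: MixedFit, c: np.ndarray, var: float) -> float:
    names = fit._state["names"]
    theta = np.array([fit.sigma2[nm] for nm in names] + [fit.sigma2["residual"]])
    fallback = float(fit.n - fit.p)
    if var <= 0 or theta[-1] <= 0:
        return fallback
    if not names:
        return fallback
    h = np.maximum(1e-10, 1e-4 * theta)
    grad = np.zeros_like(theta)
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], 1e-12)
        grad[i] = (_var_cb(fit, c, tp) - _var_cb(fit, c, tm)) / (tp[i] - tm[i])
    dim = len(theta)
    H = np.zeros((dim, dim))
    f0 = _reml_neg2_theta(fit, theta)
    for i in range(dim):
        for j in range(i, dim):
            ti = theta.copy(); ti[i] += h[i]; ti[j] += h[j]
            tj = theta.copy(); tj[i] += h[i]; tj[j] = max(tj[j] - h[j], 1e-12)
            tk = theta.copy(); tk[i] = max(tk[i] - h[i], 1e-12); tk[j] += h[j]
            tl = theta.copy()
            tl[i] = max(tl[i] - h[i], 1e-12); tl[j] = max(tl[j] - h[j], 1e-12)
            num = (_reml_neg2_theta(fit, ti) - _reml_neg2_theta(fit, tj)
                   - _reml_neg2_theta(fit, tk) + _reml_neg2_theta(fit, tl))
            step = (ti[i] - tk[i]) * (ti[j] - tj[j])
            H[i, j] = H[j, i] = num / step
    try:
        cov_theta = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return fallback
    denom = float(grad @ cov_theta @ grad)
    if denom <= 0:
        return fallback
    df = 2.0 * var * var / denom
    if not np.isfinite(df) or df < 1.0:
        return fallback
    return float(min(df, fallback))
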