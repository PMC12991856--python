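"""Linear mixed models with crossed random intercepts, fitted by REML.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma^2 I)

with a small number of crossed grouping factors (site, forest type,
management; q = total number of levels is at most a few dozen).  The REML
criterion is profiled over the residual variance and optimized over the
log variance ratios gamma_k = sigma_k^2 / sigma^2.  All per-evaluation
linear algebra is reduced to q x q problems via the Woodbury identity, so a
single fit costs a few milliseconds — this is the hot loop of the SEM
bootstrap, which refits every node model in every replicate.

Fixed-effect inference uses t statistics with n - p residual degrees of
freedom (a Satterthwaite approximation is deliberately not used; see the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedLMResult", "fit_mixed_lm"]


@dataclass
class MixedLMResult:
    """REML fit of a variance-components linear mixed model."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    vc: dict[str, float]
    resid_var: float
    reml_criterion: float
    marginal_r2: float
    dropped_groups: list[str] = field(default_factory=list)
    converged: bool = True

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def _factor_codes(values) -> np.ndarray:
    """Integer codes 0..L-1 for a 1-d array of group labels."""
    _, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes.astype(np.intp)


def _design_matrices(groups: dict[str, np.ndarray], n: int):
    """Indicator matrix Z (n x q) and the per-factor column blocks."""
    blocks = []
    cols = []
    start = 0
    for name, values in groups.items():
        codes = _factor_codes(values)
        if len(codes) != n:
            raise ValueError(f"grouping factor {name!r} has wrong length")
        L = codes.max() + 1
        Zk = np.zeros((n, L))
        Zk[np.arange(n), codes] = 1.0
        blocks.append(Zk)
        cols.append((name, start, start + L))
        start += L
    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return Z, cols


class _REMLProblem:
    """Precomputed cross-products for fast REML evaluations."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray, cols):
        self.n, self.p = X.shape
        self.cols = cols
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.q = Z.shape[1]

    def _gamma_vector(self, log_gamma: np.ndarray) -> np.ndarray:
        g = np.empty(self.q)
        for (name, a, b), lg in zip(self.cols, log_gamma):
            g[a:b] = np.exp(lg)
        return g

    def solve(self, log_gamma: np.ndarray):
        """GLS quantities under H = I + Z diag(g) Z'.

        Returns (criterion, beta, XtHiX, sigma2_hat, logdetH).
        """
        n, p = self.n, self.p
        if self.q:
            g = self._gamma_vector(log_gamma)
            s = np.sqrt(g)
            M = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
            L = np.linalg.cholesky(M)
            logdetH = 2.0 * float(np.log(np.diag(L)).sum())
            # W = M^{-1} applied to scaled cross-products
            sZtX = s[:, None] * self.ZtX
            sZty = s * self.Zty
            A = np.linalg.solve(L, np.hstack([sZtX, sZty[:, None]]))
            XtHiX = self.XtX - A[:, :p].T @ A[:, :p]
            XtHiy = self.Xty - A[:, :p].T @ A[:, p]
            ytHiy = self.yty - float(A[:, p] @ A[:, p])
        else:
            logdetH = 0.0
            XtHiX, XtHiy, ytHiy = self.XtX, self.Xty, self.yty
        Lx = np.linalg.cholesky(XtHiX)
        beta = np.linalg.solve(Lx.T, np.linalg.solve(Lx, XtHiy))
        logdetXtHiX = 2.0 * float(np.log(np.diag(Lx)).sum())
        rss = max(ytHiy - float(beta @ XtHiy), 1e-300)
        sigma2 = rss / (n - p)
        crit = (n - p) * np.log(sigma2) + logdetH + logdetXtHiX
        return crit, beta, XtHiX, sigma2, logdetH

    def solve_with_grad(self, log_gamma: np.ndarray):
        """Criterion and its exact gradient w.r.t. log gamma.

        d crit / d gamma_k = tr(Z_k' H^-1 Z_k)
                             - (n-p) ||Z_k' H^-1 r||^2 / (r' H^-1 r)
                             - tr[(X'H^-1X)^-1 (X'H^-1 Z_k)(Z_k'H^-1 X)],
        scaled by gamma_k for the log parameterization (the GLS beta and
        profiled sigma^2 drop out by first-order optimality).
        """
        n, p, q = self.n, self.p, self.q
        g = self._gamma_vector(log_gamma)
        s = np.sqrt(g)
        M = np.eye(q) + (s[:, None] * self.ZtZ) * s[None, :]
        L = np.linalg.cholesky(M)
        logdetH = 2.0 * float(np.log(np.diag(L)).sum())
        sZtX = s[:, None] * self.ZtX
        sZty = s * self.Zty
        A = np.linalg.solve(L, np.hstack([sZtX, sZty[:, None]]))
        XtHiX = self.XtX - A[:, :p].T @ A[:, :p]
        XtHiy = self.Xty - A[:, :p].T @ A[:, p]
        ytHiy = self.yty - float(A[:, p] @ A[:, p])
        Lx = np.linalg.cholesky(XtHiX)
        beta = np.linalg.solve(Lx.T, np.linalg.solve(Lx, XtHiy))
        logdetXtHiX = 2.0 * float(np.log(np.diag(Lx)).sum())
        rss = max(ytHiy - float(beta @ XtHiy), 1e-300)
        crit = (n - p) * np.log(rss / (n - p)) + logdetH + logdetXtHiX

        # Z' H^-1 [Z X y] via the same Woodbury pieces
        C = np.linalg.solve(L, s[:, None] * self.ZtZ)  # q x q
        ZtHiZ = self.ZtZ - C.T @ C
        ZtHiX = self.ZtX - C.T @ A[:, :p]
        ZtHiy = self.Zty - C.T @ A[:, p]
        u = ZtHiy - ZtHiX @ beta  # Z' H^-1 r
        # (X'H^-1X)^-1 (X'H^-1 Z) without explicit inverse
        V = np.linalg.solve(Lx, ZtHiX.T)  # p x q, Lx^-1 X'H^-1Z

        grad = np.empty(len(self.cols))
        for k, (_, a, b) in enumerate(self.cols):
            tr_HiZZ = float(np.trace(ZtHiZ[a:b, a:b]))
            quad = float(u[a:b] @ u[a:b])
            tr_X = float((V[:, a:b] ** 2).sum())
            dgamma = tr_HiZZ - (n - p) * quad / rss - tr_X
            grad[k] = dgamma * g[a]  # gamma_k, constant within the block
        return crit, grad


def fit_mixed_lm(
    y,
    X,
    groups: dict[str, np.ndarray] | None,
    names: list[str] | None = None,
) -> MixedLMResult:
    """Fit y = X beta + crossed random intercepts + noise by REML.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effects design (n, p); `X` should
        already contain an intercept column if one is wanted.
    groups
        Mapping factor name -> length-n array of group labels.  Factors
        with fewer than 2 observed levels are dropped (their variance is
        not identifiable) and recorded in ``dropped_groups``.
    names
        Column names for the fixed effects (defaults to x0..x{p-1}).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError("need n > p observations for REML")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    groups = dict(groups or {})
    dropped = [k for k, v in groups.items() if len(np.unique(v)) < 2]
    usable = {k: v for k, v in groups.items() if k not in dropped}

    Z, cols = _design_matrices(usable, n)
    prob = _REMLProblem(y, X, Z, cols)
    K = len(cols)

    converged = True
    if K:
        x0 = np.full(K, np.log(0.1))
        res = optimize.minimize(
            prob.solve_with_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-16.0, 8.0)] * K,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        converged = bool(res.success)
        log_gamma = res.x
    else:
        log_gamma = np.zeros(0)

    crit, beta, XtHiX, sigma2, _ = prob.solve(log_gamma)
    cov = sigma2 * np.linalg.inv(XtHiX)
    bse = np.sqrt(np.diag(cov))
    tvals = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
    df = n - p
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    vc = {}
    for (name, a, b), lg in zip(cols, log_gamma):
        g = float(np.exp(lg))
        vc[name] = 0.0 if g < 1e-10 else g * sigma2
    for name in dropped:
        vc[name] = 0.0

    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    denom = var_fixed + sum(vc.values()) + sigma2
    marginal_r2 = var_fixed / denom if denom > 0 else 0.0

    return MixedLMResult(
        names=list(names),
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        df_resid=df,
        vc=vc,
        resid_var=float(sigma2),
        reml_criterion=float(crit),
        marginal_r2=float(marginal_r2),
        dropped_groups=dropped,
        converged=converged,
    )
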