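"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form/QR code paths: the
marginal likelihood is integrated numerically on a tensor Gauss-Legendre
grid over (beta, log sigma^2).
"""

import numpy as np


def quad_marginal(y, X, lam, sigma, nt=220, nu=200):
    """Direct quadrature of ∫∫ N(y; Xb, s2 I) N(b; 0, s2 lam^2 Sigma) / s2 db ds2.

    Substituting u = log s2 (measure du) and b = lam sqrt(s2) t, so the prior
    over t has unit scale and a fixed t-grid covers every s2 slice.  Suitable
    for n <= ~8, k <= 2.  Returns the integral including all constant
    factors, so ratios between two models are comparable with closed-form
    log-marginal differences.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    Sinv = np.linalg.inv(sigma)
    ld_s = np.linalg.slogdet(sigma)[1]
    yty = float(y @ y)
    u_lo, u_hi = np.log(yty / n) - 10.0, np.log(yty) + 10.0
    xu, wu = np.polynomial.legendre.leggauss(nu)
    u = 0.5 * (u_hi - u_lo) * xu + 0.5 * (u_hi + u_lo)
    wu = wu * 0.5 * (u_hi - u_lo)
    t_lim = 9.0
    xt, wt = np.polynomial.legendre.leggauss(nt)
    t = t_lim * xt
    wt = wt * t_lim
    grids = np.meshgrid(*([t] * k), indexing="ij")
    T = np.stack([g.ravel() for g in grids])  # k x M
    WT = np.ones(T.shape[1])
    for g in np.meshgrid(*([wt] * k), indexing="ij"):
        WT *= g.ravel()
    XT = X @ T
    ytXT = y @ XT
    tXXt = np.einsum("ij,ij->j", XT, XT)
    tq = np.einsum("ji,jk,ki->i", T, Sinv, T)
    const = -0.5 * (n + k) * np.log(2 * np.pi) - 0.5 * ld_s
    total = 0.0
    for s2, w in zip(np.exp(u), wu):
        logf = (
            const
            - 0.5 * n * np.log(s2)
            - 0.5 * yty / s2
            + lam * ytXT / np.sqrt(s2)
            - 0.5 * lam**2 * tXXt
            - 0.5 * tq
        )
        total += w * float(WT @ np.exp(logf))
    return total


def normal_equation_residuals(y, Z):
    """OLS residuals via an explicit normal-equations solve."""
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    return y - Z @ beta
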