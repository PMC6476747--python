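"""Maximum-likelihood mixed models used by the repeatability and
model-selection stages.

Two fitters are provided:

* :func:`fit_lmm` — Gaussian linear mixed model with one random intercept
  (optionally a second, coarser intercept the first is nested in).  The
  likelihood is profiled analytically over the fixed effects and the residual
  variance, leaving a 1- or 2-dimensional search over variance ratios; each
  evaluation costs O(N) via rank-one block algebra, which makes parametric
  bootstraps cheap.
* :func:`fit_poisson_glmm` — Poisson GLMM with one random intercept, marginal
  likelihood by Gauss-Hermite quadrature (exact group-wise aggregation makes
  each likelihood evaluation O(G * Q)).

Both fit by maximum likelihood and report the ML log-likelihood so AICc
values are comparable across fixed-effect structures; the Gaussian fitter
additionally offers REML variance components for repeatability estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp

__all__ = [
    "LMMResult",
    "PoissonGLMMResult",
    "fit_lmm",
    "fit_poisson_glmm",
    "ols_loglik",
    "poisson_glm_fit",
]

_LOG_LAM_LO, _LOG_LAM_HI = -16.0, 16.0


@dataclass
class LMMResult:
    beta: np.ndarray
    se_beta: np.ndarray
    sigma2_e: float
    sigma2_g: float
    sigma2_g2: float
    loglik: float
    converged: bool
    n_params: int  # fixed effects + variance components
    group_labels: np.ndarray = field(default=None, repr=False)
    group2_labels: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    return labels, codes


class _ProfiledLMM:
    """Precomputed sufficient statistics for the profiled Gaussian loglik."""

    def __init__(self, y, X, g_codes, s_codes=None, reml=False):
        self.N, self.p = X.shape
        self.reml = reml
        M = np.column_stack([X, y])
        self.MtM = M.T @ M
        G = g_codes.max() + 1
        # per-inner-group sums of [X, y] and sizes
        self.S = np.zeros((G, self.p + 1))
        for c in range(self.p + 1):
            self.S[:, c] = np.bincount(g_codes, weights=M[:, c], minlength=G)
        self.n_g = np.bincount(g_codes, minlength=G).astype(float)
        self.s_of_g = None
        if s_codes is not None:
            # map each inner group to its (unique) outer group
            s_of_g = np.full(G, -1, dtype=int)
            for g, s in zip(g_codes, s_codes):
                if s_of_g[g] == -1:
                    s_of_g[g] = s
                elif s_of_g[g] != s:
                    raise ValueError("groups must be nested within groups2")
            self.s_of_g = s_of_g
            self.n_s = s_of_g.max() + 1

    def loglik(self, lam: float, lam2: float = 0.0):
        """Profiled ML loglik at variance ratios (lam, lam2); also beta etc."""
        c_g = lam * self.n_g / (1.0 + lam * self.n_g)
        # MtVinvM = MtM - sum_g (c_g / n_g) S_g^T S_g  [c_g/n_g = lam/(1+lam n_g)]
        w = np.where(self.n_g > 0, c_g / np.maximum(self.n_g, 1.0), 0.0)
        A = self.MtM - (self.S * w[:, None]).T @ self.S
        logdet = float(np.sum(np.log1p(lam * self.n_g)))
        if self.s_of_g is not None and lam2 > 0:
            shrink = 1.0 / (1.0 + lam * self.n_g)
            T = np.zeros((self.n_s, self.p + 1))
            cs = np.zeros(self.n_s)
            np.add.at(T, self.s_of_g, self.S * shrink[:, None])
            np.add.at(cs, self.s_of_g, self.n_g * shrink)
            d_s = lam2 / (1.0 + lam2 * cs)
            A = A - (T * d_s[:, None]).T @ T
            logdet += float(np.sum(np.log1p(lam2 * cs)))
        XtVX = A[: self.p, : self.p]
        XtVy = A[: self.p, self.p]
        ytVy = A[self.p, self.p]
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
        quad = float(ytVy - beta @ XtVy)
        quad = max(quad, 1e-300)
        if self.reml:
            df = self.N - self.p
            sigma2 = quad / df
            sign, logdet_x = np.linalg.slogdet(XtVX)
            ll = -0.5 * (
                df * np.log(2.0 * np.pi * sigma2) + df + logdet + logdet_x
            )
        else:
            sigma2 = quad / self.N
            ll = -0.5 * (self.N * np.log(2.0 * np.pi * sigma2) + self.N + logdet)
        return ll, beta, sigma2, XtVX


def fit_lmm(y, X, groups, groups2=None, x0=None, reml=False) -> LMMResult:
    """Fit ``y = X b + u_group (+ u_group2) + e`` by ML (or REML).

    ``groups2``, when given, must be a coarser grouping that ``groups`` is
    nested in (e.g. individuals within sites).  ``x0`` warm-starts the
    two-ratio search (log variance ratios) and restricts it to a single
    optimizer start — useful when refitting across bootstrap or permutation
    replicates.  ``reml=True`` gives restricted-ML variance components
    (preferred for repeatability; the reported loglik is then the REML
    criterion and not comparable across fixed-effect structures).
    ``sigma2_g`` refers to ``groups``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be 1-D and aligned with X rows")
    g_labels, g_codes = _group_codes(groups)
    s_labels = s_codes = None
    if groups2 is not None:
        s_labels, s_codes = _group_codes(groups2)
    prof = _ProfiledLMM(y, X, g_codes, s_codes, reml=reml)

    if groups2 is None:
        res = minimize_scalar(
            lambda u: -prof.loglik(np.exp(u))[0],
            bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat, lam2_hat = float(np.exp(res.x)), 0.0
        ok = bool(res.success)
        # boundary check: sigma_g = 0
        if prof.loglik(0.0)[0] >= prof.loglik(lam_hat)[0]:
            lam_hat = 0.0
        n_params = X.shape[1] + 2
    else:
        def nll(u):
            return -prof.loglik(np.exp(u[0]), np.exp(u[1]))[0]

        starts = [np.asarray(x0, dtype=float)] if x0 is not None else [
            np.array([-1.0, -1.0]), np.array([0.5, -2.0]), np.array([-2.0, 0.5])
        ]
        best = None
        for s0 in starts:
            r = minimize(nll, s0, method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
            if best is None or r.fun < best.fun:
                best = r
        lam_hat, lam2_hat = np.exp(best.x)
        ok = bool(best.success)
        # boundary checks on each ratio
        for cand in [(0.0, lam2_hat), (lam_hat, 0.0), (0.0, 0.0)]:
            if prof.loglik(*cand)[0] >= prof.loglik(lam_hat, lam2_hat)[0]:
                lam_hat, lam2_hat = cand
        n_params = X.shape[1] + 3

    ll, beta, sigma2, XtVX = prof.loglik(lam_hat, lam2_hat)
    try:
        cov = sigma2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    return LMMResult(
        beta=beta,
        se_beta=se,
        sigma2_e=float(sigma2),
        sigma2_g=float(lam_hat * sigma2),
        sigma2_g2=float(lam2_hat * sigma2),
        loglik=float(ll),
        converged=ok,
        n_params=n_params,
        group_labels=g_labels,
        group2_labels=s_labels,
        X=X,
    )


def ols_loglik(y, X) -> tuple[float, np.ndarray, float]:
    """Gaussian ML loglik of the fixed-effects-only model (LRT null)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = y.size
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return float(ll), beta, sigma2


@dataclass
class PoissonGLMMResult:
    beta: np.ndarray
    se_beta: np.ndarray
    sigma_g: float
    loglik: float
    converged: bool
    n_params: int
    group_labels: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)

    @property
    def sigma2_g(self) -> float:
        return self.sigma_g ** 2


def poisson_glm_fit(y, X, max_iter=100, tol=1e-10):
    """Plain Poisson GLM (log link) by IRLS; returns (loglik, beta)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        WX = X * mu[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))
    return ll, beta


class _PoissonGH:
    """Gauss-Hermite marginal loglik of a random-intercept Poisson GLMM."""

    def __init__(self, y, X, g_codes, n_quad=21):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.g = g_codes
        self.G = g_codes.max() + 1
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.z = np.sqrt(2.0) * nodes  # N(0,1) abscissae
        self.logw = np.log(weights) - 0.5 * np.log(np.pi)
        self.lgamma = float(np.sum(gammaln(self.y + 1.0)))
        self.sum_y = np.bincount(g_codes, weights=self.y, minlength=self.G)

    def loglik(self, beta, log_sigma):
        sigma = np.exp(log_sigma)
        eta0 = np.clip(self.X @ beta, -30, 30)
        a = np.bincount(self.g, weights=self.y * eta0, minlength=self.G)
        c = np.bincount(self.g, weights=np.exp(eta0), minlength=self.G)
        # per group g, per node q: a_g + sigma z_q sum_y_g - e^{sigma z_q} c_g
        t = (
            a[:, None]
            + sigma * self.z[None, :] * self.sum_y[:, None]
            - np.exp(sigma * self.z)[None, :] * c[:, None]
            + self.logw[None, :]
        )
        return float(np.sum(logsumexp(t, axis=1))) - self.lgamma

    def loglik_and_grad(self, beta, log_sigma):
        """Marginal loglik plus its exact gradient in (beta, log_sigma)."""
        sigma = np.exp(log_sigma)
        eta0 = np.clip(self.X @ beta, -30, 30)
        mu0 = np.exp(eta0)
        a = np.bincount(self.g, weights=self.y * eta0, minlength=self.G)
        c = np.bincount(self.g, weights=mu0, minlength=self.G)
        ez = np.exp(sigma * self.z)  # (Q,)
        t = (
            a[:, None]
            + sigma * self.z[None, :] * self.sum_y[:, None]
            - ez[None, :] * c[:, None]
            + self.logw[None, :]
        )
        lse = logsumexp(t, axis=1)
        w = np.exp(t - lse[:, None])  # softmax responsibilities (G, Q)
        # per-group design sums: A_gj = sum y_i x_ij, C_gj = sum mu0_i x_ij
        p = self.X.shape[1]
        A = np.empty((self.G, p))
        C = np.empty((self.G, p))
        for j in range(p):
            A[:, j] = np.bincount(self.g, weights=self.y * self.X[:, j], minlength=self.G)
            C[:, j] = np.bincount(self.g, weights=mu0 * self.X[:, j], minlength=self.G)
        wez = w @ ez  # (G,)  E_q[e^{sigma z}]
        grad_beta = A.sum(axis=0) - (C * wez[:, None]).sum(axis=0)
        dt_dls = sigma * self.z[None, :] * (self.sum_y[:, None] - ez[None, :] * c[:, None])
        grad_ls = float(np.sum(w * dt_dls))
        return float(lse.sum()) - self.lgamma, np.concatenate([grad_beta, [grad_ls]])


def _numeric_hessian(f, x, eps=1e-4):
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    return H


def fit_poisson_glmm(
    y, X, groups, n_quad=21, start=None, compute_se=True
) -> PoissonGLMMResult:
    """ML fit of a log-link Poisson GLMM with one random intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    g_labels, g_codes = _group_codes(groups)
    gh = _PoissonGH(y, X, g_codes, n_quad=n_quad)
    if start is None:
        _, beta0 = poisson_glm_fit(y, X)
        x0 = np.concatenate([beta0, [np.log(0.3)]])
    else:
        x0 = np.asarray(start, dtype=float)

    def nll(params):
        return -gh.loglik(params[:-1], params[-1])

    def nll_grad(params):
        ll, grad = gh.loglik_and_grad(params[:-1], params[-1])
        return -ll, -grad

    res = minimize(
        nll_grad, x0, method="L-BFGS-B", jac=True,
        bounds=[(None, None)] * X.shape[1] + [(-8.0, 3.0)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    params = res.x
    beta, log_sigma = params[:-1], params[-1]
    sigma = float(np.exp(log_sigma))
    # sigma effectively zero -> refit boundary model (plain GLM)
    if sigma < 1e-4:
        ll_glm, beta_glm = poisson_glm_fit(y, X)
        beta, sigma = beta_glm, 0.0
        ll = ll_glm
    else:
        ll = -res.fun
    if compute_se:
        try:
            H = _numeric_hessian(nll, params)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov)[: X.shape[1]], 0.0))
        except np.linalg.LinAlgError:
            se = np.full(X.shape[1], np.nan)
    else:
        se = np.full(X.shape[1], np.nan)
    return PoissonGLMMResult(
        beta=np.asarray(beta),
        se_beta=se,
        sigma_g=sigma,
        loglik=float(ll),
        converged=bool(res.success),
        n_params=X.shape[1] + 1,
        group_labels=g_labels,
        X=X,
    )
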