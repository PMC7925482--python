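"""REML engines for linear mixed models with dense covariance kernels.

Two fitters cover every model in the package:

* :func:`reml_fit` — average-information REML with damped-EM fallback steps
  for an arbitrary list of n x n covariance kernels plus an identity
  residual.  Used by the trial mixed model (genotype, GxE, block kernels)
  and the multi-environment GBLUP (genomic, environment, GxE kernels).
* :func:`reml_two_component` — exact spectral REML for the two-component
  model V = sigma2_u * K + sigma2_e * I via one eigendecomposition of K and
  a one-dimensional search over the variance ratio.  Used by the GWAS null
  model and single-environment GBLUP, and it caches the rotation for fast
  per-marker scans.

Convergence follows the usual mixed-model-engine defaults: relative
log-likelihood change below ``tol`` (1e-8) or 200 iterations.  Components
driven negative are truncated at a small floor and, when their gradient
keeps pointing outward, pinned there and reported as truncated-to-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["RemlResult", "reml_fit", "TwoComponentResult", "reml_two_component",
           "two_component_profile_loglik"]


@dataclass
class RemlResult:
    sigma2: np.ndarray  # one entry per kernel, residual last
    names: list[str]
    loglik: float
    n_iter: int
    converged: bool
    gradient_norm: float
    beta: np.ndarray
    beta_cov: np.ndarray
    Vinv: np.ndarray
    Vinv_resid: np.ndarray  # V^{-1} (y - X beta)
    truncated: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def component(self, name: str) -> float:
        return float(self.sigma2[self.names.index(name)])


def _evaluate(y, X, kernels, sigma2):
    """Return (loglik, Vinv, P, Py, beta, beta_cov) for given components."""
    n = y.size
    V = np.zeros((n, n))
    for s2, K in zip(sigma2, kernels):
        if s2 != 0.0:
            V += s2 * K
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        c, low = linalg.cho_factor(V + 1e-8 * np.trace(V) / n * np.eye(n), check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cx, lowx = linalg.cho_factor(XtVinvX, check_finite=False)
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx)))
    beta_cov = linalg.cho_solve((cx, lowx), np.eye(X.shape[1]), check_finite=False)
    beta = beta_cov @ (VinvX.T @ y)
    P = Vinv - VinvX @ beta_cov @ VinvX.T
    Py = P @ y
    loglik = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return loglik, Vinv, P, Py, beta, beta_cov


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
) -> RemlResult:
    """Average-information REML for y = X beta + sum_i u_i + e with
    cov(u_i) = sigma2_i * K_i and cov(e) = sigma2_e * I.

    ``kernels`` are the non-residual covariance kernels; an identity
    residual kernel is appended internally.  ``names`` labels the
    components (residual is named ``"sigma2_e"`` if not given).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X row count does not match y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is singular")
    ks = [np.asarray(K, dtype=float) for K in kernels] + [np.eye(n)]
    k = len(ks)
    if names is None:
        names = [f"sigma2_{i}" for i in range(k - 1)] + ["sigma2_e"]
    else:
        names = list(names)
        if len(names) == k - 1:
            names.append("sigma2_e")
    vy = float(np.var(y, ddof=1))
    if vy == 0.0:
        vy = 1.0
    floor = 1e-8 * vy
    if start is None:
        sigma2 = np.array([vy / k / max(np.mean(np.diag(K)), 1e-12) for K in ks])
    else:
        sigma2 = np.asarray(start, dtype=float).copy()
    sigma2 = np.maximum(sigma2, floor)
    pinned = np.zeros(k, dtype=bool)
    log: list[str] = []

    loglik, Vinv, P, Py, beta, beta_cov = _evaluate(y, X, ks, sigma2)
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        tr_PK = np.array([np.sum(P * K) for K in ks])
        t = [K @ Py for K in ks]
        yPKPy = np.array([float(Py @ ti) for ti in t])
        score = 0.5 * (yPKPy - tr_PK)
        Pt = [P @ ti for ti in t]
        AI = 0.5 * np.array([[float(ti @ Ptj) for Ptj in Pt] for ti in t])
        # pin components stuck at the floor with outward-pointing gradient
        pinned = (sigma2 <= floor * 1.0001) & (score < 0.0)
        free = ~pinned
        grad_norm = float(np.linalg.norm(score[free])) if free.any() else 0.0

        delta = np.zeros(k)
        if free.any():
            A = AI[np.ix_(free, free)]
            A = A + 1e-10 * np.eye(A.shape[0]) * max(np.abs(A).max(), 1.0)
            try:
                delta[free] = np.linalg.solve(A, score[free])
            except np.linalg.LinAlgError:
                delta[free] = score[free] / np.maximum(np.diag(AI)[free], 1e-12)

        improved = False
        step = 1.0
        for _ in range(12):
            cand = np.maximum(sigma2 + step * delta, floor)
            cand[pinned] = floor
            ll_new, Vinv_n, P_n, Py_n, beta_n, bc_n = _evaluate(y, X, ks, cand)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            # damped-EM fallback step (ascent direction, scaled by sigma2^2/n)
            cand = np.maximum(sigma2 + (sigma2**2) * 2.0 * score / n, floor)
            cand[pinned] = floor
            ll_new, Vinv_n, P_n, Py_n, beta_n, bc_n = _evaluate(y, X, ks, cand)
            if not np.isfinite(ll_new) or ll_new < loglik - 1e-8:
                log.append(f"iter {it}: no ascent step found, stopping")
                break
            log.append(f"iter {it}: EM fallback step")
        rel_change = abs(ll_new - loglik) / (abs(loglik) + 1.0)
        sigma2, loglik = cand, ll_new
        Vinv, P, Py, beta, beta_cov = Vinv_n, P_n, Py_n, beta_n, bc_n
        if rel_change < tol:
            converged = True
            break
    if not converged:
        log.append(f"not converged after {it} iterations (last estimates reported)")

    truncated = [names[i] for i in range(k) if sigma2[i] <= floor * 1.0001]
    out = sigma2.copy()
    out[out <= floor * 1.0001] = 0.0
    log.append(
        "REML: loglik=%.6f, iter=%d, |grad|=%.3e, components=%s"
        % (loglik, it, grad_norm, dict(zip(names, np.round(out, 6))))
    )
    return RemlResult(
        sigma2=out, names=names, loglik=loglik, n_iter=it, converged=converged,
        gradient_norm=grad_norm, beta=beta, beta_cov=beta_cov, Vinv=Vinv,
        Vinv_resid=Vinv @ (y - X @ beta), truncated=truncated, log=log,
    )


# ---------------------------------------------------------------------------
# two-component spectral REML


@dataclass
class TwoComponentResult:
    sigma2_u: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    log_delta: float  # log(sigma2_e / sigma2_u) at the optimum
    U: np.ndarray  # eigenvectors of K
    d: np.ndarray  # eigenvalues of K (clipped at 0)
    y_rot: np.ndarray
    X_rot: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else np.nan

    def weights(self) -> np.ndarray:
        """1 / diag(V) in the rotated basis (absolute scale)."""
        return 1.0 / (self.sigma2_u * self.d + self.sigma2_e)


def _profile_parts(y_rot, X_rot, d, log_delta):
    delta = np.exp(log_delta)
    w = d + delta
    Xw = X_rot / w[:, None]
    XtWX = X_rot.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y_rot)
    r = y_rot - X_rot @ beta
    n, p = X_rot.shape
    rss = float(r @ (r / w))
    s2u = rss / (n - p)
    sign, logdet_X = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(s2u) + np.sum(np.log(w)) + logdet_X + (n - p))
    return ll, beta, s2u, delta


def two_component_profile_loglik(y, X, K, log_delta: float) -> float:
    """Restricted profile log-likelihood of the ratio delta = sigma2_e/sigma2_u
    (independent grid-search oracle for the optimizer)."""
    d, U = np.linalg.eigh(np.asarray(K, dtype=float))
    d = np.clip(d, 0.0, None)
    ll, *_ = _profile_parts(U.T @ np.asarray(y, float).ravel(),
                            U.T @ np.atleast_2d(np.asarray(X, float)), d, log_delta)
    return ll

def reml_two_component(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    bounds: tuple[float, float] = (-12.0, 12.0),
) -> TwoComponentResult:
    """Exact REML for V = sigma2_u K + sigma2_e I by eigendecomposition of K
    and bounded scalar optimization of log(sigma2_e / sigma2_u)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X row count does not match y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is singular (collinear covariates)")
    K = np.asarray(K, dtype=float)
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-6 * max(abs(d.max()), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    y_rot = U.T @ y
    X_rot = U.T @ X

    res = optimize.minimize_scalar(
        lambda t: -_profile_parts(y_rot, X_rot, d, t)[0],
        bounds=bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    ll, beta, s2u, delta = _profile_parts(y_rot, X_rot, d, res.x)
    return TwoComponentResult(
        sigma2_u=s2u, sigma2_e=s2u * delta, beta=beta, loglik=ll,
        log_delta=float(res.x), U=U, d=d, y_rot=y_rot, X_rot=X_rot,
    )
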