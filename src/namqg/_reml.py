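"""Restricted maximum likelihood (REML) machinery shared across modules.

All fits use expectation-maximization (EM) REML updates, which are monotone
in the restricted likelihood and keep variance components nonnegative by
construction.  Three solvers are provided:

- :func:`em_reml` — generic dense multi-kernel solver (V = sum sigma_i^2 C_i);
- :func:`em_reml_diag` — same model after rotation to a basis where every
  kernel is diagonal (used for two-component genomic fits, where the
  eigenbasis of the relationship matrix diagonalizes both kernels);
- :func:`em_bivariate` — two-trait model with a dense 2x2 genetic covariance
  over one kernel and diagonal residual covariance, solved in the kernel
  eigenbasis where the problem factorizes into 2x2 blocks.

:func:`restricted_loglik` evaluates the restricted log-likelihood directly
(up to an additive constant) and is the quantity all solvers maximize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["restricted_loglik", "em_reml", "em_reml_diag", "em_bivariate",
           "REMLResult", "BivariateREMLResult", "REMLConvergenceError"]


class REMLConvergenceError(RuntimeError):
    """Raised when an EM-REML fit fails to converge; carries the trace."""

    def __init__(self, msg: str, trace: list | None = None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class REMLResult:
    sigma2: np.ndarray          # one variance per kernel (last = residual)
    loglik: float
    beta: np.ndarray            # fixed-effect GLS estimates
    Py: np.ndarray              # projected data vector, V^-1 (y - X beta)
    n_iter: int
    converged: bool
    trace: list


def restricted_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood of y ~ N(X beta, V), up to a constant.

    -0.5 [ log|V| + log|X'V^-1 X| + y'Py ].
    """
    cf = cho_factor(V, lower=True)
    Viy = cho_solve(cf, y)
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ beta
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    s, logdetX = np.linalg.slogdet(XtViX)
    return float(-0.5 * (logdetV + logdetX + y @ Py))


def squarem(step, s0: np.ndarray, tol: float, max_iter: int, floor: float,
            accelerate: bool = True):
    """SQUAREM-accelerated fixed-point driver for EM maps.

    ``step(s) -> (ll(s), s_new, payload)`` must implement one monotone EM
    update.  Extrapolated points are only accepted when they do not lower
    the restricted likelihood, so the safeguarded iteration inherits EM's
    monotonicity.  Returns (s, ll, payload, n_evals, converged, trace);
    ``payload`` corresponds to the returned ``s``.
    """
    sigma2 = np.asarray(s0, float).copy()
    trace = []
    ll_prev = -np.inf
    converged = False
    evals = 0
    ll, payload = -np.inf, None
    while evals < max_iter:
        ll0, s1, payload = step(sigma2)
        evals += 1
        trace.append((list(sigma2), ll0))
        ll = ll0
        if abs(ll0 - ll_prev) < tol * (1.0 + abs(ll0)):
            converged = True
            break
        ll_prev = ll0
        if not accelerate:
            sigma2 = s1
            continue
        ll1, s2, _ = step(s1)
        evals += 1
        r = s1 - sigma2
        v = (s2 - s1) - r
        nv = np.linalg.norm(v)
        if nv == 0:
            sigma2 = s2
            continue
        alpha = -np.linalg.norm(r) / nv
        cand = np.maximum(sigma2 - 2.0 * alpha * r + alpha ** 2 * v, floor)
        ll_cand, s_cand, _ = step(cand)
        evals += 1
        sigma2 = s_cand if ll_cand >= ll1 else s2
    return sigma2, ll, payload, evals, converged, trace


def em_reml(y: np.ndarray, X: np.ndarray, kernels: list[np.ndarray],
            init: np.ndarray | None = None, tol: float = 1e-8,
            max_iter: int = 500, raise_on_fail: bool = False,
            accelerate: bool = True) -> REMLResult:
    """Dense multi-kernel EM-REML: V = sum_i sigma_i^2 C_i.

    The last kernel is conventionally the residual structure (identity or
    a diagonal of inverse observation weights).  The EM map is optionally
    accelerated with SQUAREM extrapolation, falling back to the plain
    (monotone) EM step whenever the extrapolated point does not improve
    the restricted likelihood; ``max_iter`` counts EM-map evaluations.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    vary = float(np.var(y))
    floor = max(vary, 1e-8) * 1e-10
    if init is None:
        init = np.full(len(kernels), vary / len(kernels))
    sigma2 = np.asarray(init, float).copy()
    k = len(kernels)

    def step(s):
        """One EM update: returns (ll(s), s_new, beta(s), Py(s))."""
        V = np.zeros((n, n))
        for si, C in zip(s, kernels):
            V += si * C
        cf = cho_factor(V, lower=True)
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        Vinv = cho_solve(cf, np.eye(n))
        Viy = Vinv @ y
        ViX = Vinv @ X
        XtViX = X.T @ ViX
        XtViX_inv = np.linalg.inv(XtViX)
        beta = XtViX_inv @ (X.T @ Viy)
        Py = Viy - ViX @ beta
        _, logdetX = np.linalg.slogdet(XtViX)
        ll = float(-0.5 * (logdetV + logdetX + y @ Py))
        s_new = np.empty(k)
        for i, C in enumerate(kernels):
            trVC = float((Vinv * C).sum())        # tr(V^-1 C), elementwise
            CViX = C @ ViX
            trPC = trVC - float(np.trace(XtViX_inv @ (ViX.T @ CViX)))
            quad = float(Py @ (C @ Py))
            s_new[i] = max(s[i] + s[i] ** 2 / n * (quad - trPC), floor)
        return ll, s_new, (beta, Py)

    sigma2, ll, payload, evals, converged, trace = squarem(
        step, sigma2, tol, max_iter, floor, accelerate)
    beta, Py = payload
    if not converged and raise_on_fail:
        raise REMLConvergenceError(
            f"EM-REML did not converge in {max_iter} map evaluations", trace)
    return REMLResult(sigma2, ll, beta, Py, evals, converged, trace)


def em_reml_diag(y: np.ndarray, X: np.ndarray, diags: list[np.ndarray],
                 init: np.ndarray | None = None, tol: float = 1e-8,
                 max_iter: int = 2000) -> REMLResult:
    """EM-REML when every kernel is diagonal in the working basis.

    O(n) per iteration; used after rotating a two-component genomic model
    into the eigenbasis of the relationship matrix.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    D = np.column_stack(diags)  # n x k
    vary = float(np.var(y))
    floor = max(vary, 1e-8) * 1e-10
    if init is None:
        init = np.full(D.shape[1], vary / D.shape[1])
    sigma2 = np.asarray(init, float).copy()

    def step(s):
        v = D @ s
        Viy = y / v
        ViX = X / v[:, None]
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, X.T @ Viy)
        Py = Viy - ViX @ beta
        ll = float(-0.5 * (np.log(v).sum() + np.linalg.slogdet(XtViX)[1] + y @ Py))
        A = np.linalg.inv(XtViX)
        s_new = np.empty(D.shape[1])
        for j in range(D.shape[1]):
            d = D[:, j]
            B = ViX.T @ (ViX * d[:, None])
            trPC = float((d / v).sum() - np.trace(A @ B))
            quad = float(Py @ (d * Py))
            s_new[j] = max(s[j] + s[j] ** 2 / n * (quad - trPC), floor)
        return ll, s_new, (beta, Py)

    sigma2, ll, payload, n_iter, converged, trace = squarem(
        step, sigma2, tol, max_iter, floor)
    beta, Py = payload
    return REMLResult(sigma2, ll, beta, Py, n_iter, converged, trace)


@dataclass
class BivariateREMLResult:
    Sigma_psi: np.ndarray        # 2x2 genetic covariance over the kernel
    Sigma_eps: np.ndarray        # 2x2 diagonal residual covariance
    loglik: float
    beta: np.ndarray             # per-trait intercepts
    psi_blup: np.ndarray         # n x 2 genetic-value BLUPs (original basis)
    rho: float                   # genetic correlation from Sigma_psi
    degenerate: bool
    n_iter: int
    converged: bool


def _inv2(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched inverse and log-determinant of (n,2,2) SPD matrices."""
    a = V[:, 0, 0]
    b = V[:, 0, 1]
    d = V[:, 1, 1]
    det = a * d - b * b
    inv = np.empty_like(V)
    inv[:, 0, 0] = d / det
    inv[:, 1, 1] = a / det
    inv[:, 0, 1] = inv[:, 1, 0] = -b / det
    return inv, np.log(det)


def em_bivariate(Y: np.ndarray, eigvals: np.ndarray, U: np.ndarray,
                 tol: float = 1e-11, max_iter: int = 5000,
                 diagonal_psi: bool = False) -> BivariateREMLResult:
    """Two-trait GBLUP REML in the eigenbasis of the relationship kernel.

    Model: y_k = mu_k + psi_k + eps_k with (psi_1, psi_2) ~ N(0, K (x)
    Sigma_psi) and diagonal residual covariance.  ``Y`` is n x 2 on the
    original basis; ``eigvals``/``U`` are the eigendecomposition of K.
    """
    n = Y.shape[0]
    Yt = U.T @ Y                       # rotated traits
    x = U.T @ np.ones(n)               # rotated intercept column
    d = np.asarray(eigvals, float)
    vy = Y.var(axis=0)
    scale = float(vy.mean())
    floor = scale * 1e-10

    def sanitize(s):
        Sp = np.array([[s[0], s[1]], [s[1], s[2]]])
        if diagonal_psi:
            Sp = np.diag(np.diag(Sp))
        w, Q = np.linalg.eigh(Sp)
        Sp = (Q * np.maximum(w, floor)) @ Q.T
        Se = np.diag(np.maximum(s[3:5], floor))
        return Sp, Se

    def step(s):
        Sp, Se = sanitize(s)
        V = d[:, None, None] * Sp[None] + Se[None]
        Vinv, logdet = _inv2(V)
        # GLS intercepts: X_i = x_i * I2
        XtViX = (x[:, None, None] ** 2 * Vinv).sum(axis=0)
        XtViy = (x[:, None] * np.einsum("nij,nj->ni", Vinv, Yt)).sum(axis=0)
        beta = np.linalg.solve(XtViX, XtViy)
        resid = Yt - x[:, None] * beta[None, :]
        Py = np.einsum("nij,nj->ni", Vinv, resid)
        A = np.linalg.inv(XtViX)
        # 2x2 diagonal blocks of the REML projector P
        Pii = Vinv - np.einsum("nij,jk,nkl->nil", Vinv, A, Vinv) * (x ** 2)[:, None, None]
        quad = float(np.einsum("ni,ni->", resid, Py))
        ll = float(-0.5 * (logdet.sum() + np.linalg.slogdet(XtViX)[1] + quad))
        # EM updates (divided through by d analytically, safe at d=0)
        PyPy = np.einsum("ni,nj->nij", Py, Py)
        Sp_new = Sp + (Sp @ ((d[:, None, None] * (PyPy - Pii)).sum(axis=0) / n) @ Sp)
        Se_new = Se + (Se @ ((PyPy - Pii).sum(axis=0) / n) @ Se)
        Sp_new = 0.5 * (Sp_new + Sp_new.T)
        if diagonal_psi:
            Sp_new = np.diag(np.diag(Sp_new))
        s_new = np.array([Sp_new[0, 0], Sp_new[0, 1], Sp_new[1, 1],
                          max(Se_new[0, 0], floor), max(Se_new[1, 1], floor)])
        return ll, s_new, (beta, Py, Sp, Se)

    s0 = np.array([vy[0] / 2, 0.0, vy[1] / 2, vy[0] / 2, vy[1] / 2])
    s_fit, ll, payload, n_evals, converged, trace = squarem(
        step, s0, tol, max_iter, -np.inf)
    beta, Py, Sp, Se = payload
    it = n_evals - 1

    psi_rot = d[:, None] * np.einsum("ij,nj->ni", Sp, Py)
    psi = U @ psi_rot
    denom = np.sqrt(Sp[0, 0] * Sp[1, 1])
    rho = float(Sp[0, 1] / denom) if denom > 0 else float("nan")
    degenerate = bool(
        not np.isfinite(rho)
        or min(Sp[0, 0], Sp[1, 1]) <= 10 * floor
        or abs(rho) > 0.999
    )
    return BivariateREMLResult(
        Sigma_psi=Sp, Sigma_eps=Se, loglik=ll, beta=beta, psi_blup=psi,
        rho=float(np.clip(rho, -1.0, 1.0)) if np.isfinite(rho) else rho,
        degenerate=degenerate, n_iter=it + 1, converged=converged,
    )
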