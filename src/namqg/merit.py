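"""Stage-1 genetic-merit analysis of plot-level phenotypes.

Per trait the pipeline (i) computes a moving-average spatial covariate from
neighbor plots, (ii) attaches inverse within-environment phenotypic
variances as observation weights, and (iii) fits the weighted mixed model

    y = mu + beta f(s) + Z u + W g + e,

with genotype effects ``u ~ N(0, sigma_u^2 I)``, local-environment (field
block) effects ``g ~ N(0, sigma_g^2 I)`` and heteroscedastic residuals
``e ~ N(0, sigma_e^2 diag(1/w))``, by EM-REML on Henderson's mixed-model
equations.  Broad-sense heritability on an entry-mean basis is
``H = sigma_u^2 / (sigma_u^2 + sigma_e^2 / r)`` with ``r`` the mean plot
count per non-check entry.  Each genotype's BLUP is deregressed by its
reliability ``H_j = 1 - PEV_j / sigma_u^2`` to give the genetic value
``y_j = u_j / H_j`` consumed by all genomic stages.

Check plots enter the model as ordinary genotype levels (they anchor the
spatial/block correction) but are excluded from ``r`` and flagged in the
output so downstream stages can drop them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._reml import REMLConvergenceError, squarem


@dataclass
class MeritResult:
    table: pd.DataFrame        # id, family, is_check, blup, reliability, deregressed
    sigma2_u: float
    sigma2_g: float
    sigma2_e: float
    H: float                   # broad-sense, entry-mean basis
    r: float                   # mean plots per non-check entry
    mu: float
    beta_spatial: float | None
    loglik: float
    n_iter: int
    converged: bool
    sigma_u_degenerate: bool = False

    def deregressed(self, drop_checks: bool = True) -> pd.Series:
        t = self.table
        if drop_checks:
            t = t[~t.is_check]
        return t.set_index("id")["deregressed"]


def spatial_covariate(plots: pd.DataFrame, trait: str,
                      window: tuple[int, int] = (1, 1)) -> np.ndarray:
    """Moving-average of neighbor plots within each (env, block).

    The covariate of a plot is the mean raw trait value over all *other*
    plots in the same environment and block whose row and column offsets
    are within ``window``; plots with no neighbors get the block mean.
    """
    if trait not in plots.columns:
        raise KeyError(f"trait {trait!r} not in plot table")
    wr, wc = window
    out = np.full(len(plots), np.nan)
    vals = plots[trait].to_numpy(float)
    rows = plots["row"].to_numpy(int)
    cols = plots["col"].to_numpy(int)
    for _, idx in plots.groupby(["env", "block"]).indices.items():
        idx = np.asarray(idx)
        r, c, v = rows[idx], cols[idx], vals[idx]
        block_mean = float(np.nanmean(v))
        dr = np.abs(r[:, None] - r[None, :])
        dc = np.abs(c[:, None] - c[None, :])
        nb = (dr <= wr) & (dc <= wc)
        np.fill_diagonal(nb, False)
        ok = np.isfinite(v)
        counts = (nb & ok[None, :]).sum(axis=1)
        sums = (nb * np.where(ok, v, 0.0)[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            cov = np.where(counts > 0, sums / np.maximum(counts, 1), block_mean)
        out[idx] = cov
    return out


def env_weights(plots: pd.DataFrame, trait: str) -> np.ndarray:
    """Inverse within-environment phenotypic variance, per plot."""
    if trait not in plots.columns:
        raise KeyError(f"trait {trait!r} not in plot table")
    out = np.full(len(plots), np.nan)
    for env, idx in plots.groupby("env").indices.items():
        v = plots[trait].to_numpy(float)[np.asarray(idx)]
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"environment {env!r} has fewer than 2 observations")
        var = float(np.var(v, ddof=1))
        if var <= 0:
            raise ValueError(f"environment {env!r} has zero phenotypic variance")
        out[np.asarray(idx)] = 1.0 / var
    return out


def _incidence(labels: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    levels, idx = np.unique(labels, return_inverse=True)
    Z = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), idx)),
        shape=(len(labels), len(levels)),
    )
    return Z, levels


def fit_merit(plots: pd.DataFrame, trait: str,
              covariate: np.ndarray | None = None,
              weights: np.ndarray | None = None,
              tol: float = 1e-8, max_iter: int = 500) -> MeritResult:
    """Weighted two-variance-component mixed model via EM-REML on the MME."""
    keep = plots[trait].notna().to_numpy()
    plots = plots.loc[keep].reset_index(drop=True)
    y = plots[trait].to_numpy(float)
    n = len(y)
    if covariate is not None:
        covariate = np.asarray(covariate, float)[keep]
        X = np.column_stack([np.ones(n), covariate])
    else:
        X = np.ones((n, 1))
    if weights is not None:
        w = np.asarray(weights, float)[keep]
        w = w / w.mean()            # keep sigma_e^2 on the trait scale
    else:
        w = np.ones(n)

    Z, geno_levels = _incidence(plots["id"].to_numpy())
    block_labels = (plots["env"].astype(str) + "|" + plots["block"].astype(str)).to_numpy()
    W, _ = _incidence(block_labels)
    q_u, q_g = Z.shape[1], W.shape[1]
    p = X.shape[1]

    Rw = sp.diags(w)
    XtRX = X.T @ (w[:, None] * X)
    XtRZ = np.asarray((Z.T @ (w[:, None] * X)).T)
    XtRW = np.asarray((W.T @ (w[:, None] * X)).T)
    ZtRZ = (Z.T @ Rw @ Z).toarray()
    ZtRW = (Z.T @ Rw @ W).toarray()
    WtRW = (W.T @ Rw @ W).toarray()
    XtRy = X.T @ (w * y)
    ZtRy = np.asarray(Z.T @ (w * y)).ravel()
    WtRy = np.asarray(W.T @ (w * y)).ravel()
    yRy = float(y @ (w * y))
    log_w = float(np.log(w).sum())

    vary = float(np.var(y))
    floor = max(vary, 1e-8) * 1e-10
    k = p + q_u + q_g

    def step(s):
        """One EM-REML update on Henderson's mixed-model equations."""
        s2u, s2g, s2e = s
        M = np.zeros((k, k))
        M[:p, :p] = XtRX / s2e
        M[:p, p:p + q_u] = XtRZ / s2e
        M[:p, p + q_u:] = XtRW / s2e
        M[p:p + q_u, p:p + q_u] = ZtRZ / s2e + np.eye(q_u) / s2u
        M[p:p + q_u, p + q_u:] = ZtRW / s2e
        M[p + q_u:, p + q_u:] = WtRW / s2e + np.eye(q_g) / s2g
        M[p:, :p] = M[:p, p:].T
        M[p + q_u:, p:p + q_u] = M[p:p + q_u, p + q_u:].T
        rhs = np.concatenate([XtRy, ZtRy, WtRy]) / s2e
        Minv = np.linalg.inv(M)
        sol = Minv @ rhs
        b, u, g = sol[:p], sol[p:p + q_u], sol[p + q_u:]
        yPy = yRy / s2e - rhs @ sol
        _, logdetM = np.linalg.slogdet(M)
        ll = -0.5 * (
            n * np.log(s2e) - log_w + q_u * np.log(s2u) + q_g * np.log(s2g)
            + logdetM + yPy
        )
        pev_u = np.diag(Minv)[p:p + q_u]
        pev_g = np.diag(Minv)[p + q_u:]
        e_hat = y - X @ b - Z @ u - W @ g
        s_new = np.array([
            max((u @ u + pev_u.sum()) / q_u, floor),
            max((g @ g + pev_g.sum()) / q_g, floor),
            max((e_hat * w) @ y / (n - p), floor),
        ])
        return float(ll), s_new, (b, u, g, pev_u)

    s0 = np.full(3, vary / 3)
    sig, ll, payload, n_evals, converged, trace = squarem(
        step, s0, tol, max_iter, floor)
    if not converged:
        raise REMLConvergenceError(
            f"merit EM-REML did not converge in {max_iter} map evaluations "
            f"(last components u={sig[0]:.4g} g={sig[1]:.4g} e={sig[2]:.4g})",
            trace,
        )
    s2u, s2g, s2e = sig
    b, u, g, pev_u = payload
    it = n_evals - 1
    degenerate = s2u <= max(vary, 1e-8) * 1e-8
    if degenerate:
        reliability = np.zeros(q_u)
    else:
        reliability = np.clip(1.0 - pev_u / s2u, 0.0, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        dereg = np.where(reliability > 0, u / reliability, np.nan)

    is_check = plots.groupby("id")["is_check"].first().reindex(geno_levels).to_numpy().astype(bool)
    fam = plots.groupby("id")["family"].first().reindex(geno_levels).to_numpy()
    counts = plots.groupby("id").size().reindex(geno_levels).to_numpy()
    r = float(counts[~is_check].mean())
    H = 0.0 if degenerate else float(s2u / (s2u + s2e / r))

    table = pd.DataFrame({
        "id": geno_levels,
        "family": fam,
        "is_check": is_check,
        "n_plots": counts,
        "blup": u,
        "reliability": reliability,
        "deregressed": dereg,
    })
    return MeritResult(
        table=table, sigma2_u=float(s2u), sigma2_g=float(s2g), sigma2_e=float(s2e),
        H=H, r=r, mu=float(b[0]),
        beta_spatial=float(b[1]) if p > 1 else None,
        loglik=float(ll), n_iter=it + 1, converged=converged,
        sigma_u_degenerate=bool(degenerate),
    )


def broad_sense_H(sigma2_u: float, sigma2_e: float, r: float) -> float:
    """Entry-mean broad-sense heritability H = s2u / (s2u + s2e / r)."""
    return sigma2_u / (sigma2_u + sigma2_e / r)


def deregress(blup: np.ndarray, reliability: np.ndarray) -> np.ndarray:
    """Unshrink BLUPs: y_j = u_j / H_j (undefined where H_j <= 0)."""
    blup = np.asarray(blup, float)
    rel = np.asarray(reliability, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(rel > 0, blup / rel, np.nan)
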