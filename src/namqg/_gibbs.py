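"""Gibbs samplers for spike-and-slab whole-genome regression.

One numba kernel serves both samplers used in the pipeline:

- BayesCpi (association): common marker variance sigma2_b, inclusion
  probability estimated each iteration with a Beta posterior, and the
  marker-variance prior scale recomputed from the current inclusion rate,
  S_b = 0.5 var(y) / (MSx (1 - pi_null)), so the prior puts heritability
  0.5 on the marker term.
- BayesB (prediction): fixed null probability pi = 0.95 and per-marker
  variances sigma2_bj, each with scaled-inverse-chi-square prior
  (S_b = 0.5 var(y) / MSx, nu0 = 10).

MSx is the sum of centered-marker column variances.  Residual variance has
prior scale S_e = 0.5 var(y) with the same nu0 as the marker prior.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numba import njit


class GibbsResult(NamedTuple):
    mu: float
    effects: np.ndarray        # posterior-mean marker effects
    model_freq: np.ndarray     # posterior inclusion frequency per marker
    sigma2_e: float
    pi_null: float             # posterior mean null probability
    sigma2_b: float            # posterior mean marker variance (common/average)
    n_kept: int


@njit(cache=False)
def _gibbs_kernel(y, Mt, xtx, iters, burnin, seed, nu0, pi_null_init,
                  estimate_pi, per_marker_var, vary, msx, fix_marker_var,
                  s2b_init):
    np.random.seed(seed)
    m, n = Mt.shape
    Se = 0.5 * vary
    Sb_fixed = 0.5 * vary / msx
    a = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    pi_null = pi_null_init
    s2e = 0.5 * vary
    s2b_common = s2b_init
    v = np.full(m, s2b_common)
    mu = 0.0
    e = y.copy()

    a_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    s2e_sum = 0.0
    pi_sum = 0.0
    s2b_sum = 0.0
    kept = 0
    diverged_at = -1

    for it in range(iters):
        # intercept
        e_mu = e + mu
        mean_e = e_mu.sum() / n
        mu = np.random.normal(mean_e, np.sqrt(s2e / n))
        e = e_mu - mu

        # prior scale for marker variances
        if per_marker_var or fix_marker_var:
            Sb = Sb_fixed
        else:
            Sb = 0.5 * vary / (msx * max(1.0 - pi_null, 1e-8))

        k_incl = 0
        ss_a = 0.0
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            if delta[j] == 1:
                aj = a[j]
                for i in range(n):
                    e[i] += Mt[j, i] * aj
            rhs = 0.0
            for i in range(n):
                rhs += Mt[j, i] * e[i]
            vj = v[j] if per_marker_var else s2b_common
            c = xtx[j] + s2e / vj
            log_bf = 0.5 * (rhs * rhs / (s2e * c)) + 0.5 * np.log(s2e / (vj * c))
            if pi_null >= 1.0:
                p_incl = 0.0
            elif pi_null <= 0.0:
                p_incl = 1.0
            else:
                log_odds = log_bf + np.log((1.0 - pi_null) / pi_null)
                if log_odds > 35.0:
                    p_incl = 1.0
                elif log_odds < -35.0:
                    p_incl = 0.0
                else:
                    p_incl = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_incl:
                delta[j] = 1
                aj = np.random.normal(rhs / c, np.sqrt(s2e / c))
                a[j] = aj
                for i in range(n):
                    e[i] -= Mt[j, i] * aj
                k_incl += 1
                ss_a += aj * aj
            else:
                delta[j] = 0
                a[j] = 0.0
            # per-marker variance (BayesB): sampled for every marker
            if per_marker_var and not fix_marker_var:
                v[j] = (a[j] * a[j] + Sb * nu0) / np.random.chisquare(nu0 + delta[j])

        if not per_marker_var and not fix_marker_var:
            s2b_common = (ss_a + Sb * nu0) / np.random.chisquare(nu0 + k_incl)

        if estimate_pi:
            # pi_incl ~ Beta(k+1, m-k+1)  <=>  pi_null = 1 - pi_incl
            g1 = np.random.gamma(k_incl + 1.0, 1.0)
            g2 = np.random.gamma(m - k_incl + 1.0, 1.0)
            pi_null = 1.0 - g1 / (g1 + g2)

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (sse + Se * nu0) / np.random.chisquare(nu0 + n)
        if not np.isfinite(s2e) or s2e <= 0.0:
            diverged_at = it
            break

        if it >= burnin:
            kept += 1
            mu_sum += mu
            s2e_sum += s2e
            pi_sum += pi_null
            if per_marker_var:
                vbar = 0.0
                for j in range(m):
                    vbar += v[j]
                s2b_sum += vbar / m
            else:
                s2b_sum += s2b_common
            for j in range(m):
                a_sum[j] += a[j]
                incl_sum[j] += delta[j]

    return a_sum, incl_sum, mu_sum, s2e_sum, pi_sum, s2b_sum, kept, diverged_at


def wgr_sample(y: np.ndarray, M: np.ndarray, iters: int, burnin: int, seed: int,
               nu0: float, pi_null: float, estimate_pi: bool,
               per_marker_var: bool, fix_marker_var: bool = False,
               sigma2_b_fixed: float | None = None) -> GibbsResult:
    """Run the spike-and-slab Gibbs sampler and return posterior summaries."""
    if iters <= burnin:
        raise ValueError(f"iters ({iters}) must exceed burnin ({burnin})")
    y = np.ascontiguousarray(np.asarray(y, float))
    M = np.asarray(M, float)
    Mt = np.ascontiguousarray(M.T)
    xtx = (M * M).sum(axis=0)
    vary = float(np.var(y))
    msx = float(M.var(axis=0).sum())
    if msx <= 0:
        raise ValueError("all markers monomorphic: MSx = 0")
    s2b_init = 0.5 * vary / msx if sigma2_b_fixed is None else float(sigma2_b_fixed)
    out = _gibbs_kernel(
        y, Mt, xtx, int(iters), int(burnin), int(seed) % (2 ** 31), float(nu0),
        float(pi_null), bool(estimate_pi), bool(per_marker_var), vary, msx,
        bool(fix_marker_var), s2b_init,
    )
    a_sum, incl_sum, mu_sum, s2e_sum, pi_sum, s2b_sum, kept, diverged_at = out
    if diverged_at >= 0:
        raise RuntimeError(f"divergent variance draw at MCMC iteration {diverged_at}")
    return GibbsResult(
        mu=mu_sum / kept,
        effects=a_sum / kept,
        model_freq=incl_sum / kept,
        sigma2_e=s2e_sum / kept,
        pi_null=pi_sum / kept,
        sigma2_b=s2b_sum / kept,
        n_kept=kept,
    )
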