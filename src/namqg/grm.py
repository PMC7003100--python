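"""Genomic relationship kernels and SNP-BLUP narrow-sense heritability.

The additive kernel is the cross-product of the centered marker matrix,
normalized so its trace equals the number of individuals:
``K = M M' alpha`` with ``alpha = n / tr(M M')``.  The additive-by-additive
epistatic kernel is the Hadamard square of the *unnormalized* cross-product,
renormalized by its own trace: ``Q = (M M' # M M') alpha_Q``.  Narrow-sense
heritability from the SNP-BLUP model ``y = mu + M a + eps`` is

    h2 = sigma_a^2 * 2 sum_j p_j (1 - p_j) / (same + sigma_eps^2),

with the allele-frequency sum taken over the markers actually fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._reml import em_reml_diag
from .genio import MarkerPanel


@dataclass
class KernelSet:
    K: np.ndarray            # additive relationship, trace n
    Q: np.ndarray            # additive-by-additive relationship, trace n
    alpha_K: float
    alpha_Q: float
    individual_ids: np.ndarray | None = None


@dataclass
class SnpBlupResult:
    mu: float
    effects: np.ndarray      # one per fitted marker
    marker_ids: np.ndarray
    sigma2_a: float
    sigma2_eps: float
    h2: float
    converged: bool


def center_markers(panel: MarkerPanel, freq: np.ndarray | None = None) -> np.ndarray:
    """Centered marker matrix M with M[i,j] = code[i,j] - 2 p_j."""
    if panel.has_missing:
        raise ValueError(
            "panel has missing calls; run genio.impute_and_filter first"
        )
    X = panel.genotypes.astype(float)
    p = panel.allele_freq if freq is None else np.asarray(freq, float)
    return X - 2.0 * p


def build_kernels(M: np.ndarray, individual_ids: np.ndarray | None = None) -> KernelSet:
    """Additive (K) and epistatic (Q) kernels from a centered marker matrix."""
    n = M.shape[0]
    G = M @ M.T
    trG = float(np.trace(G))
    if trG <= 0:
        raise ValueError("trace(MM') is zero: all markers are monomorphic")
    alpha_K = n / trG
    H = G * G
    trH = float(np.trace(H))
    alpha_Q = n / trH
    return KernelSet(K=G * alpha_K, Q=H * alpha_Q, alpha_K=alpha_K,
                     alpha_Q=alpha_Q, individual_ids=individual_ids)


def h2_from_components(sigma2_a: float, sigma2_eps: float, het_sum: float) -> float:
    """h2 = s2a * het_sum / (s2a * het_sum + s2eps) for a given
    heterozygosity sum (2 sum p(1-p) under HWE)."""
    return sigma2_a * het_sum / (sigma2_a * het_sum + sigma2_eps)


def snp_blup_h2(y: np.ndarray, panel: MarkerPanel,
                subset: np.ndarray | list | None = None,
                het: str = "realized",
                tol: float = 1e-9, max_iter: int = 5000) -> SnpBlupResult:
    """Ridge-type SNP-BLUP with REML variances and the h2 ratio.

    ``subset`` optionally restricts the model to a set of marker ids (the
    QTL-subset scenario); variances are re-estimated on the subset and the
    heterozygosity sum runs over the fitted markers only.

    ``het`` selects the heterozygosity sum scaling sigma2_a to genetic
    variance: ``"realized"`` (default) uses the realized marker-variance
    sum tr(M'M)/n, which equals the textbook ``2 sum_j p_j (1-p_j)``
    under Hardy-Weinberg but remains correct for inbred RIL panels (where
    per-marker variance approaches ``4 p q``); ``"hwe"`` applies the
    textbook sum literally.
    """
    y = np.asarray(y, float)
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("empty marker subset")
        idx = [panel.marker_index(s) for s in subset]
        panel = panel.subset_markers(np.asarray(idx, int))
    if len(y) != panel.n_individuals:
        raise ValueError("y length does not match panel individuals")
    p = panel.allele_freq
    M = center_markers(panel)
    n, m = M.shape
    # rotate into the eigenbasis of MM' via SVD of M (cheap when m < n)
    U, sv, Vt = np.linalg.svd(M, full_matrices=True)
    d = np.zeros(n)
    d[: len(sv)] = sv ** 2          # eigenvalues of MM'
    yt = U.T @ y
    Xt = (U.T @ np.ones(n))[:, None]
    res = em_reml_diag(yt, Xt, [d, np.ones(n)], tol=tol, max_iter=max_iter)
    s2a, s2e = float(res.sigma2[0]), float(res.sigma2[1])
    if het == "hwe":
        het_sum = 2.0 * float(np.sum(p * (1.0 - p)))
    elif het == "realized":
        het_sum = float(M.var(axis=0).sum())
    else:
        raise ValueError(f"het must be 'realized' or 'hwe', got {het!r}")
    h2 = h2_from_components(s2a, s2e, het_sum)
    # marker effects: a = sigma_a^2 M' P y (BLUP identity), in rotated space
    Py = res.Py
    effects = s2a * (Vt[: len(sv)].T @ (sv * Py[: len(sv)]))
    mu = float(res.beta[0])
    return SnpBlupResult(
        mu=mu, effects=effects, marker_ids=panel.marker_ids,
        sigma2_a=s2a, sigma2_eps=s2e, h2=float(h2), converged=res.converged,
    )
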