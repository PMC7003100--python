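"""Polygenic variance decomposition, genetic correlations and indirect selection.

The G2A model decomposes deregressed genetic values into an additive term
over the additive kernel K, an additive-by-additive epistatic term over its
Hadamard-square kernel Q, and iid residuals:

    y = mu + psi + omega + eps,   psi ~ N(0, K s2_psi),  omega ~ N(0, Q s2_omega).

Decompositions are usually run within family, with kernels rebuilt from the
family's own allele frequencies so across-family structure does not leak
into the within-family components.

Bivariate GBLUP gives the additive genetic correlation between two traits
(pleiotropy) or one trait in two years (stability):

    rho_psi = sigma_psi(1,2) / [sigma_psi(1) sigma_psi(2)],

plus the Pearson correlation of the two BLUP vectors as the (total)
"genetic correlation".  The efficiency of indirect selection on trait i for
trait j defaults to the literal ratio E = rho * h2_i / h2_j; the Falconer
convention E = rho * h_i / h_j is available via ``convention="falconer"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import em_bivariate, em_reml, BivariateREMLResult
from .genio import MarkerPanel
from .grm import KernelSet, build_kernels, center_markers

MIN_FAMILY_SIZE = 10


@dataclass
class VarCompResult:
    group: str | None
    sigma2_psi: float
    sigma2_omega: float
    sigma2_eps: float
    n: int
    loglik: float
    converged: bool

    @property
    def proportions(self) -> dict:
        tot = self.sigma2_psi + self.sigma2_omega + self.sigma2_eps
        return {
            "additive": self.sigma2_psi / tot,
            "epistatic": self.sigma2_omega / tot,
            "residual": self.sigma2_eps / tot,
        }


@dataclass
class BivariateResult:
    Sigma_psi: np.ndarray
    Sigma_eps: np.ndarray
    rho_psi: float               # additive genetic correlation
    rho_blup: float              # Pearson correlation of the BLUP vectors
    degenerate: bool
    n: int
    converged: bool
    psi_blup: np.ndarray = field(repr=False, default=None)


def fit_g2a(y: np.ndarray, kernels: KernelSet | None = None,
            panel: MarkerPanel | None = None,
            groups: np.ndarray | None = None,
            max_iter: int = 2000, tol: float = 1e-8):
    """Three-component REML (K, Q, identity) fit of the G2A model.

    Pooled fit: pass precomputed ``kernels`` (and ``groups=None``).
    Per-family fit: pass the marker ``panel`` and per-individual ``groups``;
    kernels are then rebuilt within each family from that family's markers
    and allele frequencies.  Families smaller than ``MIN_FAMILY_SIZE`` are
    skipped with a warning.
    """
    y = np.asarray(y, float)
    if groups is None:
        if kernels is None:
            if panel is None:
                raise ValueError("need kernels or panel")
            kernels = build_kernels(center_markers(panel))
        return _fit_g2a_one(y, kernels, None, max_iter, tol)
    if panel is None:
        raise ValueError("per-group fits need the marker panel")
    groups = np.asarray(groups)
    results = []
    for fam in pd.unique(groups):
        idx = np.flatnonzero(groups == fam)
        if len(idx) < MIN_FAMILY_SIZE:
            warnings.warn(f"family {fam!r} has {len(idx)} < {MIN_FAMILY_SIZE} "
                          "individuals; skipped")
            continue
        sub = panel.subset_individuals(idx)
        poly = np.minimum(sub.allele_freq, 1 - sub.allele_freq) > 0
        sub = sub.subset_markers(poly)
        ks = build_kernels(center_markers(sub))
        results.append(_fit_g2a_one(y[idx], ks, str(fam), max_iter, tol))
    return results


def _fit_g2a_one(y, kernels: KernelSet, group, max_iter, tol) -> VarCompResult:
    n = len(y)
    X = np.ones((n, 1))
    res = em_reml(y, X, [kernels.K, kernels.Q, np.eye(n)],
                  tol=tol, max_iter=max_iter)
    return VarCompResult(
        group=group,
        sigma2_psi=float(res.sigma2[0]),
        sigma2_omega=float(res.sigma2[1]),
        sigma2_eps=float(res.sigma2[2]),
        n=n, loglik=res.loglik, converged=res.converged,
    )


def fit_bivariate(y1: np.ndarray, y2: np.ndarray, K: np.ndarray,
                  diagonal_psi: bool = False,
                  max_iter: int = 5000, tol: float = 1e-11) -> BivariateResult:
    """Bivariate GBLUP REML with dense genetic and diagonal residual covariance."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if y1.shape != y2.shape or len(y1) != K.shape[0]:
        raise ValueError("y1, y2 and K must be aligned on the same individuals")
    w, U = np.linalg.eigh(K)
    w = np.maximum(w, 0.0)
    fit: BivariateREMLResult = em_bivariate(
        np.column_stack([y1, y2]), w, U,
        diagonal_psi=diagonal_psi, max_iter=max_iter, tol=tol)
    if fit.degenerate:
        warnings.warn("near-singular genetic covariance: correlation is "
                      "reported with a degeneracy flag")
    b1, b2 = fit.psi_blup[:, 0], fit.psi_blup[:, 1]
    if b1.std() > 0 and b2.std() > 0:
        rho_blup = float(np.corrcoef(b1, b2)[0, 1])
    else:
        rho_blup = float("nan")
    return BivariateResult(
        Sigma_psi=fit.Sigma_psi, Sigma_eps=fit.Sigma_eps,
        rho_psi=fit.rho, rho_blup=rho_blup, degenerate=fit.degenerate,
        n=len(y1), converged=fit.converged, psi_blup=fit.psi_blup,
    )


def indirect_efficiency(h2_i: float, h2_j: float, rho: float,
                        convention: str = "literal") -> float:
    """Efficiency of indirect selection on trait i to improve trait j.

    ``literal``  : E = rho * h2_i / h2_j  (squared-heritability ratio)
    ``falconer`` : E = rho * h_i / h_j    (square-root ratio)
    """
    if h2_j <= 0:
        raise ValueError("h2_j must be > 0: direct selection response undefined")
    if h2_i < 0:
        raise ValueError("h2_i must be >= 0")
    if convention == "literal":
        return rho * h2_i / h2_j
    if convention == "falconer":
        return rho * np.sqrt(h2_i / h2_j)
    raise ValueError(f"unknown convention {convention!r}")


def stability_correlations(merit_by_year: dict, K: np.ndarray,
                           ids: np.ndarray) -> pd.DataFrame:
    """Genetic correlation of one trait with itself across year pairs.

    ``merit_by_year`` maps year -> deregressed values indexed by genotype id
    (pandas Series); all year pairs are fitted and reported.
    """
    years = sorted(merit_by_year)
    rows = []
    for i, yr1 in enumerate(years):
        for yr2 in years[i + 1:]:
            s1 = merit_by_year[yr1].reindex(ids)
            s2 = merit_by_year[yr2].reindex(ids)
            ok = s1.notna().to_numpy() & s2.notna().to_numpy()
            res = fit_bivariate(s1.to_numpy()[ok], s2.to_numpy()[ok],
                                K[np.ix_(ok.nonzero()[0], ok.nonzero()[0])])
            rows.append({
                "year_1": yr1, "year_2": yr2, "n": res.n,
                "rho_psi": res.rho_psi, "rho_blup": res.rho_blup,
                "degenerate": res.degenerate,
            })
    return pd.DataFrame(rows)
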