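"""Tri-method genome scan for NAM panels.

Three complementary association methods, each with its own significance
rule:

- **MLM** — family-nested marker effects tested by a likelihood ratio
  against a polygenic null ``y = mu + psi + e`` with ``psi ~ N(0, K s2)``.
  The marker design X has one column per family in which the marker
  segregates; the common within-family effect variance ``sigma2_beta`` is
  estimated per marker by profile REML with the null components held fixed.
  Significance: Bonferroni, ``-log10(0.025 / m)``.
- **WGR (BayesCpi)** — spike-and-slab whole-genome regression; the
  statistic is ``-log10(1 - model frequency)`` against ``-log10(0.025)``.
- **RFR** — random-forest regression importance (impurity index) with a
  global empirical threshold: the (1 - alpha) quantile of the maximum
  importance over phenotype permutations.

``qtl_effects`` reports least-squares allele-substitution effects of
significant markers on each trait, with family means removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._gibbs import wgr_sample
from ._reml import em_reml_diag
from .genio import MarkerPanel
from .grm import center_markers


@dataclass
class ScanResult:
    method: str
    table: pd.DataFrame        # marker, chrom, pos, statistic, threshold, significant, tested
    threshold: float
    extras: dict = field(default_factory=dict)

    @property
    def significant_markers(self) -> np.ndarray:
        t = self.table
        return t.loc[t.significant, "marker"].to_numpy()


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Two-sided Bonferroni threshold on the -log10(p) scale."""
    return float(-np.log10(alpha / 2.0 / n_markers))


def wgr_threshold(alpha: float = 0.05) -> float:
    """Two-sided model-frequency threshold on the -log10 scale."""
    return float(-np.log10(alpha / 2.0))


def _scan_frame(panel: MarkerPanel, statistic, threshold, tested) -> pd.DataFrame:
    pos_col = "bp" if "bp" in panel.map.table.columns else "cm"
    return pd.DataFrame({
        "marker": panel.marker_ids.astype(str),
        "chrom": panel.map.chrom,
        "pos": panel.map.table[pos_col].to_numpy(),
        "statistic": statistic,
        "threshold": threshold,
        "significant": (statistic > threshold) & tested,
        "tested": tested,
    })


def scan_mlm(y: np.ndarray, panel: MarkerPanel, K: np.ndarray,
             alpha: float = 0.05) -> ScanResult:
    """Family-nested mixed-model likelihood-ratio scan."""
    y = np.asarray(y, float)
    n, m = panel.genotypes.shape
    if len(y) != n or K.shape != (n, n):
        raise ValueError("y, panel and K must be aligned")
    w, U = np.linalg.eigh(K)
    if w.min() < 1e-8:
        w = w + 1e-6
    yt = U.T @ y
    x0 = U.T @ np.ones(n)
    null = em_reml_diag(yt, x0[:, None], [w, np.ones(n)])
    s2psi, s2e = null.sigma2
    Dv = s2psi * w + s2e
    ll_null = null.loglik

    fams, fam_idx = np.unique(panel.family, return_inverse=True)
    codes = panel.genotypes.astype(float)
    # rotated family-nested marker columns, one n x m array per family
    Xrot = []
    seg = np.zeros((len(fams), m), dtype=bool)
    for f in range(len(fams)):
        rows = fam_idx == f
        seg[f] = codes[rows].std(axis=0) > 0
        masked = np.where(rows[:, None], codes, 0.0)
        Xrot.append(U.T @ masked)

    iD = 1.0 / Dv
    yD = yt * iD
    x0D = x0 * iD
    q_yy0 = float(yt @ yD)
    q_00_0 = float(x0 @ x0D)
    q_0y0 = float(x0 @ yD)
    vary = float(np.var(y))

    def ll_marker(Xt, s2b):
        f = Xt.shape[1]
        A = Xt.T @ (Xt * iD[:, None])
        bX = Xt.T @ yD
        b0 = Xt.T @ x0D
        if s2b <= 0:
            return ll_null
        Wm = np.linalg.inv(np.eye(f) / s2b + A)
        q_yy = q_yy0 - bX @ Wm @ bX
        q_00 = q_00_0 - b0 @ Wm @ b0
        q_0y = q_0y0 - b0 @ Wm @ bX
        sign, ld = np.linalg.slogdet(np.eye(f) + s2b * A)
        logdetV = np.log(Dv).sum() + ld
        return float(-0.5 * (logdetV + np.log(q_00) + q_yy - q_0y ** 2 / q_00))

    stat = np.zeros(m)
    tested = np.zeros(m, dtype=bool)
    for j in range(m):
        which = np.flatnonzero(seg[:, j])
        if len(which) == 0:
            continue
        tested[j] = True
        Xt = np.column_stack([Xrot[f][:, j] for f in which])
        res = optimize.minimize_scalar(
            lambda s: -ll_marker(Xt, s), bounds=(0.0, 50.0 * vary),
            method="bounded", options={"xatol": 1e-8})
        lrt = max(2.0 * (-res.fun - ll_null), 0.0)
        p = stats.chi2.sf(lrt, df=1)
        stat[j] = -np.log10(max(p, 1e-300))
    thr = bonferroni_threshold(m, alpha)
    return ScanResult(
        method="MLM",
        table=_scan_frame(panel, stat, thr, tested),
        threshold=thr,
        extras={"sigma2_psi": float(s2psi), "sigma2_e": float(s2e)},
    )


def scan_bayescpi(y: np.ndarray, panel: MarkerPanel,
                  mcmc: tuple[int, int, int] = (20000, 2000, 0),
                  nu0: float = 5.0, alpha: float = 0.05) -> ScanResult:
    """BayesCpi model-frequency scan.

    Statistic: ``-log10(1 - model frequency)`` per marker, against the
    two-sided threshold ``-log10(alpha/2)``.
    """
    iters, burnin, seed = mcmc
    M = center_markers(panel)
    fit = wgr_sample(np.asarray(y, float), M, iters, burnin, seed,
                     nu0=nu0, pi_null=0.5, estimate_pi=True,
                     per_marker_var=False)
    freq = np.clip(fit.model_freq, 0.0, 1.0)
    stat = -np.log10(np.maximum(1.0 - freq, 1e-12))
    tested = M.std(axis=0) > 0
    thr = wgr_threshold(alpha)
    return ScanResult(
        method="WGR",
        table=_scan_frame(panel, stat, thr, tested),
        threshold=thr,
        extras={"model_freq": freq, "pi_null": fit.pi_null,
                "effects": fit.effects, "sigma2_e": fit.sigma2_e},
    )


def scan_rfr(y: np.ndarray, panel: MarkerPanel,
             forest: tuple[int, int, int] = (10000, 65, 0),
             n_perm: int = 1000, alpha: float = 0.05) -> ScanResult:
    """Random-forest importance scan with a permutation-based global threshold."""
    from sklearn.ensemble import RandomForestRegressor

    n_trees, mtry, seed = forest
    y = np.asarray(y, float)
    X = panel.genotypes.astype(float)
    m = X.shape[1]
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if mtry > m:
        raise ValueError(f"mtry ({mtry}) exceeds marker count ({m})")
    rng = np.random.default_rng(seed)

    def importances(target, rs):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, random_state=rs, n_jobs=1)
        rf.fit(X, target)
        return rf.feature_importances_

    imp = importances(y, seed)
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(y)
        maxima[k] = importances(perm, seed + 1 + k).max()
    thr = float(np.quantile(maxima, 1.0 - alpha))
    tested = X.std(axis=0) > 0
    return ScanResult(
        method="RFR",
        table=_scan_frame(panel, imp, thr, tested),
        threshold=thr,
        extras={"perm_maxima": maxima},
    )


def qtl_effects(y_traits: pd.DataFrame, panel: MarkerPanel,
                hits: list[str]) -> pd.DataFrame:
    """Least-squares allele-substitution effects of hit markers on each trait.

    Both the trait and the marker code are centered within family before
    the regression, so family means carry no weight.  ``effect`` is per
    copy of the counted (alternate-founder) allele; ``effect_founder_neg``
    flips the sign so that negative values indicate a trait-increasing
    allele inherited from the alternate founder (field reporting
    convention).
    """
    if len(hits) == 0:
        raise ValueError("no hit markers supplied")
    fam = pd.Series(panel.family)
    rows = []
    for hit in hits:
        j = panel.marker_index(hit)  # raises KeyError if absent
        x = pd.Series(panel.genotypes[:, j].astype(float))
        xc = x - x.groupby(fam).transform("mean")
        for trait in y_traits.columns:
            yv = pd.Series(np.asarray(y_traits[trait], float))
            ok = yv.notna()
            yc = yv - yv.groupby(fam).transform("mean")
            denom = float((xc[ok] ** 2).sum())
            beta = float((xc[ok] * yc[ok]).sum() / denom) if denom > 0 else np.nan
            rows.append({"marker": hit, "trait": trait, "effect": beta,
                         "effect_founder_neg": -beta if np.isfinite(beta) else np.nan})
    return pd.DataFrame(rows)


def consensus_table(scans: dict[str, ScanResult]) -> pd.DataFrame:
    """Union bookkeeping of per-method significance flags.

    Returns one row per marker significant in at least one scan, with a
    ``methods`` column listing the detecting methods.
    """
    per_marker: dict[str, set] = {}
    for name, scan in scans.items():
        for mk in scan.significant_markers:
            per_marker.setdefault(mk, set()).add(name)
    any_scan = next(iter(scans.values()))
    t = any_scan.table.set_index("marker")
    rows = []
    for mk, methods in per_marker.items():
        rows.append({
            "marker": mk,
            "chrom": t.loc[mk, "chrom"],
            "pos": t.loc[mk, "pos"],
            "methods": ",".join(sorted(methods)),
            "n_methods": len(methods),
        })
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True) \
        if rows else pd.DataFrame(columns=["marker", "chrom", "pos", "methods", "n_methods"])
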