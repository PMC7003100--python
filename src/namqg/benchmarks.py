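"""Parameter-recovery and operating-characteristic scenarios.

Each function simulates data under known truth with the synthetic NAM
generator, runs the corresponding analysis stage, and returns the raw
per-seed measurements.  They define the package's evaluation suite:
heritability recovery, additive/epistatic decomposition recovery,
bivariate genetic-correlation recovery, MLM detection power, BayesCpi and
random-forest null behavior, and the cross-validation scheme structure.

Problem sizes are scaled-down study conditions chosen so each scenario
runs in minutes on one CPU; seed counts are arguments so callers can
trade precision for time.
"""

from __future__ import annotations

import numpy as np

from . import gpred, grm, gwas, simnam, vc

H2_TARGET = 0.30
G2A_TARGET = (0.25, 0.25)
RHO_TARGET = 0.40
QTL_VARIANCE = 0.10


def _seed_seq(seed: int, tag: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence([seed, tag]).generate_state(n) % (2 ** 31)]


def h2_recovery(n_seeds: int = 10, seed: int = 0) -> list[float]:
    """SNP-BLUP h2 estimates on traits simulated at h2 = 0.30 (n = 2000)."""
    out = []
    for s in _seed_seq(seed, 1, n_seeds):
        cfg = simnam.SimConfig(
            n_families=20, n_ril_per_family=100, n_chrom=5,
            markers_per_chrom=100, n_environments=1,
            h2_additive_target=H2_TARGET, h2_epistatic_target=0.0,
            gxe_sd=0.0, spatial_gradient_sd=0.0, n_qtl_additive=50, seed=s)
        panel, plots, _, _ = simnam.simulate(cfg)
        y = (plots[plots.is_check == 0].set_index("id")["trait"]
             .reindex(panel.individual_ids).to_numpy(float))
        out.append(grm.snp_blup_h2(y, panel).h2)
    return out


def g2a_recovery(n_seeds: int = 10, seed: int = 0) -> list[tuple[float, float]]:
    """G2A (additive, epistatic) proportion estimates at truth (0.25, 0.25),
    n = 1000."""
    out = []
    for s in _seed_seq(seed, 2, n_seeds):
        cfg = simnam.SimConfig(
            n_families=10, n_ril_per_family=100, n_chrom=5,
            markers_per_chrom=60, n_environments=1,
            h2_additive_target=G2A_TARGET[0], h2_epistatic_target=G2A_TARGET[1],
            gxe_sd=0.0, spatial_gradient_sd=0.0,
            n_qtl_additive=20, n_qtl_epistatic_pairs=10, seed=s)
        panel, _, truth, _ = simnam.simulate(cfg)
        rng = np.random.default_rng(s + 1)
        noise_var = 1.0 - truth.true_h2_additive - truth.true_h2_epistatic
        y = truth.true_genetic_values + rng.normal(
            0, np.sqrt(max(noise_var, 1e-6)), panel.n_individuals)
        fit = vc.fit_g2a(y, kernels=grm.build_kernels(grm.center_markers(panel)))
        p = fit.proportions
        out.append((p["additive"], p["epistatic"]))
    return out


def bivariate_recovery(n_seeds: int = 10, seed: int = 0,
                       rho: float = RHO_TARGET, n_target: int = 800) -> list[float]:
    """Bivariate GBLUP correlation estimates at true additive rho = 0.4."""
    out = []
    for s in _seed_seq(seed, 3, n_seeds):
        cfg = simnam.SimConfig(
            n_families=8, n_ril_per_family=n_target // 8, n_chrom=5,
            markers_per_chrom=60, n_environments=1,
            h2_additive_target=0.4, h2_epistatic_target=0.0,
            gxe_sd=0.0, spatial_gradient_sd=0.0, seed=s)
        panel, _, _, _ = simnam.simulate(cfg)
        K = grm.build_kernels(grm.center_markers(panel)).K
        n = K.shape[0]
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        rng = np.random.default_rng(s + 1)
        g1 = L @ rng.normal(size=n)
        g2 = rho * g1 + np.sqrt(1 - rho ** 2) * (L @ rng.normal(size=n))
        y1 = g1 + rng.normal(0, np.sqrt(1.5), n)
        y2 = g2 + rng.normal(0, np.sqrt(1.5), n)
        out.append(vc.fit_bivariate(y1, y2, K).rho_psi)
    return out


def mlm_power(n_seeds: int = 10, seed: int = 0) -> list[dict]:
    """Detection and localization of a planted QTL (10% of variance) by the
    family-nested MLM scan at n = 1500, m = 500."""
    out = []
    for s in _seed_seq(seed, 4, n_seeds):
        cfg = simnam.SimConfig(
            n_families=10, n_ril_per_family=150, n_chrom=5,
            markers_per_chrom=100, n_environments=1,
            h2_additive_target=0.0, h2_epistatic_target=0.0,
            gxe_sd=0.0, spatial_gradient_sd=0.0, seed=s)
        panel, _, _, _ = simnam.simulate(cfg)
        M = grm.center_markers(panel)
        rng = np.random.default_rng(s + 1)
        # plant mid-genome at a broadly segregating marker
        fams = panel.family
        n_seg = np.array([
            sum(panel.genotypes[fams == f, j].std() > 0 for f in np.unique(fams))
            for j in range(panel.n_markers)])
        mid = panel.n_markers // 2
        cands = np.flatnonzero(n_seg >= max(n_seg.max() - 1, 1))
        qtl = int(cands[np.argmin(np.abs(cands - mid))])
        x = M[:, qtl]
        beta = np.sqrt(QTL_VARIANCE / x.var() / (1 - QTL_VARIANCE))
        y = x * beta + rng.normal(0, 1.0, panel.n_individuals)
        scan = gwas.scan_mlm(y, panel, grm.build_kernels(M).K)
        stat = scan.table.statistic
        peak = int(stat.idxmax())
        out.append({
            "detected": bool(stat[peak] > scan.threshold),
            "within_5": bool(abs(peak - qtl) <= 5),
            "peak_stat": float(stat[peak]),
        })
    return out


def bayescpi_null_fpr(n_seeds: int = 10, seed: int = 0,
                      mcmc: tuple[int, int] = (5000, 500)) -> list[float]:
    """Per-scan fraction of null markers flagged by BayesCpi (n=500, m=200)."""
    out = []
    for s in _seed_seq(seed, 5, n_seeds):
        cfg = simnam.SimConfig(
            n_families=5, n_ril_per_family=100, n_chrom=4,
            markers_per_chrom=50, n_environments=1,
            h2_additive_target=0.0, h2_epistatic_target=0.0,
            gxe_sd=0.0, spatial_gradient_sd=0.0, seed=s)
        panel, _, _, _ = simnam.simulate(cfg)
        rng = np.random.default_rng(s + 1)
        y = rng.normal(size=panel.n_individuals)
        scan = gwas.scan_bayescpi(y, panel, mcmc=(mcmc[0], mcmc[1], s))
        t = scan.table
        out.append(float(t.significant.sum() / t.tested.sum()))
    return out


def rfr_null_rate(n_scans: int = 8, seed: int = 0, n_trees: int = 500,
                  n_perm: int = 100, alpha: float = 0.05) -> list[bool]:
    """Whether each null random-forest scan flags any marker at the
    permutation threshold (expected rate <= alpha)."""
    cfg = simnam.SimConfig(
        n_families=3, n_ril_per_family=40, n_chrom=3, markers_per_chrom=20,
        n_environments=1, h2_additive_target=0.0, h2_epistatic_target=0.0,
        gxe_sd=0.0, spatial_gradient_sd=0.0, seed=seed)
    panel, _, _, _ = simnam.simulate(cfg)
    mtry = max(int(np.sqrt(panel.n_markers)), 2)
    hits = []
    for s in _seed_seq(seed, 6, n_scans):
        rng = np.random.default_rng(s)
        y = rng.normal(size=panel.n_individuals)
        scan = gwas.scan_rfr(y, panel, forest=(n_trees, mtry, s),
                             n_perm=n_perm, alpha=alpha)
        hits.append(bool(scan.table.significant.any()))
    return hits


def cv_structure(n_seeds: int = 10, seed: int = 0, reps: int = 5,
                 models: tuple[str, ...] = ("GBLUP",),
                 mcmc: tuple[int, int] = (5000, 500)) -> list[dict]:
    """Mean predictive ability per scheme and model on a structured NAM trait
    (5 families x 100 RILs, 500 markers)."""
    out = []
    for s in _seed_seq(seed, 7, n_seeds):
        cfg = simnam.SimConfig(
            n_families=5, n_ril_per_family=100, n_chrom=5,
            markers_per_chrom=100, n_environments=1,
            h2_additive_target=H2_TARGET, h2_epistatic_target=0.0,
            gxe_sd=0.0, spatial_gradient_sd=0.0, n_qtl_additive=30, seed=s)
        panel, plots, _, _ = simnam.simulate(cfg)
        y = (plots[plots.is_check == 0].set_index("id")["trait"]
             .reindex(panel.individual_ids).to_numpy(float))
        K = grm.build_kernels(grm.center_markers(panel)).K
        cell = {}
        for model in models:
            for scheme in gpred.SCHEMES:
                r = gpred.cross_validate(
                    y, panel, K, scheme, model, folds=5, reps=reps, seed=s,
                    mcmc=(mcmc[0], mcmc[1], s))
                cell[(model, scheme)] = r.mean_pa
        out.append(cell)
    return out
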