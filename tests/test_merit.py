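"""Spatial covariate, environment weights and the stage-1 mixed model."""

import numpy as np
import pandas as pd
import pytest

from namqg import merit, simnam
from namqg.merit import (broad_sense_H, deregress, env_weights, fit_merit,
                         spatial_covariate)
from tests.oracles import grid_search_reml, restricted_ll


def grid_plots(values, env="e1", block=1):
    """One rectangular block laid out row-major from a 2-D value array."""
    values = np.asarray(values, float)
    nr, nc = values.shape
    rows, cols = np.divmod(np.arange(nr * nc), nc)
    return pd.DataFrame({
        "id": [f"g{i}" for i in range(nr * nc)], "family": "f1", "env": env,
        "year": 2013, "loc": "A", "block": block, "row": rows, "col": cols,
        "is_check": 0, "trait": values.ravel(),
    })


class TestSpatialCovariate:
    def test_center_of_three_by_three(self):
        plots = grid_plots(np.arange(1.0, 10.0).reshape(3, 3))
        cov = spatial_covariate(plots, "trait", window=(1, 1))
        center = (plots.row == 1) & (plots.col == 1)
        assert cov[center.to_numpy()][0] == pytest.approx(np.mean([1, 2, 3, 4, 6, 7, 8, 9]))

    def test_constant_field(self):
        plots = grid_plots(np.full((4, 4), 7.0))
        cov = spatial_covariate(plots, "trait")
        np.testing.assert_allclose(cov, 7.0)

    def test_single_plot_block_gets_block_mean(self):
        plots = grid_plots(np.array([[3.5]]))
        cov = spatial_covariate(plots, "trait")
        assert cov[0] == pytest.approx(3.5)

    def test_missing_trait_raises(self):
        with pytest.raises(KeyError):
            spatial_covariate(grid_plots(np.ones((2, 2))), "nope")


class TestEnvWeights:
    def test_inverse_variance_definition(self):
        a = grid_plots(np.array([[0.0, 2.0]]), env="e1")      # var 2
        b = grid_plots(np.array([[0.0, 4.0]]), env="e2")      # var 8
        plots = pd.concat([a, b], ignore_index=True)
        w = env_weights(plots, "trait")
        np.testing.assert_allclose(w[:2], 1.0 / 2.0)
        np.testing.assert_allclose(w[2:], 1.0 / 8.0)
        assert w[0] / w[2] == pytest.approx(4.0)

    def test_equal_variance_envs_get_equal_weights(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        a = grid_plots(base.reshape(3, 4), env="e1")
        b = grid_plots((base + 100.0).reshape(3, 4), env="e2")  # shifted mean only
        w = env_weights(pd.concat([a, b], ignore_index=True), "trait")
        assert w[0] == pytest.approx(w[12])

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero"):
            env_weights(grid_plots(np.full((2, 3), 1.0)), "trait")


class TestFormulas:
    def test_broad_sense_arithmetic(self):
        assert broad_sense_H(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_deregression_arithmetic(self):
        assert deregress(np.array([0.2]), np.array([0.4]))[0] == pytest.approx(0.5)
        assert np.isnan(deregress(np.array([0.2]), np.array([0.0]))[0])


def two_env_plots(n_geno=12, reps=2, seed=4, s2u=1.0, s2g=0.5, s2e=1.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s2u), n_geno)
    frames = []
    for e in range(reps):
        g = rng.normal(0, np.sqrt(s2g))
        vals = u + g + rng.normal(0, np.sqrt(s2e), n_geno)
        nc = 4
        rows, cols = np.divmod(np.arange(n_geno), nc)
        frames.append(pd.DataFrame({
            "id": [f"g{i}" for i in range(n_geno)], "family": "f1",
            "env": f"e{e}", "year": 2013 + e, "loc": "A", "block": 1,
            "row": rows, "col": cols, "is_check": 0, "trait": vals,
        }))
    return pd.concat(frames, ignore_index=True)


class TestFitMerit:
    def test_em_matches_grid_search_oracle(self):
        # 30 plots, genotype + block + residual components: EM-REML must
        # land within one 1e-3 grid step of the exhaustive grid optimum
        plots = two_env_plots(n_geno=15, reps=2, seed=8)
        fit = fit_merit(plots, "trait")
        y = plots["trait"].to_numpy()
        n = len(y)
        ids, idx = np.unique(plots["id"], return_inverse=True)
        Z = np.eye(len(ids))[idx]
        envs, eidx = np.unique(plots["env"], return_inverse=True)
        W = np.eye(len(envs))[eidx]
        kernels = [Z @ Z.T, W @ W.T, np.eye(n)]
        X = np.ones((n, 1))
        best, best_ll = grid_search_reml(y, X, kernels, upper=3.0 * y.var())
        est = np.array([fit.sigma2_u, fit.sigma2_g, fit.sigma2_e])
        assert np.all(np.abs(est - best) <= 2e-3 + 1e-6 * best)

    def test_unweighted_oracle_with_equal_weights(self):
        # equal weights and no spatial covariate: identical fit to the
        # unweighted model (weights enter only as relative precisions)
        plots = two_env_plots(seed=9)
        f1 = fit_merit(plots, "trait")
        f2 = fit_merit(plots, "trait", weights=np.full(len(plots), 3.7))
        assert f1.sigma2_u == pytest.approx(f2.sigma2_u, rel=1e-8)
        assert f1.H == pytest.approx(f2.H, rel=1e-8)

    def test_single_env_weights_are_noop(self):
        plots = two_env_plots(reps=1, seed=10)
        w = env_weights(plots, "trait")
        f1 = fit_merit(plots, "trait")
        f2 = fit_merit(plots, "trait", weights=w)
        assert f1.sigma2_u == pytest.approx(f2.sigma2_u, rel=1e-8)

    def test_shrinkage_property(self):
        plots = two_env_plots(seed=12)
        fit = fit_merit(plots, "trait")
        t = fit.table[fit.table.reliability > 0]
        assert t.blup.var() <= t.deregressed.var() + 1e-12

    def test_H_scale_invariance(self):
        plots = two_env_plots(seed=13)
        f1 = fit_merit(plots, "trait")
        scaled = plots.assign(trait=plots.trait * 7.3)
        f2 = fit_merit(scaled, "trait")
        assert f1.H == pytest.approx(f2.H, rel=1e-6)
        assert f2.sigma2_u == pytest.approx(f1.sigma2_u * 7.3 ** 2, rel=1e-6)

    def test_H_recovery_on_simulated_population(self):
        # generator configured for entry-mean H ~= 0.35 over 6 environments
        errs = []
        for seed in range(3):
            cfg = simnam.SimConfig(
                n_families=3, n_ril_per_family=60, n_chrom=2,
                markers_per_chrom=40, n_environments=6,
                h2_additive_target=0.082, h2_epistatic_target=0.0,
                gxe_sd=0.0, spatial_gradient_sd=0.2, seed=seed)
            panel, plots, truth, _ = simnam.simulate(cfg)
            cov = merit.spatial_covariate(plots, "trait")
            w = merit.env_weights(plots, "trait")
            fit = fit_merit(plots, "trait", covariate=cov, weights=w)
            errs.append(fit.H - truth.broad_sense_H)
        assert abs(np.mean(errs)) < 0.07

    def test_spatial_covariate_absorbs_field_trend(self):
        cfg = simnam.SimConfig(
            n_families=2, n_ril_per_family=60, n_chrom=2, markers_per_chrom=30,
            n_environments=2, h2_additive_target=0.3, h2_epistatic_target=0.0,
            gxe_sd=0.0, spatial_gradient_sd=0.6, seed=31)
        panel, plots, truth, _ = simnam.simulate(cfg)
        cov = merit.spatial_covariate(plots, "trait")
        with_cov = fit_merit(plots, "trait", covariate=cov)
        without = fit_merit(plots, "trait")
        g = truth.true_genetic_values
        ids = panel.individual_ids
        r_with = np.corrcoef(
            with_cov.table.set_index("id").blup.reindex(ids).to_numpy(float), g)[0, 1]
        r_without = np.corrcoef(
            without.table.set_index("id").blup.reindex(ids).to_numpy(float), g)[0, 1]
        assert r_with > r_without
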