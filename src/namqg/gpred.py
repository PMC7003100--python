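"""Genomic prediction and cross-validation geometries.

Two models: GBLUP (ridge regression on the genomic relationship matrix,
REML variance components) and BayesB (spike-and-slab marker regression
with fixed null probability pi = 0.95 and per-marker variances).

Three cross-validation schemes probe different sources of information:

- ``across_family``  — folds over the whole panel: relationship + LD.
- ``within_family``  — folds within each family, trained on that family
  only: LD with QTL segregating in the family.
- ``leave_family_out`` — train on all other families, predict the held-out
  family: relatedness of untested families.

Predictive ability (PA) is the Pearson correlation between predicted and
observed (deregressed) genetic values in the held-out set; within-family
and leave-family-out PAs are computed within family, never pooled, to
avoid inflation by family means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._gibbs import wgr_sample
from ._reml import em_reml_diag
from .genio import MarkerPanel
from .grm import center_markers

SCHEMES = ("within_family", "across_family", "leave_family_out")
MODELS = ("GBLUP", "BayesB")


@dataclass
class GBLUPPredictor:
    mu: float
    alpha: np.ndarray          # weights on training rows of K
    train_idx: np.ndarray
    lambda_: float
    sigma2_u: float
    sigma2_e: float

    def predict(self, K: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        rows = np.arange(K.shape[0]) if idx is None else np.asarray(idx)
        return self.mu + K[np.ix_(rows, self.train_idx)] @ self.alpha


@dataclass
class BayesBPredictor:
    mu: float
    effects: np.ndarray
    inclusion: np.ndarray

    def predict(self, M: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        rows = M if idx is None else M[np.asarray(idx)]
        return self.mu + rows @ self.effects


@dataclass
class CVResult:
    scheme: str
    model: str
    trait: str
    records: pd.DataFrame      # unit (family or rep/fold), PA

    @property
    def mean_pa(self) -> float:
        return float(self.records["pa"].mean())

    @property
    def sd_pa(self) -> float:
        return float(self.records["pa"].std(ddof=1))


def fit_gblup(y_train: np.ndarray, K: np.ndarray, train_idx: np.ndarray,
              lambda_: float | None = None) -> GBLUPPredictor:
    """GBLUP on a training subset; predicts any individual via kernel rows.

    ``lambda_`` (= sigma_e^2 / sigma_u^2) is estimated by REML on the
    training subset unless given.
    """
    y_train = np.asarray(y_train, float)
    train_idx = np.asarray(train_idx)
    Ktt = K[np.ix_(train_idx, train_idx)]
    nt = len(train_idx)
    if lambda_ is None:
        w, U = np.linalg.eigh(Ktt)
        w = np.maximum(w, 0.0)
        res = em_reml_diag(U.T @ y_train, (U.T @ np.ones(nt))[:, None],
                           [w, np.ones(nt)])
        s2u, s2e = float(res.sigma2[0]), float(res.sigma2[1])
        lambda_ = s2e / max(s2u, 1e-12)
    else:
        s2u, s2e = float("nan"), float("nan")
    A = Ktt + lambda_ * np.eye(nt)
    mu = float(y_train.mean())
    try:
        alpha = np.linalg.solve(A, y_train - mu)
    except np.linalg.LinAlgError:
        alpha = np.linalg.solve(A + 1e-8 * np.eye(nt), y_train - mu)
    return GBLUPPredictor(mu=mu, alpha=alpha, train_idx=train_idx,
                          lambda_=float(lambda_), sigma2_u=s2u, sigma2_e=s2e)


def fit_bayesb(y_train: np.ndarray, M_train: np.ndarray,
               mcmc: tuple[int, int, int] = (5000, 500, 0),
               prior: tuple[float, float] = (0.95, 10.0)) -> BayesBPredictor:
    """BayesB Gibbs fit: fixed pi, per-marker scaled-inv-chi-square variances."""
    pi_null, nu0 = prior
    iters, burnin, seed = mcmc
    fit = wgr_sample(np.asarray(y_train, float), M_train, iters, burnin, seed,
                     nu0=nu0, pi_null=pi_null, estimate_pi=False,
                     per_marker_var=True)
    return BayesBPredictor(mu=fit.mu, effects=fit.effects,
                           inclusion=fit.model_freq)


def predictive_ability(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.std() == 0 or obs.std() == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def _fold_partition(idx: np.ndarray, folds: int, rng: np.random.Generator):
    """Random exact partition of idx into `folds` near-equal folds."""
    perm = rng.permutation(idx)
    return np.array_split(perm, folds)


def _predict(model: str, y, K, M, train, test, mcmc, seed):
    train = np.asarray(train)
    test = np.asarray(test)
    if model == "GBLUP":
        p = fit_gblup(y[train], K, train)
        return p.predict(K, test)
    if model == "BayesB":
        iters, burnin, _ = mcmc
        p = fit_bayesb(y[train], M[train], mcmc=(iters, burnin, seed))
        return p.predict(M, test)
    raise ValueError(f"unknown model {model!r}")


def cross_validate(y: np.ndarray, panel: MarkerPanel, K: np.ndarray,
                   scheme: str, model: str, trait: str = "trait",
                   folds: int = 5, reps: int = 25, seed: int = 0,
                   mcmc: tuple[int, int, int] = (5000, 500, 0)) -> CVResult:
    """Run one cross-validation scheme for one model and trait."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    y = np.asarray(y, float)
    n = panel.n_individuals
    if len(y) != n:
        raise ValueError("y must align with panel individuals")
    M = center_markers(panel) if model == "BayesB" else None
    fams = panel.family
    ss = np.random.SeedSequence([seed, SCHEMES.index(scheme), MODELS.index(model)])
    rng = np.random.default_rng(ss)
    chain_seeds = iter(ss.generate_state(20000))

    records = []
    if scheme == "across_family":
        for rep in range(reps):
            for fold_i, test in enumerate(_fold_partition(np.arange(n), folds, rng)):
                train = np.setdiff1d(np.arange(n), test)
                pred = _predict(model, y, K, M, train, test, mcmc,
                                int(next(chain_seeds)))
                records.append({"rep": rep, "fold": fold_i,
                                "pa": predictive_ability(pred, y[test])})
    elif scheme == "within_family":
        for fam in pd.unique(fams):
            fidx = np.flatnonzero(fams == fam)
            if len(fidx) < folds:
                warnings.warn(f"family {fam!r} smaller than fold count; skipped")
                continue
            for rep in range(reps):
                preds = np.full(len(fidx), np.nan)
                pos = {g: k for k, g in enumerate(fidx)}
                for fold_i, test in enumerate(_fold_partition(fidx, folds, rng)):
                    train = np.setdiff1d(fidx, test)
                    pred = _predict(model, y, K, M, train, test, mcmc,
                                    int(next(chain_seeds)))
                    for g, pv in zip(test, pred):
                        preds[pos[g]] = pv
                records.append({"family": fam, "rep": rep,
                                "pa": predictive_ability(preds, y[fidx])})
    else:  # leave_family_out
        for fam in pd.unique(fams):
            test = np.flatnonzero(fams == fam)
            train = np.flatnonzero(fams != fam)
            pred = _predict(model, y, K, M, train, test, mcmc,
                            int(next(chain_seeds)))
            records.append({"family": fam,
                            "pa": predictive_ability(pred, y[test])})
    return CVResult(scheme=scheme, model=model, trait=trait,
                    records=pd.DataFrame(records))


def cv_summary(results: list[CVResult]) -> pd.DataFrame:
    """Tidy mean/sd predictive-ability table over schemes and models."""
    rows = [{"scheme": r.scheme, "model": r.model, "trait": r.trait,
             "mean_pa": r.mean_pa, "sd_pa": r.sd_pa,
             "n_cells": len(r.records)} for r in results]
    return pd.DataFrame(rows)
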