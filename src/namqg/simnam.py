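"""Synthetic nested association mapping (NAM) population generator.

Emulates the structure of soybean NAM panels: one common parent crossed to
many founder parents, each cross advanced to recombinant inbred lines (RILs)
by single-seed descent, genotyped on a genome-wide SNP panel, and phenotyped
in a multi-environment augmented field design with checks.

The generator exposes the full simulation truth (QTL positions and effects,
per-genotype genetic values, realized variance fractions) so parameter
recovery of every downstream stage can be tested against known values.

Defaults mirror the study conditions the analysis chain targets: ~40
families of ~140 RILs, ~20 chromosomes, low plot-level heritability,
additive plus additive-by-additive genetic architecture, genotype-by-
environment family deviations and smooth spatial field trends, and a 7:1
line-to-check augmented layout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import MISSING, GeneticMap, MarkerPanel

COMMON_PARENT_ID = "IA_common"
CHECK_FAMILY = "CHECK"
FOUNDER_FAMILY = "FOUNDER"
N_CHECK_GENOTYPES = 3


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimConfig:
    """Configuration of a synthetic NAM population.

    Heritability targets are fractions of the *plot-level* phenotypic
    variance (within-environment scale, which is normalized to 1 trait
    unit²); ``gxe_sd`` and ``spatial_gradient_sd`` are on the same trait
    scale.
    """

    n_families: int = 40
    n_ril_per_family: int = 140
    n_chrom: int = 20
    markers_per_chrom: int = 212
    chrom_length_cM: float = 100.0
    selfing_generations: int = 5
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    n_qtl_additive: int = 10
    n_qtl_epistatic_pairs: int = 5
    h2_additive_target: float = 0.30
    h2_epistatic_target: float = 0.10
    gxe_sd: float = 0.15
    spatial_gradient_sd: float = 0.25
    n_environments: int = 6
    reps_per_env: int = 1
    check_ratio: int = 7
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_families": (self.n_families, 1),
            "n_ril_per_family": (self.n_ril_per_family, 2),
            "n_chrom": (self.n_chrom, 1),
            "markers_per_chrom": (self.markers_per_chrom, 2),
            "selfing_generations": (self.selfing_generations, 0),
            "n_environments": (self.n_environments, 1),
            "reps_per_env": (self.reps_per_env, 1),
            "check_ratio": (self.check_ratio, 1),
        }
        for name, (value, lo) in counts.items():
            if int(value) != value or value < lo:
                raise SimConfigError(f"{name} must be an integer >= {lo}, got {value}")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError(
                f"founder_maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.founder_maf_range}"
            )
        for name in ("h2_additive_target", "h2_epistatic_target", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SimConfigError(f"{name} must be in [0, 1), got {v}")
        if self.h2_additive_target + self.h2_epistatic_target >= 1.0:
            raise SimConfigError("h2_additive_target + h2_epistatic_target must be < 1")
        if self.chrom_length_cM < 0:
            raise SimConfigError(f"chrom_length_cM must be >= 0, got {self.chrom_length_cM}")
        for name in ("gxe_sd", "spatial_gradient_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated trait, for parameter-recovery tests."""

    qtl_positions: np.ndarray          # additive QTL marker indices, increasing
    qtl_effects: np.ndarray            # per counted-allele copy, trait units
    epistatic_pairs: list              # (index_a, index_b, effect)
    true_h2_additive: float            # realized var fraction, plot scale
    true_h2_epistatic: float
    true_genetic_values: np.ndarray    # per RIL, additive + epistatic
    env_effects: np.ndarray            # per environment
    var_additive: float = 0.0
    var_epistatic: float = 0.0
    var_gxe: float = 0.0
    var_spatial: float = 0.0
    var_residual: float = 0.0
    mean_reps_per_entry: float = 0.0

    @property
    def broad_sense_H(self) -> float:
        """Entry-mean broad-sense heritability implied by the drawn components."""
        vg = self.var_additive + self.var_epistatic
        r = max(self.mean_reps_per_entry, 1.0)
        return vg / (vg + self.var_residual / r)

    def to_json(self, path: str | Path) -> None:
        d = {
            "qtl_positions": self.qtl_positions.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "epistatic_pairs": [[int(a), int(b), float(e)] for a, b, e in self.epistatic_pairs],
            "true_h2_additive": self.true_h2_additive,
            "true_h2_epistatic": self.true_h2_epistatic,
            "true_genetic_values": self.true_genetic_values.tolist(),
            "env_effects": self.env_effects.tolist(),
            "var_additive": self.var_additive,
            "var_epistatic": self.var_epistatic,
            "var_gxe": self.var_gxe,
            "var_spatial": self.var_spatial,
            "var_residual": self.var_residual,
            "mean_reps_per_entry": self.mean_reps_per_entry,
            "broad_sense_H": self.broad_sense_H,
        }
        Path(path).write_text(json.dumps(d))


def default_map(cfg: SimConfig) -> GeneticMap:
    """Evenly spaced marker map; ids follow the ``Gm<CC>_<POS>`` convention.

    Base-pair coordinates are synthesized at 500 kb per cM (1-based).
    """
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        cm = np.linspace(0.0, cfg.chrom_length_cM, cfg.markers_per_chrom)
        # unique, strictly increasing 1-based coordinates even for
        # co-located markers (zero-length test chromosomes)
        bp = np.round(cm * 5e5).astype(int) + 1 + np.arange(cfg.markers_per_chrom)
        for pos_cm, pos_bp in zip(cm, bp):
            rows.append((f"Gm{c:02d}_{pos_bp}", c, pos_cm, pos_bp))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cm", "bp"]))


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> MarkerPanel:
    """Draw fully inbred founder genotypes.

    Returns one common parent plus ``n_families`` alternate founders, coded
    {0, 2} with the counted allele being the alternate-founder allele: the
    common parent is 0 everywhere and each alternate founder carries the
    counted allele at a random subset of loci, with per-locus carrier
    frequency drawn uniformly from ``founder_maf_range``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = cfg.n_chrom * cfg.markers_per_chrom
    freq = rng.uniform(*cfg.founder_maf_range, size=m)
    alt = (rng.random((cfg.n_families, m)) < freq).astype(np.int8) * 2
    # guarantee polymorphism among alternate founders where possible
    mono = alt.sum(axis=0) == 0
    if mono.any() and cfg.n_families >= 1:
        rows = rng.integers(0, cfg.n_families, size=mono.sum())
        alt[rows, np.flatnonzero(mono)] = 2
    common = np.zeros((1, m), dtype=np.int8)
    geno = np.vstack([common, alt])
    ids = np.array(
        [COMMON_PARENT_ID] + [f"F{k:02d}" for k in range(1, cfg.n_families + 1)],
        dtype=object,
    )
    family = np.array([FOUNDER_FAMILY] * (cfg.n_families + 1), dtype=object)
    gmap = default_map(cfg)
    return MarkerPanel(
        genotypes=geno,
        marker_ids=gmap.marker,
        map=gmap,
        individual_ids=ids,
        family=family,
    )


def _recomb_fractions(gmap: GeneticMap) -> np.ndarray:
    """Per-adjacent-interval recombination fraction under the Haldane map.

    r = 0.5 (1 - exp(-2 d / 100)) for d in cM; chromosome boundaries get
    r = 0.5 (free recombination).
    """
    cm = gmap.cm
    chrom = gmap.chrom
    d = np.diff(cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def _meiosis(hapA: np.ndarray, hapB: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized gamete formation for a batch of individuals.

    ``hapA``/``hapB`` are (n, m) haplotype allele arrays; ``r`` the (m-1,)
    interval recombination fractions.  Each gamete starts on a random
    haplotype and switches between them at crossover points.
    """
    n, m = hapA.shape
    start = rng.integers(0, 2, size=(n, 1))
    switches = (rng.random((n, m - 1)) < r).astype(np.int8)
    chooser = (start + np.concatenate([np.zeros((n, 1), np.int8), np.cumsum(switches, axis=1)], axis=1)) % 2
    return np.where(chooser == 0, hapA, hapB)


def derive_rils(founders: MarkerPanel, gmap: GeneticMap, cfg: SimConfig,
                rng: np.random.Generator | None = None) -> MarkerPanel:
    """Derive RIL families by F1 crossing and repeated selfing.

    For each family the F1 of (common x founder) is selfed for
    ``selfing_generations`` rounds by single-seed descent with Haldane
    (no-interference) recombination.  Residual heterozygosity is coded 1.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if founders.n_markers != len(gmap):
        raise ValueError(
            f"map/marker mismatch: {len(gmap)} map rows, {founders.n_markers} markers"
        )
    r = _recomb_fractions(gmap)
    common = (founders.genotypes[0] // 2).astype(np.int8)
    geno_rows, ids, fams = [], [], []
    for k in range(cfg.n_families):
        founder_hap = (founders.genotypes[1 + k] // 2).astype(np.int8)
        n = cfg.n_ril_per_family
        # F1: one haplotype from each inbred parent
        hapA = np.tile(common, (n, 1))
        hapB = np.tile(founder_hap, (n, 1))
        for _ in range(cfg.selfing_generations):
            new_A = _meiosis(hapA, hapB, r, rng)
            new_B = _meiosis(hapA, hapB, r, rng)
            hapA, hapB = new_A, new_B
        geno_rows.append((hapA + hapB).astype(np.int8))
        fam_name = f"fam{k + 1:02d}"
        ids.extend(f"{fam_name}_r{j + 1:03d}" for j in range(n))
        fams.extend([fam_name] * n)
    return MarkerPanel(
        genotypes=np.vstack(geno_rows),
        marker_ids=founders.marker_ids,
        map=gmap,
        individual_ids=np.asarray(ids, dtype=object),
        family=np.asarray(fams, dtype=object),
    )


def _spatial_surface(rows: np.ndarray, cols: np.ndarray, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth field trend in one block: linear gradient + low-frequency sine."""
    if sd == 0.0 or len(rows) < 2:
        return np.zeros(len(rows))
    r = (rows - rows.mean()) / max(np.ptp(rows), 1)
    c = (cols - cols.mean()) / max(np.ptp(cols), 1)
    a, b = rng.normal(size=2)
    phase = rng.uniform(0, 2 * np.pi)
    surf = a * r + b * c + np.sin(2 * np.pi * (r + c) / 2.0 + phase)
    s = surf.std()
    return surf / s * sd if s > 0 else np.zeros(len(rows))


def simulate_phenotypes(panel: MarkerPanel, cfg: SimConfig,
                        rng: np.random.Generator | None = None,
                        trait: str = "trait",
                        founders: MarkerPanel | None = None,
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate plot-level phenotypes over a multi-environment augmented design.

    Genetic values are a sum of additive QTL effects and pairwise
    additive-by-additive products on centered codes, rescaled so the
    additive and epistatic variances hit the configured fractions of the
    (unit) plot-level phenotypic variance.  Plot values add environment
    main effects, family-by-environment deviations, a smooth spatial
    gradient per (environment, block) and iid residual noise.  Checks are
    interleaved at one per ``check_ratio`` lines.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n, m = panel.genotypes.shape
    if panel.has_missing:
        raise ValueError("simulate_phenotypes requires complete genotypes")

    var_noise = 1.0 - cfg.h2_additive_target - cfg.h2_epistatic_target
    var_spatial = cfg.spatial_gradient_sd ** 2
    var_gxe = cfg.gxe_sd ** 2
    var_resid = var_noise - var_spatial - var_gxe
    if var_resid <= 0:
        raise SimConfigError(
            "h2 targets plus spatial and GxE variance leave no residual variance; "
            "lower h2_*_target, gxe_sd or spatial_gradient_sd"
        )

    X = panel.genotypes.astype(float)
    Xc = X - X.mean(axis=0)

    # additive QTL: markers sampled genome-wide, effects N(0,1) then rescaled
    n_qtl = min(cfg.n_qtl_additive, m)
    qtl_pos = np.sort(rng.choice(m, size=n_qtl, replace=False))
    eff = rng.normal(size=n_qtl)
    g_add = Xc[:, qtl_pos] @ eff
    sd = g_add.std()
    if cfg.h2_additive_target > 0 and sd > 0:
        scale = np.sqrt(cfg.h2_additive_target) / sd
    else:
        scale = 0.0
    eff = eff * scale
    g_add = g_add * scale

    # epistatic pairs: products of centered codes at random marker pairs
    pairs = []
    g_epi = np.zeros(n)
    if cfg.n_qtl_epistatic_pairs > 0 and cfg.h2_epistatic_target > 0 and m >= 2:
        raw = np.zeros(n)
        chosen = []
        for _ in range(cfg.n_qtl_epistatic_pairs):
            a, b = rng.choice(m, size=2, replace=False)
            w = rng.normal()
            chosen.append([a, b, w])
            raw = raw + w * Xc[:, a] * Xc[:, b]
        sd = raw.std()
        escale = np.sqrt(cfg.h2_epistatic_target) / sd if sd > 0 else 0.0
        pairs = [(int(a), int(b), float(w * escale)) for a, b, w in chosen]
        g_epi = raw * escale

    g = g_add + g_epi
    env_effects = rng.normal(0.0, 0.5, size=cfg.n_environments)
    fams = np.unique(panel.family)
    gxe = rng.normal(0.0, cfg.gxe_sd, size=(len(fams), cfg.n_environments))
    fam_idx = {f: i for i, f in enumerate(fams)}

    # check genotypes: replicated fixed entries with their own genetic values
    if founders is not None and founders.n_individuals >= N_CHECK_GENOTYPES:
        chk_X = founders.genotypes[:N_CHECK_GENOTYPES].astype(float)
        chk_Xc = chk_X - X.mean(axis=0)
        chk_add = chk_Xc[:, qtl_pos] @ eff
        chk_epi = np.zeros(N_CHECK_GENOTYPES)
        for a, b, w in pairs:
            chk_epi += w * chk_Xc[:, a] * chk_Xc[:, b]
        chk_g = chk_add + chk_epi
    else:
        chk_g = rng.normal(0.0, np.sqrt(max(cfg.h2_additive_target, 1e-12)),
                           size=N_CHECK_GENOTYPES)
    check_ids = [f"check{c + 1}" for c in range(N_CHECK_GENOTYPES)]

    mu = 10.0
    years = [2013 + (e * 3) // max(cfg.n_environments, 1) for e in range(cfg.n_environments)]
    locs = ["ACRE" if e % 2 == 0 else "TPAC" for e in range(cfg.n_environments)]

    records = []
    order = np.arange(n)
    for e in range(cfg.n_environments):
        for rep in range(cfg.reps_per_env):
            rng.shuffle(order)
            # interleave one check per `check_ratio` lines
            entries = []
            ci = 0
            for j, idx in enumerate(order):
                if j % cfg.check_ratio == 0:
                    entries.append(("check", ci % N_CHECK_GENOTYPES))
                    ci += 1
                entries.append(("ril", idx))
            n_plots = len(entries)
            ncol = int(np.ceil(np.sqrt(n_plots)))
            rows_ = np.arange(n_plots) // ncol
            cols_ = np.arange(n_plots) % ncol
            block = rep + 1
            spatial = _spatial_surface(rows_.astype(float), cols_.astype(float),
                                       cfg.spatial_gradient_sd, rng)
            noise = rng.normal(0.0, np.sqrt(var_resid), size=n_plots)
            for p_i, (kind, idx) in enumerate(entries):
                if kind == "check":
                    gid, fam_label, gval, gxe_dev = (
                        check_ids[idx], CHECK_FAMILY, chk_g[idx], 0.0)
                    is_check = 1
                else:
                    gid = panel.individual_ids[idx]
                    fam_label = panel.family[idx]
                    gval = g[idx]
                    gxe_dev = gxe[fam_idx[fam_label], e]
                    is_check = 0
                y = mu + gval + env_effects[e] + gxe_dev + spatial[p_i] + noise[p_i]
                records.append((gid, fam_label, f"env{e + 1}", years[e], locs[e],
                                block, rows_[p_i], cols_[p_i], is_check, y))
    plots = pd.DataFrame(
        records,
        columns=["id", "family", "env", "year", "loc", "block", "row", "col",
                 "is_check", trait],
    )

    reps = plots.loc[plots.is_check == 0].groupby("id").size()
    truth = SimTruth(
        qtl_positions=qtl_pos,
        qtl_effects=eff,
        epistatic_pairs=pairs,
        true_h2_additive=float(np.var(g_add)),
        true_h2_epistatic=float(np.var(g_epi)),
        true_genetic_values=g,
        env_effects=env_effects,
        var_additive=float(np.var(g_add)),
        var_epistatic=float(np.var(g_epi)),
        var_gxe=var_gxe,
        var_spatial=var_spatial,
        var_residual=var_resid,
        mean_reps_per_entry=float(reps.mean()),
    )
    return plots, truth


def mask_missing(panel: MarkerPanel, rate: float, rng: np.random.Generator) -> MarkerPanel:
    """Mask a random fraction of genotype calls as missing."""
    if rate <= 0:
        return panel
    g = panel.genotypes.copy()
    mask = rng.random(g.shape) < rate
    g[mask] = MISSING
    out = MarkerPanel(
        genotypes=g,
        marker_ids=panel.marker_ids,
        map=panel.map,
        individual_ids=panel.individual_ids,
        family=panel.family,
    )
    return out


def simulate(cfg: SimConfig, trait: str = "trait"):
    """End-to-end simulation: founders -> RILs -> phenotypes (+missing mask).

    Returns ``(panel, plots, truth, founders)``; ``panel`` carries missing
    calls at ``cfg.missing_rate``, while phenotypes were generated from the
    complete genotypes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_founder, r_ril, r_pheno, r_miss = (np.random.default_rng(s) for s in ss.spawn(4))
    founders = simulate_founders(cfg, r_founder)
    rils = derive_rils(founders, founders.map, cfg, r_ril)
    plots, truth = simulate_phenotypes(rils, cfg, r_pheno, trait=trait, founders=founders)
    panel = mask_missing(rils, cfg.missing_rate, r_miss)
    return panel, plots, truth, founders
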