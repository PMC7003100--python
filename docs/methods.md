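# Methods

This note documents the models, numerical choices and evaluation design of
`namqg`, and states what the synthetic-data experiments do and do not show.

## Synthetic NAM populations (`simnam`)

The generator emulates a soybean-style NAM panel: one common parent crossed
to `n_families` founder parents (defaults 40 families × 140 RILs, 20
chromosomes × 212 markers ≈ 4240 SNPs), each family advanced by
`selfing_generations` (default 5) rounds of single-seed descent.

- **Meiosis.** Haldane (no-interference) map function: crossover
  probability between adjacent loci at distance d cM is
  r = ½(1 − e^(−2d/100)); chromosome boundaries recombine freely.  Chosen
  as the simplest defensible meiosis model.
- **Founders.** Fully inbred, coded {0, 2}; the counted allele is the
  alternate-founder allele (the common parent is 0 everywhere), giving
  downstream allele-substitution effects a stable sign anchor.
- **Genetic architecture.** Additive QTL effects on centered codes plus
  pairwise additive×additive products — exactly the architecture the G2A
  analysis fits, so decomposition recovery is a well-posed question.
  Effects are rescaled so the additive and epistatic variances equal
  `h2_additive_target` and `h2_epistatic_target` as fractions of the
  within-environment plot variance, which is normalized to 1 trait unit².
- **Field design.** Per environment, lines are laid on a near-square grid
  with one replicated check entry per 7 lines (3 fixed check genotypes
  cycling).  The spatial field effect per (environment, block) is a linear
  row/column gradient plus one low-frequency sinusoid, scaled to
  `spatial_gradient_sd` — detectable by a moving-average covariate without
  committing to an autoregressive error structure.  GxE is simulated as
  independent family×environment normal deviations (`gxe_sd`), which
  reproduces near-zero-to-moderate stability correlations without an
  unstated factor-analytic structure.
- **What it does not emulate.** Sequence-level variation, dominance,
  selection during line derivation, realistic LD decay, segregation
  distortion, or correlated multi-trait architectures.  Passing recovery
  tests therefore demonstrates correctness of the estimators under their
  assumed model class, not robustness to real-data violations of it.

`simulate()` masks genotype calls at `missing_rate` after phenotype
generation, so the recorded truth always refers to the complete genotypes.

## Stage-1 genetic merit (`merit`)

Weighted mixed model y = μ + βf(s) + Zu + Wg + e fitted by EM-REML on
Henderson's mixed-model equations (MME).  Choices:

- The spatial covariate is the mean raw trait value of neighbor plots
  within a (rows, cols) window, default (1, 1) (rook+diagonal), one
  covariate per trait entered as a fixed regression.  Raw values rather
  than residuals keep the covariate a one-pass computation.
- Observation weights are inverse within-environment phenotypic variances,
  normalized to mean 1 inside the fit so σ²ₑ stays in trait units.
- Checks are ordinary levels of u (they inform the spatial/block
  correction) but are excluded from the replicate count r and from all
  genomic stages.
- Reliability is Hⱼ = 1 − PEVⱼ/σ²ᵤ with PEVⱼ read off the inverted MME
  coefficient matrix — the standard definition consistent with
  deregression.  If σ²ᵤ collapses (≤ 10⁻⁸ × phenotypic variance) the fit
  is flagged degenerate, H = 0 and deregressed values are undefined.
- r is the mean plot count per non-check entry across all environments.

## REML numerics (`_reml`)

All variance-component fits are EM-REML: monotone in the restricted
likelihood and nonnegative by construction, with a component floor of
10⁻¹⁰ × var(y).  Plain EM crawls when a component approaches its boundary,
so every solver drives the EM map through SQUAREM extrapolation with a
likelihood safeguard: an extrapolated point is accepted only if it does
not lower the restricted likelihood, otherwise the plain double-EM step is
used.  The fixed point is unchanged — unit tests verify agreement with
plain EM and with exhaustive grid search of the restricted likelihood
(staged refinement to a 1e-3 step) on n ≤ 30 problems.  Convergence is
declared at relative log-likelihood change < 1e-8 (1e-11 for the bivariate
fit, whose boundary drift is slower); iteration caps are 500 map
evaluations for stage 1 and 2000–5000 for kernel fits.

Two-component genomic fits (SNP-BLUP, GBLUP, the MLM null) are solved in
the eigenbasis of the relationship matrix where every kernel is diagonal
(O(n) per iteration).  The bivariate model is solved in the same basis,
where it factorizes into 2×2 blocks per eigenvalue; Σψ is kept positive
semidefinite by eigenvalue flooring, and fits with |ρψ| > 0.999 or a
near-zero genetic variance carry a `degenerate` flag.

## Kernels and heritability (`grm`)

K = MM′·n/tr(MM′); Q is the Hadamard square of the *unnormalized* MM′,
renormalized by its own trace (the normalized variant differs only by a
scalar absorbed by the normalizer).  Allele frequencies are computed on
the post-QC analysis set so the h² denominator matches the fitted markers.

The h² heterozygosity sum defaults to the realized marker-variance sum
tr(M′M)/n.  Under Hardy–Weinberg this equals the textbook 2Σpⱼ(1−pⱼ), but
RIL panels are inbred (per-marker variance → 4pq), where the textbook sum
would understate marker-borne variance about twofold; `het="hwe"` applies
it literally for comparability with outbred-convention reports.  The
QTL-subset scenario re-estimates σ²ₐ on the subset rather than reusing the
all-marker estimate.

## Variance decomposition and correlations (`vc`)

Within-family G2A fits rebuild K and Q from the family's own markers and
allele frequencies (monomorphic-within-family markers dropped) so
across-family structure cannot leak into within-family components;
families below 10 individuals are skipped with a warning.  Pleiotropy uses
two traits on one kernel; stability uses one trait refit per year, all
year pairs reported.  The indirect-selection efficiency defaults to the
literal squared-heritability ratio E = ρψ·h²ᵢ/h²ⱼ, with Falconer's
E = ρψ·hᵢ/hⱼ selectable — the two conventions coincide at equal
heritabilities and are both exposed because the ratio's exponent is a
genuine ambiguity in the field's shorthand.

## Association scans (`gwas`)

- **MLM.** Null polygenic model fitted once; its eigendecomposition and
  variance components are reused for every marker (profile REML over the
  common within-family effect variance σ²β only, via low-rank Woodbury
  updates).  The marker design nests codes within families and includes a
  family's column only where the marker segregates, avoiding singular
  designs.  The LRT is referred to χ²(1); this is anticonservative at the
  boundary (the ½χ²(0)+½χ²(1) mixture halves the p-value) but is the
  plain likelihood-ratio reading, and the Bonferroni threshold is the
  binding control.  Because the tested marker also sits inside K, very
  small panels absorb part of the signal into the polygenic term; at scan
  scales (m ≥ 500) this proximal contamination is negligible.
- **BayesCpi.** Gibbs sampler with common marker variance
  σ²β ~ scaled-inv-χ²(S_b, ν₀ = 5), S_b = 0.5·var(y)/(MSx·(1−π)) recomputed
  each iteration from the current null probability π (prior heritability
  0.5), S_e = 0.5·var(y), π ~ Beta(counts + 1), default chain 20000/2000.
  MSx is the sum of centered-marker column variances.  Statistic:
  −log10(1 − model frequency), i.e. the posterior exclusion probability
  against 0.025 two-sided.
- **RFR.** scikit-learn regression forests (impurity importances,
  bootstrap bagging, mtry candidate features per split; defaults 10000
  trees, mtry 65, reducible).  The global empirical threshold is the
  (1−α) quantile of the maximum importance over phenotype permutations
  (default 1000): exchangeability makes the family-wise null rate ≤ α by
  construction, with no distributional assumptions.
- **Effects.** Allele-substitution effects of hits are OLS slopes with
  trait and marker centered within family; reported per counted
  (alternate-founder) allele copy, plus the sign-flipped field convention
  (negative = trait-increasing founder allele).

## Genomic prediction (`gpred`)

GBLUP estimates λ = σ²ₑ/σ²ᵤ by REML on the training subset of a kernel
built once on the full panel (per-fold kernel rebuilds are not standard
and change little).  BayesB fixes π = 0.95 with per-marker
scaled-inv-χ²(S_b, ν₀ = 10) variances; the CV default chain is 5000/500
iterations — a speed/accuracy knob, since posterior-mean effects for
prediction stabilize far faster than tail posteriors.  Within-family and
leave-family-out predictive abilities are computed within family and
never pooled, avoiding inflation by family means (a Simpson's-paradox
artifact of pooled across-family correlations).  The observed value is
always the deregressed genetic value, not the raw plot phenotype.

## Pipeline (`cli`)

YAML config validated by pydantic models; one top-level seed with
per-stage seeds derived by CRC32-stable hashing, so reruns with the same
config+seed are bit-identical (tested by double-run diff).  Each run
writes a manifest (config hash, seed, version, stage timings).

## Evaluation suite (`benchmarks`) and problem sizes

Scenario sizes are the package's scaled-down study conditions, chosen so
the whole suite runs in minutes on one CPU while keeping each estimate's
Monte-Carlo error well inside the acceptance margin:

| scenario | truth | size | seeds (tests / script) |
|---|---|---|---|
| SNP-BLUP h² recovery | 0.30 | 2000 RILs × 500 markers | 10 / 5 |
| G2A proportions | 0.25 / 0.25 | 1000 × 300 | 10 / 5 |
| bivariate ρψ | 0.40 | 800 × 300 | 10 / 5 |
| MLM power (10% QTL) | detect + localize ≤ 5 | 1500 × 500 | 10 / 5 |
| BayesCpi null FPR | ≤ 0.05 | 500 × 200, chain 5000/500 | 10 / 5 |
| RFR null rate | ≤ α = 0.05 | 120 × 60, 500 trees, 100 perms | 8 / 6 scans |
| CV structure | ordering + model gap | 5 fam × 100 × 500 markers, 5 reps | 10 (+3 BayesB) / 5 (+2) |

## Known limitations

- EM-REML standard errors are not reported; only point estimates.
- The MLM statistic assumes a common σ²β across families.
- Single-trait stage 1; no factor-analytic GxE or AR1×AR1 spatial models.
- The HMM-based genotype imputation used with real array data is out of
  scope; the within-family modal-code rule is adequate for the simulated
  missingness it is paired with, not for real low-density data.
- Bivariate fits on fewer than ~200 individuals are frequently flagged
  degenerate when the genetic variance of either trait is small.
- With few families, leave-family-out predictive ability is highly
  dispersed (QTL private to the held-out family cannot be learned from
  the others), so the leave-family-out vs within-family leg of the scheme
  hierarchy is resolvable only in panels with many families; the
  across-family advantage is robust at any size.
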