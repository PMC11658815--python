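# Methods

## Model and inference

`lpdsub` fits latent process decomposition: per sample *d*, process weights
θ_d ~ Dirichlet(α); per gene *g* and sample *d*, a latent process
z_gd ~ Categorical(θ_d) and expression e_gd ~ N(μ_gz, σ²_gz). The
gene-level re-draw of z is essential: it is what lets a single tumor be
explained by several transcriptional programs at once, and it is the
property the synthetic generator reproduces (one process per *gene and
sample*, not one per sample).

Inference is mean-field variational EM with q(θ_d) = Dirichlet(γ_d) and
q(z_gd) categorical with responsibilities Q. The E-step is exact coordinate
ascent:

    Q_dgk ∝ exp(ψ(γ_dk) − ψ(Σ_j γ_dj)) · N(e_gd; μ_gk, σ²_gk),
    γ_dk = α_k + Σ_g Q_dgk.

The M-step updates μ and σ² in closed form and α by the standard
inverse-digamma fixed point for the Dirichlet maximum likelihood (a monotone
MM update). `variational_bound` returns the evidence lower bound on
log p(e | α, μ, σ²) with q(z) at its optimum given γ, so it is a true lower
bound on the marginal likelihood for *any* γ; the quadrature oracle
`exact_marginal_loglik` verifies this on tiny problems by integrating the
likelihood over the simplex.

**Bound trace.** Because the variance update is MAP-regularized (below), the
quantity EM actually ascends is the bound *plus* the variance-prior log
density. `LPDFit.bound_trace` records that penalized objective, which is
non-decreasing by construction; `variational_bound` itself stays the pure
bound so that comparisons against the exact marginal likelihood remain
valid.

## The process-spread ("sigma") prior

Unregularized per-process gene variances are the model's known failure mode:
a process can shrink a gene's variance onto a handful of samples (a singular
Gaussian), which distorts the recovered signatures. The spread
hyperparameter therefore acts as an inverse-gamma-style MAP prior pulling
σ²_gk toward that gene's pooled variance v_g with strength
ν = |sigma| · D pseudo-observations (`log10` dialect: ν = 10^sigma · D):

    σ²_gk = (Σ_d Q_dgk (e_gd − μ_gk)² + ν v_g) / (Σ_d Q_dgk + ν),

floored at 10⁻⁶. Scaling ν with the cohort size D makes the prior's
relative pull scale-free. The default sigma = −0.01 contributes roughly one
effective prior observation at D ≈ 90 — weak enough to leave well-populated
processes untouched, strong enough to prevent collapse; the grid search
explores {−0.1, −0.01, −0.001} by default. The exact parameterization used
in prior LPD work is not recoverable from its published descriptions, so
this mapping (and the alternative log10 dialect) is a design choice of this
package.

## Initialization and restarts

Each process mean starts halfway between the gene mean and the profile of a
randomly chosen sample (distinct anchors per process); K = 1 starts at the
exact gene means. Near-symmetric starts (gene mean plus small jitter) were
found to converge to clearly inferior optima in weak-separation regimes, so
sample-anchored starts are the default. The fit is non-convex: restart
protocols treat the final penalized bound as the model's own objective —
`fit_lpd_restarts` keeps the best of n seeded fits, the direct analogue of
k-means keeping the best of 50 restarts by within-cluster sum of squares.
All randomness flows through a counter-based (Philox) generator keyed by a
single integer seed, so every run is bit-reproducible.

## Model selection

For each (K, sigma) cell, samples are split into folds (default 5; the
replication studies use 3), the model is fitted on the training folds (best
of `restarts` seeded fits by training bound) and scored by the mean
per-sample predictive bound of the held-out fold, obtained by E-step-only
iterations with μ, σ², α frozen. The operating point is the smallest K whose
best-over-sigma mean held-out log-likelihood lies within one standard error
(of the global-best cell, over folds) of the global maximum. The one-SE
rule is a reproducible operationalization of choosing "the point just
before the plateau" on a hold-out likelihood curve.

## Survival-anchored ensemble

The decomposition is refitted from `n_runs` (default 100) consecutive seeds.
A run *qualifies* as showing a poor-prognosis subtype when the overall
log-rank test across its max-membership groups has p < 0.05 **and** a unique
worst-surviving group (lowest Kaplan–Meier curve at the median follow-up
time). The representative run minimizes |−log10(p) − mode|, the mode being
the midpoint of the most populated Freedman–Diaconis histogram bin of the
qualifying runs' −log10(p) values — both the scale and the estimator are
choices this package fixes, since "closest to the mode" is otherwise
underdetermined. Subtypes are matched across datasets by Pearson
correlation of median z-score signatures (genes z-scored across the whole
cohort, medians over the subtype's samples) on the shared gene set.

## Differential expression

Median-of-ratios size factors (computed in linear space over genes with all
samples nonzero), per-gene NB dispersions by within-group method of moments
shrunk geometrically toward an a₀ + a₁/μ trend, then a Wald test on the
group coefficient of an NB log-link GLM with log-size-factor offsets
(statsmodels IRLS). BH adjustment excludes all-zero genes from the
denominator. Calls are filtered at strict |log2FC| > 1.5 and padj < 0.01;
per-process call sets are the union of that process's pairwise contrasts;
the robustness filter keeps calls present with the same direction in ≥ 80%
of qualifying ensemble runs. Numerical parity with any specific DE package
is a non-goal; correctness is defined by calibration (uniform null p) and
power/bias targets. Note that median-of-ratios normalization is mildly
biased when a large fraction of genes change in one direction — with 10% of
genes planted four-fold up, recovered log2 fold changes shrink by ≈ 0.15 —
which is a property of the estimator, not a defect of the implementation.

## Synthetic generator: what it emulates and what it does not

Defaults mirror the development-cohort scale: D = 88 samples, G = 500
high-variance transcripts, K = 3 processes, symmetric Dirichlet α = 0.3
(heterogeneous tumors with a clear dominant program), exponential survival
with hazard linear in θ (multipliers (3, 1, 1): the first process is the
poor-prognosis program), independent exponential censoring at rates giving
roughly half the samples an observed event, NB counts with dispersion 0.1,
and a subtype-skewed sex covariate. Process signatures give each gene one
"up" process, offset by `separation_sd` (default 3) within-process standard
deviations; the noise sd is 0.5 on the log2 scale, a typical within-subtype
spread. Simulation studies use reduced sizes chosen for statistical
adequacy: recovery at D=90/G=200; selection replicates at D=75/G=150 with
K grid 1..6, 3 folds, 2 restarts; ensemble calibration at G=100 with 200
independent null replicates (each with freshly drawn survival — with one
fixed survival table the restart runs' p-values would be correlated and no
binomial band would apply); the head-to-head at D=150/G=100 with α=0.5 and
1.5-sd separation, the moderately mixed, moderately separated regime where
modeling heterogeneity should matter.

The generator does **not** emulate: batch effects between cohorts, library
composition artifacts, gene–gene correlation beyond what shared processes
induce, non-proportional hazards, or informative censoring. Tests passing
on this generator therefore demonstrate internal correctness and the
intended statistical behavior of the pipeline, not performance on real
cross-platform data.

## Numerical choices and degenerate inputs

Variance floor 10⁻⁶; convergence when the relative change of the penalized
objective drops below 10⁻⁵ (replication studies use 10⁻⁴ with capped
iterations); membership ties broken to the lowest process index (logged);
top-variance ties broken lexicographically by gene id; constant genes are
dropped from z-score signatures with a warning; a process that loses all
responsibility mass keeps its previous parameters and is logged; empty
clusters in k-means are handled by scikit-learn's reseeding. Chi-square
tests use no continuity correction, and the clinical Bonferroni family is
m = 4 (sample type, age, ethnicity, sex) — the family of covariate
comparisons, regardless of how many can be computed on a given dataset.
Cox regression uses Efron tie handling (Breslow via flag).

## Known limitations

- The variational bound is a lower bound; hold-out comparisons across K are
  bound comparisons, not exact likelihood comparisons.
- Representative-run selection anchors on survival, so its log-rank p is
  selected, not a fresh test; it is used for characterization, not
  inference.
- The one-vs-rest DE contrast is available but the default is
  pairwise-union; with K > 3 the union can mix heterogeneous contrasts.
- The NB dispersion trend is a two-parameter curve; strongly non-monotone
  mean–dispersion relationships would be under-fit.
- Exact quadrature oracles are limited to K ≤ 3 and D·G ≤ 30.
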