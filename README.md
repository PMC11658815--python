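# lpdsub

Bayesian subtype discovery for bulk tumor transcriptomes by **latent process
decomposition (LPD)** — a Dirichlet–Gaussian mixed-membership model — with
survival-anchored restart selection, robust negative-binomial differential
expression, cross-dataset subtype matching, and a hard-clustering baseline
comparison. The package was built around the osteosarcoma subtyping problem:
small, heterogeneous cohorts (~90–165 samples) where every tumor is a mixture
of transcriptional programs and classical clustering obscures the prognostic
structure.

## The model

For a genes × samples log-expression matrix *e* (the top ~500 most variable
transcripts), each sample *d* carries latent process weights
θ<sub>d</sub> ~ Dirichlet(α). Independently for every gene *g*, a process
z<sub>gd</sub> ~ Categorical(θ<sub>d</sub>) is drawn and

&nbsp;&nbsp;&nbsp;&nbsp;e<sub>gd</sub> | z<sub>gd</sub>=k ~ N(μ<sub>gk</sub>, σ²<sub>gk</sub>).

Because the process is re-drawn per gene, a sample is a *genuine mixture* of
the K latent expression programs rather than a member of one cluster.
Inference is mean-field variational EM (q(θ<sub>d</sub>) Dirichlet with
parameters γ<sub>d</sub> — the "degree of membership" — and q(z) categorical),
maximizing the evidence lower bound. Two hyperparameters are tuned by
cross-validated hold-out log-likelihood: the number of processes K and the
process spread ("sigma"), a prior on the per-process gene variances. Samples
are hard-assigned to their max-membership process for clinical
characterization; the fit is repeated from 100 seeds and the run whose
survival log-rank statistic sits at the mode of the qualifying runs is taken
as representative.

Downstream, the pipeline provides Kaplan–Meier / log-rank / Cox (Efron ties)
survival analysis, chi-square and ANOVA+Tukey clinical associations with
Bonferroni correction, NB Wald differential expression (median-of-ratios size
factors, trend-shrunk dispersions) filtered at |log2FC| > 1.5 and BH-adjusted
p < 0.01 plus an 80% run-support robustness filter, median z-score signature
matching of subtypes across cohorts, and Ward-D2 / k-means baselines scored
by silhouette and survival separation.

## Worked example

```bash
lpdsub simulate --genes 200 --samples 90 --k 3 --alpha 0.3 --seed 7 --outdir demo/
lpdsub select --expr demo/expression.tsv --k 1..4 --sigmas -0.01 \
    --folds 3 --restarts 2 --seed 1 --out demo/grid.json
lpdsub ensemble --expr demo/expression.tsv --clinical demo/clinical.tsv \
    --k 3 --runs 20 --base-seed 1 --out demo/ens/
```

which prints

```
wrote synthetic cohort (200 genes x 90 samples) to demo
selected K=3, sigma=-0.01
20/20 runs associate with a poor-prognosis subtype
representative run seed=3 logrank_p=2.12e-06
```

The simulated cohort has three latent processes with the first process
tripling the death hazard; the hold-out grid search recovers K=3; all 20
restart runs find a subtype with significantly lower survival, and the
representative run (the one closest to the modal log-rank value) separates
the groups at p ≈ 2×10⁻⁶. `demo/ens/assignments.tsv` then holds the
per-sample subtype calls and membership weights used by `lpdsub clinical`
and `lpdsub de`.

The same pipeline runs end to end from a YAML config via `lpdsub run
--config study.yaml` (see `lpdsub.pipeline.DEFAULTS` for the knobs), or
programmatically through `lpdsub.lpd.fit_lpd`, `lpdsub.selection.grid_search`,
`lpdsub.ensemble.run_ensemble`, etc.

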