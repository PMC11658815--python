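"""Reproducible study-scale experiments over the synthetic generator.

Each function runs one self-contained simulation study — calibration,
recovery, selection, power or head-to-head comparison — at the scale the
package documents in its methods note, returning plain dictionaries of the
quantities measured.  They back both the acceptance checks and the
reproduction script, and all randomness derives from the single seed each
function receives.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from scipy.optimize import linear_sum_assignment

from lpdsub.baseline import hclust_ward, kmeans_cluster, survival_by_cluster
from lpdsub.clinical import bonferroni_adjust, chi_square_independence
from lpdsub.data_io import CountMatrix, ExpressionMatrix, summarize_manifest
from lpdsub.de import nb_wald_de
from lpdsub.ensemble import _survival_stats, run_ensemble
from lpdsub.lpd import (
    LPDHyperParams,
    assign_subtypes,
    exact_marginal_loglik,
    fit_lpd,
    fit_lpd_restarts,
    variational_bound,
)
from lpdsub.selection import grid_search, select_operating_point
from lpdsub.synthetic import (
    generate_counts_from_expression,
    generate_lpd_data,
    simulate_cohort,
    study_manifest,
    table2_fixtures,
)

CLINICAL_TEST_FAMILY = 4  # sample type, age, ethnicity, sex


def table2_results() -> dict:
    """Association tests on the published subtype-by-covariate tables plus
    the cohort-manifest totals."""
    tables = table2_fixtures()
    raw = {
        name: chi_square_independence(tables[name].to_numpy()).p
        for name in ("sex", "ethnicity", "vital_status")
    }
    adj = {
        name: float(bonferroni_adjust([p], m=CLINICAL_TEST_FAMILY)[0])
        for name, p in raw.items()
    }
    return {
        "sex_p_adjusted": adj["sex"],
        "ethnicity_p_adjusted": adj["ethnicity"],
        "vital_status_p_adjusted": adj["vital_status"],
        "manifest_total": summarize_manifest(study_manifest())["total"],
    }


def bound_correctness(seed: int, n_toys: int = 6, n_fits: int = 20) -> dict:
    """Variational-bound sanity: bound <= exact marginal log-likelihood on
    quadrature-feasible toys, and non-decreasing traces on seeded fits."""
    gaps = []
    for i in range(n_toys):
        expr, _ = generate_lpd_data(G=2, D=3, K_true=2, alpha=1.0, seed=seed + i)
        fit = fit_lpd(expr, LPDHyperParams(K=2, seed=seed + 100 + i, max_iter=50))
        bound = variational_bound(expr, fit)
        exact = exact_marginal_loglik(expr, fit.mu, fit.var, fit.alpha)
        gaps.append(bound - exact)
    worst_drop = np.inf
    for i in range(n_fits):
        expr, _ = generate_lpd_data(G=60, D=40, K_true=3, alpha=0.3, seed=seed + 200 + i)
        fit = fit_lpd(expr, LPDHyperParams(K=3, seed=seed + 300 + i, max_iter=60))
        diffs = np.diff(fit.bound_trace)
        if len(diffs):
            worst_drop = min(worst_drop, float(diffs.min()))
    return {
        "max_bound_minus_exact": float(np.max(gaps)),
        "min_trace_increment": float(worst_drop),
    }


def _match_mu_rmse(mu_true: np.ndarray, mu_hat: np.ndarray) -> float:
    K = mu_true.shape[1]
    cost = np.array([
        [float(np.mean((mu_true[:, i] - mu_hat[:, j]) ** 2)) for j in range(K)]
        for i in range(K)
    ])
    r, c = linear_sum_assignment(cost)
    return float(np.sqrt(np.mean((mu_true[:, r] - mu_hat[:, c]) ** 2)))


def recovery_experiment(
    seed: int, n_seeds: int = 20, D: int = 90, G: int = 200,
    K: int = 3, alpha: float = 0.1,
) -> dict:
    """Parameter recovery on well-separated mixed-membership cohorts."""
    aris, rmses = [], []
    for i in range(n_seeds):
        expr, truth = generate_lpd_data(G=G, D=D, K_true=K, alpha=alpha,
                                        seed=seed + i)
        fit = fit_lpd(expr, LPDHyperParams(K=K, seed=seed + 500 + i))
        aris.append(adjusted_rand_score(
            truth.dominant_process, assign_subtypes(fit).labels))
        rmses.append(_match_mu_rmse(truth.mu_true, fit.mu))
    aris, rmses = np.array(aris), np.array(rmses)
    return {
        "ari": aris,
        "mu_rmse": rmses,
        "n_pass": int(((aris >= 0.9) & (rmses <= 0.15)).sum()),
        "n_seeds": n_seeds,
        "ari_median": float(np.median(aris)),
        "mu_rmse_median": float(np.median(rmses)),
    }


def selection_experiment(
    seed: int, k_true: int, n_reps: int = 20, D: int = 75, G: int = 150,
    K_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
) -> dict:
    """How often the one-SE plateau rule recovers the true process count."""
    picks = []
    for i in range(n_reps):
        expr, _ = generate_lpd_data(G=G, D=D, K_true=k_true, alpha=0.1,
                                    seed=seed + i)
        grid = grid_search(
            expr, K_values=list(K_values), sigma_values=[-0.01],
            folds=3, restarts=2, seed=seed + 900 + i, max_iter=60, tol=1e-4,
        )
        picks.append(select_operating_point(grid)[0])
    picks = np.array(picks)
    return {
        "picks": picks,
        "fraction_correct": float((picks == k_true).mean()),
        "n_reps": n_reps,
    }


def ensemble_null_calibration(seed: int, n_reps: int = 200) -> dict:
    """Fraction of independent null replicates (equal hazards) whose single
    seeded run qualifies as a poor-prognosis run."""
    qualify = 0
    for i in range(n_reps):
        cohort = simulate_cohort(
            G=100, D=88, K_true=3, alpha=0.3, hazard_multipliers=[1, 1, 1],
            seed=seed + 10 * i,
        )
        ens = run_ensemble(
            cohort["expression"],
            LPDHyperParams(K=3, max_iter=100),
            n_runs=1, base_seed=seed + 10 * i + 5,
            clinical=cohort["clinical"],
        )
        qualify += len(ens.qualifying(0.05))
    return {"fraction_qualifying": qualify / n_reps, "n_reps": n_reps}


def ensemble_power(seed: int, n_runs: int = 100) -> dict:
    """Restart ensemble on one prognostic cohort (hazard multipliers 3,1,1):
    how many of the runs associate with a poor-prognosis subtype."""
    cohort = simulate_cohort(
        G=100, D=150, K_true=3, alpha=0.3, hazard_multipliers=[3, 1, 1],
        seed=seed,
    )
    ens = run_ensemble(
        cohort["expression"], LPDHyperParams(K=3, max_iter=100),
        n_runs=n_runs, base_seed=seed + 1, clinical=cohort["clinical"],
    )
    n_q = len(ens.qualifying(0.05))
    return {
        "n_qualifying": n_q,
        "n_runs": n_runs,
        "fraction_qualifying": n_q / n_runs,
        "ensemble": ens,
        "cohort": cohort,
    }


def _flat_counts(G: int, n_per_group: int, mean: float, dispersion: float,
                 seed: int, lfc_genes: int = 0, lfc: float = 2.0):
    """NB counts for two groups with an optional planted log2 fold change in
    the first ``lfc_genes`` genes of group B."""
    D = 2 * n_per_group
    log_mean = np.log2(mean + 1.0)
    expr_vals = np.full((G, D), log_mean)
    if lfc_genes:
        expr_vals[:lfc_genes, n_per_group:] = np.log2(mean * 2**lfc + 1.0)
    expr = ExpressionMatrix(
        expr_vals,
        [f"g{i:04d}" for i in range(G)],
        [f"s{i:03d}" for i in range(D)],
    )
    counts = generate_counts_from_expression(expr, dispersion, seed=seed)
    cond = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    return counts, cond


def de_calibration(seed: int, G: int = 2000, n_per_group: int = 20,
                   mean: float = 100.0, dispersion: float = 0.1) -> dict:
    """Type-I calibration of the NB Wald test under the null."""
    counts, cond = _flat_counts(G, n_per_group, mean, dispersion, seed)
    res = nb_wald_de(counts, cond)
    p = res["p"].dropna().to_numpy()
    ks_p = float(stats.kstest(p, "uniform").pvalue)
    return {
        "rejection_rate_05": float((p < 0.05).mean()),
        "ks_uniform_p": ks_p,
        "n_genes": len(p),
    }


def de_power(seed: int, G: int = 2000, n_planted: int = 200,
             n_per_group: int = 20, mean: float = 100.0,
             dispersion: float = 0.1, lfc: float = 2.0) -> dict:
    """Bias and power on planted four-fold (log2FC = 2) changes."""
    counts, cond = _flat_counts(G, n_per_group, mean, dispersion, seed,
                                lfc_genes=n_planted, lfc=lfc)
    res = nb_wald_de(counts, cond)
    planted = res.iloc[:n_planted]
    return {
        "mean_abs_log2fc_error": float((planted["log2fc"] - lfc).abs().mean()),
        "power_padj_01": float((planted["padj"] < 0.01).mean()),
        "n_planted": n_planted,
    }


def baseline_head_to_head(seed: int, n_reps: int = 50) -> dict:
    """The decomposition's max-membership grouping (best-of-restarts by the
    variational bound) against k-means and Ward clustering, scored by the
    overall log-rank p of each arm's groups on theta-driven survival."""
    rows = []
    for i in range(n_reps):
        cohort = simulate_cohort(
            G=100, D=150, K_true=3, alpha=0.5, separation_sd=1.5,
            hazard_multipliers=[3, 1, 1], seed=seed + 10 * i,
        )
        expr, clin = cohort["expression"], cohort["clinical"]
        fit = fit_lpd_restarts(
            expr, LPDHyperParams(K=3, max_iter=200), n_restarts=5,
            base_seed=seed + 10 * i + 1,
        )
        p_lpd, _, _ = _survival_stats(assign_subtypes(fit), clin)
        p_km = survival_by_cluster(
            kmeans_cluster(expr, 3, seed=seed + i).labels, expr.sample_ids, clin)
        p_ward = survival_by_cluster(
            hclust_ward(expr, 3).labels, expr.sample_ids, clin)
        rows.append((p_lpd, p_km, p_ward))
    arr = np.array(rows, dtype=float)
    med = np.median(arr, axis=0)
    return {
        "median_p_lpd": float(med[0]),
        "median_p_kmeans": float(med[1]),
        "median_p_ward": float(med[2]),
        "n_reps": n_reps,
    }
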