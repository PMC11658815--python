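"""Hyperparameter selection by cross-validated hold-out log-likelihood.

The number of processes K and the process spread sigma are chosen on a grid:
for every (K, sigma) cell, samples are split into folds, the model is fitted
on the training folds (best of several restarts by training bound) and
scored by the mean per-sample predictive bound of the left-out fold.  The
operating point is the smallest K whose best-over-sigma mean held-out
log-likelihood comes within one standard error of the global maximum — a
reproducible stand-in for picking the point "just before the plateau" on a
hold-out likelihood curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lpdsub.data_io import ExpressionMatrix
from lpdsub.lpd import LPDHyperParams, fit_lpd, holdout_loglik, variational_bound


@dataclass
class SelectionGrid:
    """Per-cell cross-validated hold-out log-likelihood statistics."""

    K_values: list[int]
    sigma_values: list[float]
    folds: int
    restarts: int
    seed: int
    mean: np.ndarray = field(default=None)  # (nK, nS) mean held-out LL per sample
    sd: np.ndarray = field(default=None)    # (nK, nS) sd over folds
    valid: np.ndarray = field(default=None)  # (nK, nS) bool

    def cell(self, K: int, sigma: float) -> tuple[float, float]:
        i = self.K_values.index(K)
        j = self.sigma_values.index(sigma)
        return float(self.mean[i, j]), float(self.sd[i, j])

    def to_dict(self) -> dict:
        return {
            "K_values": self.K_values,
            "sigma_values": self.sigma_values,
            "folds": self.folds,
            "restarts": self.restarts,
            "seed": self.seed,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "valid": self.valid.tolist(),
        }


def _fold_indices(D: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(D)
    return [perm[i::folds] for i in range(folds)]


DEFAULT_K_VALUES = list(range(2, 9))
DEFAULT_SIGMA_VALUES = [-0.1, -0.01, -0.001]


def grid_search(
    expr: ExpressionMatrix,
    K_values: list[int] = None,
    sigma_values: list[float] = None,
    folds: int = 5,
    restarts: int = 3,
    seed: int = 0,
    max_iter: int = 150,
    tol: float = 1e-5,
    sigma_dialect: str = "linear",
) -> SelectionGrid:
    """Cross-validate every (K, sigma) cell.

    Within a cell and fold, ``restarts`` seeded fits are run on the training
    folds and the one with the best training bound is scored on the held-out
    fold.  Fold splits are shared across cells so cells are comparable.
    """
    K_values = list(K_values or DEFAULT_K_VALUES)
    sigma_values = list(sigma_values or DEFAULT_SIGMA_VALUES)
    G, D = expr.shape
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    splits = _fold_indices(D, folds, rng)
    train_count = min(D - len(s) for s in splits)
    for K in K_values:
        if K > train_count:
            raise ValueError(f"K={K} exceeds training-fold sample count {train_count}")

    n_k, n_s = len(K_values), len(sigma_values)
    mean = np.full((n_k, n_s), -np.inf)
    sd = np.full((n_k, n_s), np.nan)
    valid = np.zeros((n_k, n_s), dtype=bool)
    sample_ids = np.asarray(expr.sample_ids)

    for i, K in enumerate(K_values):
        for j, sigma in enumerate(sigma_values):
            fold_scores = []
            for f, held_idx in enumerate(splits):
                train_idx = np.setdiff1d(np.arange(D), held_idx)
                train = expr.subset_samples(list(sample_ids[train_idx]))
                held = expr.subset_samples(list(sample_ids[held_idx]))
                best_fit, best_bound = None, -np.inf
                for r in range(restarts):
                    hp = LPDHyperParams(
                        K=K, sigma_spread=sigma, max_iter=max_iter, tol=tol,
                        seed=seed + 1009 * (i * n_s + j) + 101 * f + r,
                        sigma_dialect=sigma_dialect,
                    )
                    try:
                        cand = fit_lpd(train, hp)
                        b = variational_bound(train, cand)
                    except (RuntimeError, FloatingPointError):
                        continue
                    if b > best_bound:
                        best_fit, best_bound = cand, b
                if best_fit is None:
                    continue
                fold_scores.append(holdout_loglik(best_fit, held))
            if fold_scores:
                mean[i, j] = float(np.mean(fold_scores))
                sd[i, j] = float(np.std(fold_scores, ddof=1)) if len(fold_scores) > 1 else 0.0
                valid[i, j] = True
    if not valid.any():
        raise RuntimeError("all grid cells failed")
    return SelectionGrid(
        K_values=K_values, sigma_values=sigma_values, folds=folds,
        restarts=restarts, seed=seed, mean=mean, sd=sd, valid=valid,
    )


def select_operating_point(grid: SelectionGrid) -> tuple[int, float]:
    """One-standard-error plateau rule.

    The global-best cell sets the reference level; the selected K is the
    smallest whose best-over-sigma mean held-out log-likelihood is within one
    standard error (of the global-best cell, over folds) of that level;
    sigma is the argmax within the selected K.  Deterministic: ties resolve
    to the smaller K and the earlier sigma in the grid's order.
    """
    masked = np.where(grid.valid, grid.mean, -np.inf)
    i_best, j_best = np.unravel_index(np.argmax(masked), masked.shape)
    best_mean = masked[i_best, j_best]
    se = grid.sd[i_best, j_best] / np.sqrt(grid.folds)
    order = np.argsort(grid.K_values)
    for i in order:
        if not grid.valid[i].any():
            continue
        j = int(np.argmax(masked[i]))
        if masked[i, j] >= best_mean - se:
            return grid.K_values[i], grid.sigma_values[j]
    return grid.K_values[i_best], grid.sigma_values[j_best]
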