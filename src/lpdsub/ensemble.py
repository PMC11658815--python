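"""Restart-run ensembles with survival-anchored representative-run selection.

The decomposition is a non-convex fit, so it is repeated (by default 100
times) from different seeds.  Runs whose max-membership subtypes separate
survival (overall log-rank p below alpha, with a unique worst-surviving
subtype) are the "poor prognosis" runs; the representative run is the one
whose -log10(p) sits closest to the mode of the qualifying runs' values.
Subtypes are matched across datasets by Pearson correlation of median
z-score signatures over the shared input transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from lpdsub.clinical import km_estimate, logrank_test
from lpdsub.data_io import ClinicalTable, ExpressionMatrix
from lpdsub.lpd import LPDFit, LPDHyperParams, SubtypeAssignment, assign_subtypes, fit_lpd

log = logging.getLogger(__name__)


@dataclass
class RunRecord:
    seed: int
    fit: LPDFit | None
    assignment: SubtypeAssignment | None
    logrank_p: float | None
    worst_process: int | None
    worst_unique: bool
    error: str | None = None


@dataclass
class RunEnsemble:
    hp: LPDHyperParams
    base_seed: int
    runs: list[RunRecord]

    @property
    def ok_runs(self) -> list[RunRecord]:
        return [r for r in self.runs if r.fit is not None]

    def qualifying(self, alpha: float = 0.05) -> list[RunRecord]:
        """Runs associated with a poor-prognosis subtype."""
        return [
            r for r in self.ok_runs
            if r.logrank_p is not None and r.logrank_p < alpha and r.worst_unique
        ]


@dataclass
class SubtypeMatch:
    run_index: int
    process: int
    r: float
    p: float


def _survival_stats(
    assignment: SubtypeAssignment, clinical: ClinicalTable
) -> tuple[float | None, int | None, bool]:
    """Overall log-rank p across max-membership groups plus the worst-survival
    process (lowest KM curve at the median follow-up time)."""
    surv = clinical.survival(assignment.sample_ids)
    if len(surv) == 0:
        return None, None, False
    merged = surv.merge(
        pd.DataFrame({"sample_id": assignment.sample_ids, "label": assignment.labels}),
        on="sample_id",
    )
    groups = []
    labels = []
    for k, sub in merged.groupby("label"):
        groups.append((sub["time"].to_numpy(), sub["event"].to_numpy()))
        labels.append(int(k))
    if len(groups) < 2:
        return None, None, False
    p = logrank_test(groups).p
    t_ref = float(np.median(merged["time"]))
    km_at_ref = np.array([km_estimate(t, e).at(t_ref) for t, e in groups])
    order = np.argsort(km_at_ref)
    worst = labels[order[0]]
    unique = (km_at_ref == km_at_ref.min()).sum() == 1
    return float(p), worst, unique


def run_ensemble(
    expr: ExpressionMatrix,
    hp: LPDHyperParams,
    n_runs: int,
    base_seed: int,
    clinical: ClinicalTable | None = None,
) -> RunEnsemble:
    """Fit ``n_runs`` restarts with seeds base_seed..base_seed+n_runs-1.

    Individual run failures are recorded and the ensemble proceeds; an
    ensemble with no successful run raises.
    """
    runs: list[RunRecord] = []
    for i in range(n_runs):
        seed = base_seed + i
        try:
            fit = fit_lpd(expr, replace(hp, seed=seed))
            assignment = assign_subtypes(fit)
            if clinical is not None:
                p, worst, unique = _survival_stats(assignment, clinical)
            else:
                p, worst, unique = None, None, False
            runs.append(RunRecord(seed, fit, assignment, p, worst, unique))
        except (RuntimeError, FloatingPointError, ValueError) as exc:  # pragma: no cover
            log.warning("run with seed %d failed: %s", seed, exc)
            runs.append(RunRecord(seed, None, None, None, None, False, str(exc)))
    if not any(r.fit is not None for r in runs):
        raise RuntimeError("all ensemble runs failed")
    return RunEnsemble(hp=hp, base_seed=base_seed, runs=runs)


def count_poor_prognosis_runs(ensemble: RunEnsemble, alpha: float = 0.05) -> int:
    """Number of runs with log-rank p < alpha and a unique worst-survival
    subtype."""
    return len(ensemble.qualifying(alpha))


def select_representative_run(ensemble: RunEnsemble, alpha: float = 0.05) -> int:
    """Index (into ensemble.runs) of the run whose -log10(log-rank p) lies
    closest to the mode of the qualifying runs' values.

    The mode is the midpoint of the most populated histogram bin
    (Freedman-Diaconis width); ties go to the lowest seed.
    """
    qualifying = ensemble.qualifying(alpha)
    if not qualifying:
        raise RuntimeError("no qualifying runs to select from")
    x = np.array([-np.log10(r.logrank_p) for r in qualifying])
    if np.ptp(x) == 0:
        mode = x[0]
    else:
        counts, edges = np.histogram(x, bins="fd")
        b = int(np.argmax(counts))
        mode = 0.5 * (edges[b] + edges[b + 1])
    dist = np.abs(x - mode)
    seeds = np.array([r.seed for r in qualifying])
    best = int(np.lexsort((seeds, dist))[0])
    chosen_seed = qualifying[best].seed
    return next(i for i, r in enumerate(ensemble.runs) if r.seed == chosen_seed)


def subtype_signature(
    expr: ExpressionMatrix, assignment: SubtypeAssignment, process: int
) -> pd.Series:
    """Median z-score signature of one process.

    Genes are z-scored across all samples of the dataset; the signature is
    the per-gene median over the process's samples.  Constant genes (zero
    variance) are dropped with a warning.
    """
    members = [i for i, l in enumerate(assignment.labels) if l == process]
    if not members:
        raise ValueError(f"process {process} has no samples")
    x = expr.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0)
    if const.any():
        log.warning("%d constant genes dropped from signature", int(const.sum()))
    z = (x[~const] - mean[~const]) / sd[~const]
    med = np.median(z[:, members], axis=1)
    genes = [g for g, c in zip(expr.gene_ids, const) if not c]
    return pd.Series(med, index=genes, name=f"process_{process}")


def match_subtype(
    reference: pd.Series,
    ensemble: RunEnsemble,
    expr: ExpressionMatrix,
    min_shared_genes: int = 10,
) -> tuple[list[SubtypeMatch], int]:
    """Best-matching process per run, and the best run overall.

    Each run's processes are scored by Pearson correlation between their
    median z-score signature and the reference signature on the shared gene
    set; the run-level winner maximizes r (the validation-run criterion).
    Returns (per-run best matches, index into ensemble.runs of the best run).
    """
    per_run: list[SubtypeMatch] = []
    for i, run in enumerate(ensemble.runs):
        if run.fit is None:
            continue
        best = None
        for k in np.unique(run.assignment.labels):
            sig = subtype_signature(expr, run.assignment, int(k))
            shared = reference.index.intersection(sig.index)
            if len(shared) < min_shared_genes:
                raise ValueError(
                    f"only {len(shared)} shared genes (< {min_shared_genes})"
                )
            r, p = stats.pearsonr(reference[shared], sig[shared])
            if best is None or r > best.r:
                best = SubtypeMatch(run_index=i, process=int(k), r=float(r), p=float(p))
        per_run.append(best)
    if not per_run:
        raise RuntimeError("no successful runs to match against")
    best_idx = per_run[int(np.argmax([m.r for m in per_run]))].run_index
    return per_run, best_idx
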