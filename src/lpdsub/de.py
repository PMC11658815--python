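"""Negative-binomial Wald differential expression and over-representation.

The DE stage follows the standard count-based recipe: median-of-ratios size
factors, per-gene NB dispersion estimated by method of moments within
groups and shrunk toward a mean-dispersion trend, then a Wald test on the
group coefficient of an NB log-linear model with size-factor offsets.
Benjamini-Hochberg controls the FDR; calls are filtered on effect size and
adjusted p (strict |log2FC| > 1.5, padj < 0.01 by default), then made robust
by requiring the same-direction call in at least 80% of the qualifying
ensemble runs.  Over-representation against user-supplied gene sets uses the
upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lpdsub.data_io import CountMatrix


@dataclass
class DEResult:
    transcript: str
    log2fc: float
    se: float
    p: float
    padj: float
    direction: str            # "up" | "down"
    run_support: float | None = None


def size_factors_median_ratios(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios normalization factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of count / per-gene geometric mean.
    """
    x = counts.values.astype(float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; a pseudo-reference "
            "normalization would be required"
        )
    sub = x[all_nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    sf = np.median(sub / geomean, axis=0)
    return sf


def _dispersion_estimates(
    q: np.ndarray, cond: np.ndarray, inv_sf: np.ndarray
) -> np.ndarray:
    """Trend-shrunk NB dispersions from normalized counts ``q`` (genes x samples).

    Per gene, a within-group method-of-moments estimate
    alpha = (var - mu * mean(1/sf)) / mu^2 is pooled across the two groups,
    then geometrically shrunk toward a 1/mu parametric trend fitted across
    genes.
    """
    n_genes = q.shape[0]
    raw = np.full(n_genes, np.nan)
    mu_bar = q.mean(axis=1)
    num = np.zeros(n_genes)
    den = 0.0
    for g_val in np.unique(cond):
        sel = cond == g_val
        n_j = sel.sum()
        if n_j < 2:
            continue
        m_j = q[:, sel].mean(axis=1)
        v_j = q[:, sel].var(axis=1, ddof=1)
        w_inv = inv_sf[sel].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a_j = (v_j - m_j * w_inv) / m_j**2
        num += (n_j - 1) * np.nan_to_num(a_j)
        den += n_j - 1
    raw = num / max(den, 1)
    raw = np.clip(raw, 1e-8, 10.0)

    ok = mu_bar > 0
    # parametric trend alpha(mu) = a0 + a1/mu, least squares on the raw estimates
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_bar[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = np.clip(a0 + a1 / np.maximum(mu_bar, 1e-8), 1e-8, 10.0)
    return np.exp(0.5 * (np.log(raw) + np.log(trend)))


def nb_wald_de(
    counts: CountMatrix,
    condition: np.ndarray,
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test between two groups.

    ``condition`` holds exactly two distinct labels; the coefficient is the
    log2 fold change of the lexicographically larger label over the smaller.
    All-zero genes get NA p-values and are excluded from the BH denominator.
    """
    cond = np.asarray(condition)
    levels = sorted(pd.unique(cond).tolist())
    if len(levels) != 2:
        raise ValueError("nb_wald_de requires exactly two groups")
    for lev in levels:
        if (cond == lev).sum() < 2:
            raise ValueError("each group needs >= 2 samples")
    if size_factors is None:
        size_factors = size_factors_median_ratios(counts)
    sf = np.asarray(size_factors, dtype=float)

    y_all = counts.values.astype(float)
    q = y_all / sf[None, :]
    disp = _dispersion_estimates(q, cond, 1.0 / sf)

    x_design = np.column_stack([np.ones(len(cond)), (cond == levels[1]).astype(float)])
    offset = np.log(sf)
    ln2 = np.log(2.0)
    rows = []
    for g in range(y_all.shape[0]):
        y = y_all[g]
        if y.sum() == 0:
            rows.append((counts.gene_ids[g], np.nan, np.nan, np.nan))
            continue
        try:
            model = sm.GLM(
                y, x_design,
                family=sm.families.NegativeBinomial(alpha=float(disp[g])),
                offset=offset,
            )
            res = model.fit()
            beta, se = res.params[1], res.bse[1]
            z = beta / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((counts.gene_ids[g], beta / ln2, se / ln2, p))
        except Exception:
            rows.append((counts.gene_ids[g], np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["transcript", "log2fc", "se", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through and do not
    count toward the denominator."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def filter_de(
    results: pd.DataFrame,
    lfc_threshold: float = 1.5,
    padj_threshold: float = 0.01,
) -> pd.DataFrame:
    """Strict effect-size and significance filters: |log2FC| > lfc and
    padj < padj (both strict, so a log2FC of exactly 1.5 is excluded)."""
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be positive")
    keep = (results["log2fc"].abs() > lfc_threshold) & (
        results["padj"] < padj_threshold
    )
    return results[keep.fillna(False)].reset_index(drop=True)


def run_support_filter(
    per_run_de_sets: list[set[tuple[str, str]]],
    min_fraction: float = 0.8,
) -> pd.DataFrame:
    """Keep calls present with the same direction in >= min_fraction of runs.

    Each run's set contains (transcript, direction) pairs; a transcript up
    in half the runs and down in the other half supports neither call.
    Returns transcript, direction and the support fraction.
    """
    if not per_run_de_sets:
        raise ValueError("need >= 1 qualifying run")
    n = len(per_run_de_sets)
    tally: dict[tuple[str, str], int] = {}
    for s in per_run_de_sets:
        for key in s:
            tally[key] = tally.get(key, 0) + 1
    rows = [
        {"transcript": t, "direction": d, "run_support": c / n}
        for (t, d), c in sorted(tally.items())
        if c / n >= min_fraction
    ]
    return pd.DataFrame(rows, columns=["transcript", "direction", "run_support"])


def core_overlap(named_sets: dict[str, set]) -> tuple[set, pd.DataFrame]:
    """Exact intersection across datasets plus Venn-style subset counts."""
    if len(named_sets) < 2:
        raise ValueError("need >= 2 sets")
    names = list(named_sets)
    core = set.intersection(*named_sets.values())
    universe = set.union(*named_sets.values())
    rows = []
    for item in sorted(universe):
        membership = tuple(item in named_sets[n] for n in names)
        rows.append({"item": item, **dict(zip(names, membership))})
    table = pd.DataFrame(rows)
    return core, table


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int
    universe: int
    p: float
    padj: float
    members: list[str]


def hypergeom_enrichment(
    query: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each annotation term.

    Terms and the query are intersected with the universe first; p-values are
    BH-adjusted across terms.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & set(universe)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    m_univ = len(universe)
    n_query = len(query)
    rows = []
    for term, genes in annotation.items():
        genes = set(genes) & set(universe)
        overlap = sorted(query & genes)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(genes), n_query))
        rows.append({
            "term": term, "overlap": k, "set_size": len(genes),
            "universe": m_univ, "p": p, "members": ",".join(overlap),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (term, description, genes...) or a two-column
    gene<TAB>term file."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
            elif len(parts) == 2:
                gene, term = parts
                sets.setdefault(term, set()).add(gene)
    return sets


def pairwise_de(
    counts: CountMatrix,
    labels: np.ndarray,
    size_factors: np.ndarray | None = None,
    lfc_threshold: float = 1.5,
    padj_threshold: float = 0.01,
) -> dict[int, set[tuple[str, str]]]:
    """Per-process DE calls as the union of that process's pairwise contrasts.

    For each ordered process pair (k vs j), genes passing the filters enter
    process k's call set with the direction of the k-side fold change.
    """
    if size_factors is None:
        size_factors = size_factors_median_ratios(counts)
    labels = np.asarray(labels)
    procs = sorted(np.unique(labels).tolist())
    calls: dict[int, set[tuple[str, str]]] = {k: set() for k in procs}
    for a_idx in range(len(procs)):
        for b_idx in range(a_idx + 1, len(procs)):
            a_lab, b_lab = procs[a_idx], procs[b_idx]
            sel = np.isin(labels, [a_lab, b_lab])
            if (labels == a_lab).sum() < 2 or (labels == b_lab).sum() < 2:
                continue
            sub = CountMatrix(
                counts.values[:, sel], list(counts.gene_ids),
                [s for s, m in zip(counts.sample_ids, sel) if m],
            )
            res = nb_wald_de(sub, labels[sel], np.asarray(size_factors)[sel])
            hits = filter_de(res, lfc_threshold, padj_threshold)
            # nb_wald_de's coefficient is for the larger label over the smaller
            for _, row in hits.iterrows():
                up_in_b = row["log2fc"] > 0
                calls[b_lab].add((row["transcript"], "up" if up_in_b else "down"))
                calls[a_lab].add((row["transcript"], "down" if up_in_b else "up"))
    return calls
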