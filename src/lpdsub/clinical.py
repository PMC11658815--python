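"""Survival estimation and clinical association testing.

Kaplan-Meier curves, the log-rank chi-square test, Cox proportional-hazards
regression (Efron ties), Pearson chi-square on contingency tables (no
continuity correction), one-way ANOVA with Tukey HSD post hocs, and
Bonferroni adjustment.  Survival machinery delegates to lifelines; the
contingency and ANOVA tests to scipy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate of a survival function."""

    times: np.ndarray         # sorted distinct observed times
    at_risk: np.ndarray       # risk-set size just before each time
    events: np.ndarray        # events at each time
    survival: np.ndarray      # S(t) just after each time

    def at(self, t: float) -> float:
        """Survival probability at time t (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class AssociationResult:
    test: str
    statistic: float
    df: float
    p: float
    p_adjusted: float | None = None
    detail: object = None


def km_estimate(time: np.ndarray, event: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times shrink the risk set without introducing steps.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if (time < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    et = kmf.event_table
    times = et.index.to_numpy(dtype=float)
    # drop the synthetic baseline row lifelines adds at t=0 when no subject sits there
    keep = ~((times == 0.0) & (et["removed"].to_numpy() == 0))
    sf = kmf.survival_function_["KM_estimate"].to_numpy()
    return SurvivalCurve(
        times=times[keep],
        at_risk=et["at_risk"].to_numpy()[keep],
        events=et["observed"].to_numpy()[keep],
        survival=sf[keep],
    )


def logrank_test(
    groups: list[tuple[np.ndarray, np.ndarray]], pairwise: bool = False
):
    """Log-rank chi-square across >= 2 groups; df = groups - 1.

    ``groups`` is a list of (time, event) arrays.  With ``pairwise`` a
    DataFrame of all pairwise tests is returned alongside the overall result.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    for i, (t, e) in enumerate(groups):
        if len(t) == 0:
            raise ValueError(f"group {i} has no observations")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    overall = AssociationResult(
        test="logrank",
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p=float(res.p_value),
    )
    if not pairwise:
        return overall
    pw = pairwise_logrank_test(times, labels, events)
    return overall, pw.summary


def cox_ph(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    reference=None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional hazards on a categorical group indicator.

    Returns one row per non-reference level: hazard ratio, 95% CI and Wald
    p.  Efron tie handling by default ('breslow' by flag).  Complete
    separation is reported via lifelines' convergence warnings.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("cox_ph needs >= 2 groups")
    if event.sum() < 1:
        raise ValueError("cox_ph needs >= 1 event")
    if reference is None:
        reference = sorted(levels.tolist())[0]
    dummies = pd.get_dummies(pd.Categorical(group), dtype=float)
    dummies = dummies.drop(columns=[reference])
    df = pd.concat(
        [pd.DataFrame({"time": time, "event": event}), dummies.reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"step_size": 0.5})
    out = cph.summary[["coef", "exp(coef)", "exp(coef) lower 95%",
                       "exp(coef) upper 95%", "p"]].copy()
    out.columns = ["log_hr", "hr", "hr_lower95", "hr_upper95", "p"]
    out.index.name = "group"
    return out


def chi_square_independence(table: np.ndarray) -> AssociationResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.sum() == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 non-empty rows and columns")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(test="chi_square", statistic=float(stat), df=df, p=float(p))


def anova_tukey(values: np.ndarray, groups: np.ndarray) -> AssociationResult:
    """One-way ANOVA with Tukey HSD pairwise post hocs.

    Groups with fewer than 2 observations are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    by_group = []
    labels = []
    for g in pd.unique(groups):
        v = values[groups == g]
        if len(v) < 2:
            log.warning("group %r has < 2 values; excluded from ANOVA", g)
            continue
        by_group.append(v)
        labels.append(g)
    if len(by_group) < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f_stat, p = stats.f_oneway(*by_group)
    tukey = stats.tukey_hsd(*by_group)
    pairs = [
        {"group_a": labels[i], "group_b": labels[j],
         "diff": float(np.mean(by_group[i]) - np.mean(by_group[j])),
         "p_adj": float(tukey.pvalue[i, j])}
        for i in range(len(labels)) for j in range(i + 1, len(labels))
    ]
    return AssociationResult(
        test="anova", statistic=float(f_stat),
        df=len(by_group) - 1, p=float(p), detail=pd.DataFrame(pairs),
    )


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """min(1, m * p) elementwise; m defaults to the number of tests."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


def clinical_association_table(
    assignment_labels: np.ndarray,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = ("sample_type", "age", "ethnicity", "sex"),
    m: int | None = None,
) -> pd.DataFrame:
    """Chi-square (categorical) / ANOVA (age) of each covariate against the
    subtype assignment, Bonferroni-adjusted over the tests actually run.

    Missing covariate values are excluded pairwise.  ``m`` defaults to the
    number of covariates requested (matching a pre-registered family of
    comparisons) rather than the number that could be computed.
    """
    rows = []
    m_eff = m if m is not None else len(covariates)
    for cov in covariates:
        if cov not in clinical.columns:
            continue
        vals = clinical[cov]
        ok = vals.notna()
        if ok.sum() < 3 or vals[ok].nunique() < 2:
            continue
        if cov == "age":
            res = anova_tukey(vals[ok].to_numpy(float), assignment_labels[ok])
        else:
            table = pd.crosstab(vals[ok], assignment_labels[ok]).to_numpy()
            res = chi_square_independence(table)
        rows.append({"covariate": cov, "test": res.test,
                     "statistic": res.statistic, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bonferroni_adjust(out["p"].to_numpy(), m=m_eff)
    return out
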