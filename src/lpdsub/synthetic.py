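"""Synthetic cohort generator with the exact mixed-membership structure LPD assumes.

The generative model is the one the decomposition fits: per-sample process
weights theta_d ~ Dirichlet(alpha); independently for every gene g and sample
d a latent process z_gd ~ Categorical(theta_d); log-expression
e_gd ~ Normal(mu_{g,z}, sigma^2_{g,z}).  Drawing the process *per gene* (not
once per sample) is what makes samples genuine mixtures and distinguishes the
model from hard clustering.

Survival is exponential with hazard linear in theta (a "poor prognosis"
process carries a hazard multiplier > 1), with independent exponential
censoring.  Counts for the differential-expression stage are negative
binomial around 2^e - 1.  Every generator is driven by a counter-based
(Philox) RNG, so a fixed seed gives bit-identical output.

Default scale mirrors the study's development cohort: 88 samples, 500
high-variance transcripts, 3 latent processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lpdsub.data_io import ClinicalTable, CountMatrix, ExpressionMatrix


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=int(seed)))


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a simulated cohort."""

    K_true: int
    alpha_true: np.ndarray          # (K,)
    mu_true: np.ndarray             # (G, K)
    var_true: np.ndarray            # (G, K)
    theta_true: np.ndarray          # (D, K), rows on the simplex
    hazard_multipliers: np.ndarray  # (K,)
    seed: int

    def __post_init__(self) -> None:
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        self.mu_true = np.asarray(self.mu_true, dtype=float)
        self.var_true = np.asarray(self.var_true, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.hazard_multipliers = np.asarray(self.hazard_multipliers, dtype=float)
        if (self.alpha_true <= 0).any():
            raise ValueError("Dirichlet parameters must be positive")
        if (self.var_true <= 0).any():
            raise ValueError("variances must be positive")
        if (self.hazard_multipliers <= 0).any():
            raise ValueError("hazard multipliers must be positive")
        if not np.allclose(self.theta_true.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("theta rows must sum to 1")

    @property
    def dominant_process(self) -> np.ndarray:
        """Per-sample index of the highest-weight process."""
        return self.theta_true.argmax(axis=1)


def make_process_signatures(
    G: int,
    K: int,
    separation_sd: float = 3.0,
    noise_sd: float = 0.5,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene, per-process Gaussian parameters (mu, var).

    Each gene gets a shared baseline level; one process (chosen uniformly at
    random per gene) is shifted up by ``separation_sd`` within-process
    standard deviations, giving every process a distinctive signature across
    roughly G/K genes.
    """
    rng = _rng(seed)
    base = rng.normal(baseline_mean, baseline_sd, size=G)
    mu = np.tile(base[:, None], (1, K))
    up = rng.integers(0, K, size=G)
    mu[np.arange(G), up] += separation_sd * noise_sd
    var = np.full((G, K), noise_sd**2)
    return mu, var


def generate_lpd_data(
    G: int = 500,
    D: int = 88,
    K_true: int = 3,
    alpha: float | np.ndarray = 0.3,
    separation_sd: float = 3.0,
    noise_sd: float = 0.5,
    hazard_multipliers: np.ndarray | None = None,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a log-expression matrix from the mixed-membership model.

    If ``truth`` is given, its mu/var/alpha are reused (fresh theta and noise
    are still drawn, from ``seed``).  Returns genes x samples log-expression
    and the ground truth.
    """
    if K_true < 1 or G < 1 or D < 1:
        raise ValueError("K_true, G and D must all be >= 1")
    rng = _rng(seed)
    if truth is not None:
        alpha_vec = truth.alpha_true
        mu, var = truth.mu_true, truth.var_true
        K_true = truth.K_true
        hz = truth.hazard_multipliers
        if mu.shape[0] != G:
            raise ValueError("truth gene dimension does not match G")
    else:
        alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (K_true,)).copy()
        if (alpha_vec <= 0).any():
            raise ValueError("Dirichlet parameters must be positive")
        mu, var = make_process_signatures(
            G, K_true, separation_sd, noise_sd, seed=seed
        )
        if hazard_multipliers is None:
            hz = np.ones(K_true)
            hz[0] = 3.0  # process 0 plays the poor-prognosis subtype
        else:
            hz = np.asarray(hazard_multipliers, dtype=float)

    theta = rng.dirichlet(alpha_vec, size=D)                  # (D, K)
    cum = np.cumsum(theta, axis=1)
    u = rng.random((G, D))
    z = np.minimum((u[:, :, None] >= cum[None, :, :]).sum(axis=2), K_true - 1)
    sd = np.sqrt(var)
    rows = np.arange(G)[:, None]
    e = mu[rows, z] + rng.standard_normal((G, D)) * sd[rows, z]

    gene_ids = [f"g{i:04d}" for i in range(G)]
    sample_ids = [f"s{i:03d}" for i in range(D)]
    expr = ExpressionMatrix(e, gene_ids, sample_ids)
    truth_out = SyntheticTruth(
        K_true=K_true,
        alpha_true=alpha_vec,
        mu_true=mu,
        var_true=var,
        theta_true=theta,
        hazard_multipliers=hz,
        seed=seed,
    )
    return expr, truth_out


def generate_counts_from_expression(
    expr: ExpressionMatrix, dispersion: float, seed: int = 0
) -> CountMatrix:
    """Negative-binomial counts around mean 2^e - 1 (clipped at 0.1).

    ``dispersion`` is the NB dispersion in the Var = m + dispersion * m^2
    parameterization; draws use the gamma-Poisson mixture.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(seed)
    mean = np.maximum(np.exp2(expr.values) - 1.0, 0.1)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    counts = rng.poisson(lam)
    return CountMatrix(counts, list(expr.gene_ids), list(expr.sample_ids))


def generate_survival(
    theta_true: np.ndarray,
    hazard_multipliers: np.ndarray,
    baseline_rate: float = 0.05,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard linear in the process weights.

    hazard_d = baseline_rate * sum_k theta_dk * multiplier_k; censoring is an
    independent Exponential(censor_rate); event = 1 iff the event precedes
    censoring; the recorded time is the minimum of the two.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    theta = np.asarray(theta_true, dtype=float)
    hz = np.asarray(hazard_multipliers, dtype=float)
    if (hz <= 0).any():
        raise ValueError("hazard multipliers must be positive")
    rng = _rng(seed)
    rate = baseline_rate * theta @ hz
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate, size=len(rate))
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    return time, event


def generate_clinical_covariates(
    assignments: np.ndarray,
    skew: dict[str, dict],
    seed: int = 0,
) -> pd.DataFrame:
    """Categorical covariates drawn from subtype-specific distributions.

    ``skew`` maps a covariate name to ``{"categories": [...], "probs": P}``
    where P is (n_subtypes, n_categories) with rows summing to 1.  With
    identical rows the covariate is independent of subtype (the null).
    """
    rng = _rng(seed)
    assignments = np.asarray(assignments)
    out = {}
    for name, spec in skew.items():
        cats = list(spec["categories"])
        probs = np.asarray(spec["probs"], dtype=float)
        if probs.shape[1] != len(cats):
            raise ValueError(f"{name}: probability columns != categories")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError(f"{name}: probability rows must sum to 1")
        draws = [rng.choice(len(cats), p=probs[a]) for a in assignments]
        out[name] = [cats[i] for i in draws]
    return pd.DataFrame(out)


def simulate_cohort(
    G: int = 500,
    D: int = 88,
    K_true: int = 3,
    alpha: float | np.ndarray = 0.3,
    separation_sd: float = 3.0,
    noise_sd: float = 0.5,
    hazard_multipliers: np.ndarray | None = None,
    baseline_rate: float = 0.05,
    censor_rate: float = 0.05,
    dispersion: float = 0.1,
    seed: int = 0,
) -> dict:
    """Full synthetic study: expression, NB counts, clinical table, truth."""
    expr, truth = generate_lpd_data(
        G, D, K_true, alpha, separation_sd, noise_sd, hazard_multipliers, seed=seed
    )
    counts = generate_counts_from_expression(expr, dispersion, seed=seed + 1)
    time, event = generate_survival(
        truth.theta_true, truth.hazard_multipliers, baseline_rate, censor_rate,
        seed=seed + 2,
    )
    dominant = truth.dominant_process
    K = truth.K_true
    sex_probs = np.tile([0.45, 0.55], (K, 1))
    sex_probs[0] = [0.65, 0.35]  # poor-prognosis subtype skewed female, as in osteosarcoma
    covs = generate_clinical_covariates(
        dominant,
        {"sex": {"categories": ["F", "M"], "probs": sex_probs}},
        seed=seed + 3,
    )
    clin = pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "sample_type": "primary",
            "sex": covs["sex"],
            "time": time,
            "event": event,
        }
    )
    return {
        "expression": expr,
        "counts": counts,
        "clinical": ClinicalTable(clin),
        "truth": truth,
    }


def study_manifest():
    """Sample inventory of the four published osteosarcoma cohorts the
    study design mirrors (per-dataset counts by sample type)."""
    from lpdsub.data_io import DatasetManifest

    return DatasetManifest({
        "GREEN": {"primary": 7, "metastatic": 3, "cell_line": 0, "ctc": 5, "normal": 0},
        "PERRY": {"primary": 35, "metastatic": 0, "cell_line": 0, "ctc": 0, "normal": 0},
        "SCOTT": {"primary": 35, "metastatic": 9, "cell_line": 5, "ctc": 0, "normal": 3},
        "TARGET": {"primary": 88, "metastatic": 0, "cell_line": 0, "ctc": 0, "normal": 0},
    })


def table2_fixtures() -> dict[str, pd.DataFrame]:
    """Published contingency tables of clinical covariates vs the three subtypes.

    Columns are the three subtypes (sizes 26/39/23); rows the covariate
    levels.  These serve as fixed inputs for the association tests.
    """
    cols = ["LPD-1", "LPD-2", "LPD-3"]
    sex = pd.DataFrame(
        [[17, 9, 11], [9, 30, 12]], index=["Female", "Male"], columns=cols
    )
    ethnicity = pd.DataFrame(
        [[2, 3, 2], [2, 3, 2], [12, 27, 13]],
        index=["Asian", "Black/African descent", "Caucasian/European descent"],
        columns=cols,
    )
    vital = pd.DataFrame(
        [[10, 31, 16], [16, 7, 6]], index=["Alive", "Dead"], columns=cols
    )
    return {"sex": sex, "ethnicity": ethnicity, "vital_status": vital}
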