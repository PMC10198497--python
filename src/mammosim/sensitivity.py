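"""Latin-hypercube sensitivity analysis.

Perturbs calibrated parameters over a Latin-hypercube design (one sample
per equal-probability stratum per parameter, columns independently
permuted), re-runs the model for each parameter combination, and
summarizes the response of each outcome by multiple-regression
coefficients and partial correlation coefficients (PCCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .calibration_trials import replace_params
from .cohort import cohort_from_individuals, simulate_cohort
from .exposure_effects import EffectParameters
from .synthetic_population import PopulationConfig, default_config, sample_population
from .tissue_dynamics import RateParameters

__all__ = [
    "SensitivityDesign",
    "latin_hypercube",
    "sensitivity_regression",
    "run_sensitivity",
    "default_sensitivity_parameters",
]


@dataclass
class SensitivityDesign:
    """Perturbation ranges and sampling plan for one sensitivity run."""

    parameters: list[tuple[str, float, float]]  # (name, low, high)
    n_samples: int = 100
    n_individuals: int = 100_000
    outcomes: tuple[str, ...] = (
        "cumulative_incidence_75",
        "median_onset_age",
        "brca_rr",
        "breastfeeding_rr",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in self.parameters:
            if not lo < hi:
                raise ValueError(f"parameter {name}: low must be < high")


def default_sensitivity_parameters(
    params: RateParameters, fraction: float = 0.2
) -> list[tuple[str, float, float]]:
    """Symmetric +/-20% ranges around the calibrated rate parameters."""
    names = ["tau", "tau_final", "g0", "growth_rate_attenuation",
             "g_malignant", "lambda0", "late_loss_factor"]
    return [
        (n, getattr(params, n) * (1 - fraction),
         getattr(params, n) * (1 + fraction))
        for n in names
    ]


def latin_hypercube(
    design: SensitivityDesign, rng: np.random.Generator | None = None
) -> np.ndarray:
    """(n_samples, n_params) Latin-hypercube sample over the design ranges:
    exactly one draw per equal-width stratum per column, strata assigned by
    independent permutations across columns."""
    d = len(design.parameters)
    seed = design.seed if rng is None else rng
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(design.n_samples)
    lows = np.array([p[1] for p in design.parameters])
    highs = np.array([p[2] for p in design.parameters])
    return qmc.scale(unit, lows, highs)


def sensitivity_regression(
    parameter_matrix: np.ndarray,
    outcome_matrix: np.ndarray,
    parameter_names: list[str] | None = None,
    outcome_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(parameter, outcome) multiple-regression coefficient and
    partial correlation coefficient.

    The PCC is the correlation between the residuals of the parameter and
    of the outcome after each is regressed on all other parameters.
    Raises on rank-deficient designs (including n_samples <= n_params).
    """
    X = np.asarray(parameter_matrix, dtype=float)
    Y = np.atleast_2d(np.asarray(outcome_matrix, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"need more samples ({n}) than parameters ({p}) for regression"
        )
    X1 = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X1) < p + 1:
        raise ValueError("rank-deficient sensitivity design")
    pnames = parameter_names or [f"p{j}" for j in range(p)]
    onames = outcome_names or [f"y{j}" for j in range(Y.shape[1])]

    beta, *_ = np.linalg.lstsq(X1, Y, rcond=None)

    rows = []
    for j in range(p):
        others = np.column_stack(
            [np.ones(n)] + [X[:, k] for k in range(p) if k != j]
        )
        bx, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        rx = X[:, j] - others @ bx
        by, *_ = np.linalg.lstsq(others, Y, rcond=None)
        RY = Y - others @ by
        for m, oname in enumerate(onames):
            ry = RY[:, m]
            denom = np.sqrt((rx**2).sum() * (ry**2).sum())
            pcc = float((rx * ry).sum() / denom) if denom > 0 else 0.0
            rows.append(
                {"parameter": pnames[j], "outcome": oname,
                 "beta": float(beta[j + 1, m]), "pcc": pcc}
            )
    return pd.DataFrame(rows)


def _run_outcomes(
    params: RateParameters,
    effects: EffectParameters,
    cohort,
    outcomes: tuple[str, ...],
    seed: int,
) -> dict[str, float]:
    out = simulate_cohort(
        cohort, params, effects, mode="stochastic", seed=seed, horizon=75,
        use_screening=False, force_survival=True,
    )
    det = out.detection_age
    ci = float(np.mean(det <= 75))
    res: dict[str, float] = {}
    for name in outcomes:
        if name == "cumulative_incidence_75":
            res[name] = ci
        elif name == "median_onset_age":
            cases = det[det <= 75]
            res[name] = float(np.median(cases)) if len(cases) else np.nan
        elif name == "brca_rr":
            carriers = cohort.brca1
            ci_c = float(np.mean(det[carriers] <= 75)) if carriers.any() else np.nan
            ci_n = float(np.mean(det[~carriers] <= 75))
            res[name] = ci_c / ci_n if ci_n > 0 else np.nan
        elif name == "breastfeeding_rr":
            bf = cohort.breastfeeds & (cohort.first_birth >= 0)
            parous = cohort.first_birth >= 0
            ci_b = float(np.mean(det[bf] <= 75)) if bf.any() else np.nan
            ci_nb = float(np.mean(det[parous & ~bf] <= 75))
            res[name] = ci_b / ci_nb if ci_nb > 0 else np.nan
        else:
            raise ValueError(f"unknown outcome {name!r}")
    return res


def run_sensitivity(
    design: SensitivityDesign,
    params: RateParameters,
    effects: EffectParameters,
    config: PopulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full pipeline: design matrix -> model outcomes -> coefficients.

    Returns (design frame, outcomes frame, coefficient/PCC frame).  The
    population is sampled once and shared across runs, as are random
    streams, so outcome variation reflects the parameter perturbations.
    """
    config = config or default_config()
    X = latin_hypercube(design)
    pnames = [p[0] for p in design.parameters]
    pop = sample_population(config, design.n_individuals, seed=design.seed)
    cohort = cohort_from_individuals(pop)

    records = []
    for i in range(design.n_samples):
        p = params
        for j, name in enumerate(pnames):
            p = replace_params(p, name, X[i, j])
        records.append(
            _run_outcomes(p, effects, cohort, design.outcomes, design.seed)
        )
    design_df = pd.DataFrame(X, columns=pnames)
    design_df.insert(0, "run_id", np.arange(design.n_samples))
    outcomes_df = pd.DataFrame(records)
    outcomes_df.insert(0, "run_id", np.arange(design.n_samples))

    Y = outcomes_df[list(design.outcomes)].to_numpy()
    keep = ~np.isnan(Y).any(axis=1)
    coef = sensitivity_regression(
        X[keep], Y[keep], pnames, list(design.outcomes)
    )
    return design_df, outcomes_df, coef
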