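"""Calibration of physiology and exposure effect sizes; in-silico trials.

Calibration is staged: the baseline physiology is tuned first (incidence
magnitude, onset timing, old-age downturn), then each exposure's effect
size is solved one at a time by 1-D root finding against a published
epidemiologic target (a relative risk or cumulative risk), holding the
baseline fixed.  Every exposure statistic is monotone in its own
parameter, so bisection on a bracketing interval is sufficient.

Counterfactual pairing and common random numbers: the two arms of every
contrast share the same sampled women and the same uniform random streams
(the engine's transformation draws are inverse-CDF Poisson on uniforms
keyed by seed, age and individual), so an arm with the intervention
nullified reproduces the control arm exactly and Monte-Carlo noise largely
cancels in relative risks.  Trial cohorts force survival to the horizon so
windowed relative risks are free of competing mortality.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortArrays, CohortOutcomes, cohort_from_individuals, simulate_cohort
from .exposure_effects import BMI_REFERENCE, EffectParameters
from .synthetic_population import PopulationConfig, default_config, sample_population
from .tissue_dynamics import RateParameters

__all__ = [
    "CalibrationTarget",
    "CalibrationError",
    "CalibrationContext",
    "TrialSpec",
    "calibrate_baseline",
    "calibrate_exposure",
    "calibrate_all",
    "default_exposure_targets",
    "default_baseline_targets",
    "simulate_screening_trial",
    "simulate_ht_trial",
    "simulate_oc_trial",
]

HORIZON = 75  # risk-accumulation horizon (years of age) for targets


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationTarget:
    """A named simulated statistic and the value calibration must hit.

    ``tolerance`` is relative to ``target_value``; ``n_sim`` is the cohort
    size per arm; ``common_random_numbers`` keeps the engine seed fixed
    across root-finding iterations and arms.
    """

    name: str
    statistic: str
    target_value: float
    tolerance: float = 0.01
    weight: float = 1.0
    n_sim: int = 100_000
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.weight <= 0:
            raise ValueError("tolerance and weight must be positive")


@dataclass
class TrialSpec:
    """Arms of a paired counterfactual trial (identical women, shared
    random streams, differing only in the intervention)."""

    name: str
    n_per_arm: int
    horizon: int = HORIZON
    seed: int = 0


@dataclass
class CalibrationContext:
    """Shared state for staged calibration: the calibrated-so-far baseline
    and the population the contrast cohorts are carved from."""

    params: RateParameters
    effects: EffectParameters
    config: PopulationConfig = field(default_factory=default_config)
    seed: int = 0
    _population_cache: dict = field(default_factory=dict, repr=False)

    def base_cohort(self, n: int) -> CohortArrays:
        key = ("base", n)
        if key not in self._population_cache:
            pop = sample_population(self.config, n, seed=self.seed + 11)
            self._population_cache[key] = cohort_from_individuals(pop)
        return self._population_cache[key]


def _simulate(
    co: CohortArrays,
    params: RateParameters,
    effects: EffectParameters,
    seed: int,
    horizon: int = HORIZON,
) -> CohortOutcomes:
    return simulate_cohort(
        co,
        params,
        effects,
        mode="stochastic",
        seed=seed,
        horizon=horizon,
        use_screening=False,
        force_survival=True,
    )


def _ci(out: CohortOutcomes, age: float = HORIZON) -> float:
    return float(np.mean(out.detection_age <= age))


# ---------------------------------------------------------------------------
# Baseline calibration
# ---------------------------------------------------------------------------

def default_baseline_targets() -> list[CalibrationTarget]:
    """Plausible contemporary-US incidence anchors for the uncalibrated
    baseline: lifetime-scale risk to 75 of ~10.5% and median onset in the
    mid-sixties among cases before 75."""
    return [
        CalibrationTarget("incidence magnitude", "cumulative_incidence_75",
                          0.105, tolerance=0.03, n_sim=50_000),
        CalibrationTarget("onset timing", "median_onset_age", 66.0,
                          tolerance=0.02, n_sim=50_000),
    ]


_BASELINE_LEVERS = {
    # statistic -> (parameter, increasing in parameter?, bracket factor)
    "cumulative_incidence_75": ("tau", True, 1.6),
    "median_onset_age": ("g0", False, 1.5),
    "log_slope": ("tau_final", True, 4.0),
    "late_downturn_ratio": ("late_loss_factor", False, 2.0),
}


def _baseline_statistic(
    statistic: str, out: CohortOutcomes
) -> float:
    det = out.detection_age
    if statistic == "cumulative_incidence_75":
        return float(np.mean(det <= HORIZON))
    if statistic == "median_onset_age":
        cases = det[det <= HORIZON]
        if len(cases) == 0:
            return np.inf
        return float(np.median(cases))
    if statistic == "late_downturn_ratio":
        from .epi_stats import age_specific_incidence

        curve = age_specific_incidence(out, bins=np.arange(0, 100, 5))
        peak = curve.rate.max()
        late = curve.rate[(curve.bin_start == 85)][0]
        return float(late / peak) if peak > 0 else np.inf
    if statistic == "log_slope":
        from .epi_stats import age_specific_incidence, log_slope

        curve = age_specific_incidence(out, bins=np.arange(0, 100, 5))
        return log_slope(curve, (30.0, 55.0))
    raise CalibrationError(f"unknown baseline statistic {statistic!r}")


def _solve_monotone(
    f, x0: float, increasing: bool, target: float, tol_abs: float,
    bracket_factor: float, budget: list, name: str,
    x_min: float = 1e-12, x_max: float = 1e6,
):
    """Bisection on a monotone noisy statistic; expands the bracket
    geometrically from ``x0`` first.  ``budget`` is a single-element list
    of remaining evaluations, shared across stages."""

    def eval_f(x):
        if budget[0] <= 0:
            raise CalibrationError(
                f"evaluation budget exhausted while calibrating {name} "
                f"(worst offender: {name})"
            )
        budget[0] -= 1
        return f(x)

    sign = 1.0 if increasing else -1.0
    best = [None, np.inf]  # (x, |f - target|)

    def record(x, fx):
        if abs(fx - target) < best[1]:
            best[0], best[1] = (x, fx), abs(fx - target)

    f0 = eval_f(x0)
    record(x0, f0)
    if abs(f0 - target) <= tol_abs:
        return x0, f0
    lo = hi = x0
    if sign * (f0 - target) < 0:  # need larger x
        while True:
            nxt = min(hi * bracket_factor, x_max)
            if nxt == hi:
                raise CalibrationError(
                    f"cannot bracket target {target} for {name}: statistic "
                    f"stuck at {f0:.4g} at the parameter bound {x_max}"
                )
            lo, hi = hi, nxt
            fh = eval_f(hi)
            record(hi, fh)
            if abs(fh - target) <= tol_abs:
                return hi, fh
            if sign * (fh - target) >= 0:
                break
    else:
        while True:
            nxt = max(lo / bracket_factor, x_min)
            if nxt == lo:
                raise CalibrationError(
                    f"cannot bracket target {target} for {name}: statistic "
                    f"stuck at {f0:.4g} at the parameter bound {x_min}"
                )
            lo, hi = nxt, lo
            fl = eval_f(lo)
            record(lo, fl)
            if abs(fl - target) <= tol_abs:
                return lo, fl
            if sign * (fl - target) < 0:
                break
    # geometric bisection (rates live on a log scale); with few-case
    # statistics the response is a step function, so return the best
    # point seen once the interval is resolved or the budget runs out
    for _ in range(30):
        if budget[0] <= 0 or hi / lo < 1.004:
            break
        x = np.sqrt(lo * hi)
        fx = eval_f(x)
        record(x, fx)
        if abs(fx - target) <= tol_abs:
            return x, fx
        if sign * (fx - target) < 0:
            lo = x
        else:
            hi = x
    (xb, fb), _ = best
    return xb, fb


def calibrate_baseline(
    params0: RateParameters,
    targets: list[CalibrationTarget] | None = None,
    budget: int = 120,
    *,
    effects: EffectParameters | None = None,
    config: PopulationConfig | None = None,
    seed: int = 0,
    sweeps: int = 2,
) -> RateParameters:
    """Stage the baseline physiology onto incidence targets.

    Levers are applied in a fixed order (transformation rate for
    magnitude/timing, final-step rate for slope, late-loss for the old-age
    downturn), each solved by 1-D search at fixed common random numbers;
    two sweeps absorb the mild interaction between levers.  Raises
    :class:`CalibrationError` when the budget runs out or a target cannot
    be bracketed, naming the worst offender.
    """
    if targets is None:
        targets = default_baseline_targets()
    if not targets:
        return params0
    effects = effects or EffectParameters()
    config = config or default_config()
    ctx = CalibrationContext(params0, effects, config, seed)
    params = copy.deepcopy(params0)
    shared_budget = [budget]

    order = list(_BASELINE_LEVERS)
    targets_by_stat = {t.statistic: t for t in targets}
    unknown = set(targets_by_stat) - set(order)
    if unknown:
        raise CalibrationError(f"no lever for statistics {sorted(unknown)}")

    for _ in range(sweeps):
        for stat in order:
            if stat not in targets_by_stat:
                continue
            t = targets_by_stat[stat]
            lever, increasing, factor = _BASELINE_LEVERS[stat]
            co = ctx.base_cohort(t.n_sim)

            def f(x, lever=lever, stat=stat):
                p = replace_params(params, lever, x)
                out = _simulate(co, p, effects, seed=ctx.seed,
                                horizon=HORIZON if stat != "late_downturn_ratio" else 95)
                return _baseline_statistic(stat, out)

            tol_abs = t.tolerance * abs(t.target_value)
            x, achieved = _solve_monotone(
                f, getattr(params, lever), increasing, t.target_value,
                tol_abs, factor, shared_budget, t.name,
            )
            params = replace_params(params, lever, x)
    return params


def replace_params(params: RateParameters, name: str, value: float) -> RateParameters:
    p = copy.deepcopy(params)
    setattr(p, name, value)
    return p


# ---------------------------------------------------------------------------
# Exposure calibration
# ---------------------------------------------------------------------------

def default_exposure_targets() -> dict[str, CalibrationTarget]:
    """Literature anchors for each exposure effect size.

    BRCA1 carrier cumulative risk 0.57 by 75; breastfeeding RR 0.76;
    +12% risk per 5 BMI units; +7.1% risk per 10 g/day alcohol; OC
    during-use RR 1.24; HT 1-4-year-duration RR 1.05; smoking RR 1.10
    (a mid-range current-smoker estimate); polygenic-score risk gradient
    1.55 per standard deviation.
    """
    return {
        "brca_mult": CalibrationTarget(
            "BRCA1 carrier risk", "carrier_ci75", 0.57, tolerance=0.01
        ),
        "prs_scale": CalibrationTarget(
            "PRS gradient per SD", "prs_rr_per_sd", 1.55, tolerance=0.01
        ),
        "bf_loss_factor": CalibrationTarget(
            "breastfeeding RR", "breastfeeding_rr75", 0.76, tolerance=0.01
        ),
        "bmi_per5_growth": CalibrationTarget(
            "BMI risk per 5 units", "bmi_rr_per5", 1.12, tolerance=0.01
        ),
        "beta_alcohol": CalibrationTarget(
            "alcohol risk at 10 g/day", "alcohol_rr_10g", 1.071,
            tolerance=0.007
        ),
        "sigma_smoke": CalibrationTarget(
            "smoking RR", "smoker_rr75", 1.10, tolerance=0.01
        ),
        "m_oc": CalibrationTarget(
            "OC during-use RR", "oc_during_use_rr", 1.24, tolerance=0.015
        ),
        "m_ht": CalibrationTarget(
            "HT 1-4y duration RR", "ht_duration_1_4_rr", 1.05,
            tolerance=0.01
        ),
    }


def _neutral_cohort(co: CohortArrays) -> CohortArrays:
    """Strip every calibrated exposure so single-exposure contrasts are
    clean: median life courses kept, behaviours and genetics neutralized."""
    n = co.n
    return co.replace_fields(
        breastfeeds=np.zeros(n, dtype=bool),
        smoker=np.zeros(n, dtype=bool),
        grams_per_day=np.zeros(n),
        bmi_category=np.array(["normal"] * n, dtype=object),
        bmi_midpoint=None,
        oc_start=np.full(n, -1),
        oc_stop=np.full(n, -1),
        ht_duration=np.zeros(n, dtype=np.int64),
        brca1=np.zeros(n, dtype=bool),
    )


def _exposure_arms(param: str, ctx: CalibrationContext, n: int):
    """(exposed_cohort, control_cohort_or_None) for a single-exposure
    contrast; control is None when the statistic needs only one arm."""
    base = _neutral_cohort(ctx.base_cohort(n))
    nn = base.n
    if param == "brca_mult":
        return base.replace_fields(brca1=np.ones(nn, dtype=bool)), None
    if param == "prs_scale":
        return (
            base.replace_fields(prs=np.ones(nn)),
            base.replace_fields(prs=np.zeros(nn)),
        )
    if param == "bf_loss_factor":
        parous = base.first_birth >= 0
        sub = _subset(base, parous)
        return (
            sub.replace_fields(breastfeeds=np.ones(sub.n, dtype=bool)),
            sub,
        )
    if param == "bmi_per5_growth":
        return (
            base.replace_fields(
                bmi_midpoint=np.full(nn, BMI_REFERENCE + 5.0)
            ),
            base.replace_fields(bmi_midpoint=np.full(nn, BMI_REFERENCE)),
        )
    if param == "beta_alcohol":
        return base.replace_fields(grams_per_day=np.full(nn, 10.0)), base
    if param == "sigma_smoke":
        return base.replace_fields(smoker=np.ones(nn, dtype=bool)), base
    raise CalibrationError(f"no contrast defined for parameter {param!r}")


def _subset(co: CohortArrays, mask: np.ndarray) -> CohortArrays:
    fields = {}
    from dataclasses import fields as dc_fields

    for f in dc_fields(co):
        v = getattr(co, f.name)
        fields[f.name] = v[mask] if isinstance(v, np.ndarray) else v
    return CohortArrays(**fields)


def _set_effect(effects: EffectParameters, params: RateParameters,
                name: str, value: float):
    """The breastfeeding loss factor lives with the physiology rates; all
    other calibrated effect sizes live in EffectParameters."""
    if name == "bf_loss_factor":
        return effects, replace_params(params, name, value)
    e = copy.deepcopy(effects)
    setattr(e, name, value)
    return e, params


def _exposure_statistic(
    param: str,
    value: float,
    ctx: CalibrationContext,
    n_sim: int,
    cache: dict,
) -> float:
    effects, params = _set_effect(ctx.effects, ctx.params, param, value)

    if param == "m_oc":
        # during-use cases are rare: pool five population replicates and
        # stop at the oldest possible stopping age
        table = simulate_oc_trial(params, effects, n_sim, ctx.seed,
                                  config=ctx.config, horizon=46,
                                  n_replicates=5, strata="during",
                                  _cache=cache)
        return float(
            table.loc[table.stratum == "during_use", "model_value"].iloc[0]
        )
    if param == "m_ht":
        table = simulate_ht_trial(params, effects, n_sim, ctx.seed,
                                  config=ctx.config, horizon=62,
                                  n_replicates=4, strata="duration",
                                  _cache=cache)
        sel = (table.stratum_type == "duration_of_use") & (
            table.stratum == "1-4"
        )
        return float(table.loc[sel, "model_value"].iloc[0])

    if "arms" not in cache:
        cache["arms"] = _exposure_arms(param, ctx, n_sim)
    exposed_co, control_co = cache["arms"]

    out_e = _simulate(exposed_co, params, effects, seed=ctx.seed)
    ci_e = _ci(out_e)
    if param == "brca_mult":
        return ci_e
    if "control_ci" not in cache:
        # control arm does not depend on the calibrated parameter
        e0, p0 = _set_effect(ctx.effects, ctx.params, param,
                             _identity_value(param))
        cache["control_ci"] = _ci(
            _simulate(control_co, p0, e0, seed=ctx.seed)
        )
    ci_c = cache["control_ci"]
    if ci_c == 0:
        raise CalibrationError(f"no control-arm cases for {param}")
    return ci_e / ci_c


def _identity_value(param: str) -> float:
    return 0.0 if param in ("beta_alcohol", "prs_scale") else 1.0


_EXPOSURE_BRACKETS = {
    # parameter: (x0, increasing statistic?, bracket factor, x_min, x_max)
    "brca_mult": (1.6, True, 1.5, 1.0001, 100.0),
    "prs_scale": (0.09, True, 1.5, 1e-4, 2.0),
    "bf_loss_factor": (30.0, False, 2.2, 1.0001, 5e4),
    "bmi_per5_growth": (1.4, True, 1.3, 1.0001, 50.0),
    "beta_alcohol": (0.0015, True, 1.8, 1e-6, 1.0),
    "sigma_smoke": (1.02, True, 1.15, 1.0001, 20.0),
    "m_oc": (1.15, True, 1.25, 1.0001, 20.0),
    "m_ht": (1.05, True, 1.25, 1.0001, 20.0),
}


def calibrate_exposure(
    effect_param: str,
    target: CalibrationTarget,
    context: CalibrationContext,
    budget: int = 25,
    x0: float | None = None,
) -> float:
    """Solve one exposure effect size against its target by monotone 1-D
    search with common random numbers; returns the calibrated value.

    ``x0`` warm-starts the search (e.g. from a previously calibrated
    parameter file); the default starting points are order-of-magnitude
    guesses.
    """
    if effect_param not in _EXPOSURE_BRACKETS:
        raise CalibrationError(f"unknown exposure parameter {effect_param!r}")
    default_x0, increasing, factor, x_min, x_max = _EXPOSURE_BRACKETS[effect_param]
    if x0 is None:
        x0 = default_x0
    cache: dict = {}
    shared_budget = [budget]

    def f(x):
        return _exposure_statistic(
            effect_param, x, context, target.n_sim, cache
        )

    tol_abs = target.tolerance * abs(target.target_value)
    x, achieved = _solve_monotone(
        f, x0, increasing, target.target_value, tol_abs, factor,
        shared_budget, target.name, x_min=x_min, x_max=x_max,
    )
    return float(x)


def calibrate_all(
    params: RateParameters,
    effects: EffectParameters,
    *,
    config: PopulationConfig | None = None,
    seed: int = 0,
    targets: dict[str, CalibrationTarget] | None = None,
    n_sim: int | None = None,
    budget_per_exposure: int = 25,
    warm_start: bool = False,
) -> tuple[RateParameters, EffectParameters, pd.DataFrame]:
    """Calibrate every exposure effect size in sequence against the fixed
    baseline; returns updated parameters and a report table."""
    config = config or default_config()
    targets = targets or default_exposure_targets()
    ctx = CalibrationContext(params, effects, config, seed)
    rows = []
    for param, target in targets.items():
        if n_sim is not None:
            target = replace(target, n_sim=n_sim)
        if warm_start:
            current = (getattr(params, param) if param == "bf_loss_factor"
                       else getattr(effects, param))
            value = calibrate_exposure(param, target, ctx,
                                       budget_per_exposure, x0=current)
        else:
            value = calibrate_exposure(param, target, ctx, budget_per_exposure)
        ctx.effects, ctx.params = _set_effect(
            ctx.effects, ctx.params, param, value
        )
        achieved = _exposure_statistic(param, value, ctx, target.n_sim, {})
        rows.append(
            {
                "target": target.name,
                "statistic": target.statistic,
                "target_value": target.target_value,
                "achieved": achieved,
                "tolerance": target.tolerance,
                "parameter": param,
                "value": value,
            }
        )
    return ctx.params, ctx.effects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulated randomized trials
# ---------------------------------------------------------------------------

def simulate_oc_trial(
    params: RateParameters,
    effects: EffectParameters,
    n_per_arm: int,
    seed: int,
    *,
    config: PopulationConfig | None = None,
    horizon: int = HORIZON,
    n_replicates: int = 1,
    strata: str = "all",
    _cache: dict | None = None,
) -> pd.DataFrame:
    """Paired counterfactual oral-contraceptive trial.

    The treatment arm is the population's OC ever-users; the control arm
    is the same women with OC use removed (growth multiplier nullified),
    sharing all random streams.  Relative risks of detected cancer are
    reported during use and 1-4, 5-9 and 10+ years after stopping, next to
    the published epidemiologic estimates they are calibrated against.

    Because during-use cases are rare (the use window sits at young ages),
    case counts can be pooled over ``n_replicates`` independent population
    replicates; ``strata="during"`` restricts the table to the during-use
    window (used by calibration, where a shorter ``horizon`` suffices).
    """
    config = config or default_config()
    cache = _cache if _cache is not None else {}
    windows_spec = [
        ("during_use", 0, 0, 1.24),
        ("stopped_1_4", 1, 5, 1.16),
        ("stopped_5_9", 5, 10, 1.07),
        ("stopped_10_plus", 10, 10_000, 1.01),
    ]
    if strata == "during":
        windows_spec = windows_spec[:1]
    elif strata != "all":
        raise ValueError(f"unknown strata selection {strata!r}")

    counts = {w[0]: [0, 0] for w in windows_spec}
    for r in range(n_replicates):
        rseed = seed + 7919 * r
        key = ("oc_cohort", r)
        if key not in cache:
            ctx = CalibrationContext(params, effects, config, rseed)
            base = ctx.base_cohort(n_per_arm)
            users = base.oc_start >= 0
            if not users.any():
                raise CalibrationError("population has no OC users")
            cache[key] = _subset(_neutral_oc(base), users)
        co = cache[key]

        out_e = _simulate(co, params, effects, seed=rseed, horizon=horizon)
        ckey = ("oc_control", r)
        if ckey not in cache:
            e0 = copy.deepcopy(effects)
            e0.m_oc = 1.0
            cache[ckey] = _simulate(co, params, e0, seed=rseed,
                                    horizon=horizon)
        out_c = cache[ckey]

        det_e = np.nan_to_num(out_e.detection_time, nan=-1.0)
        det_c = np.nan_to_num(out_c.detection_time, nan=-1.0)
        for label, off_lo, off_hi, _ in windows_spec:
            if label == "during_use":
                lo, hi = co.oc_start, co.oc_stop
            else:
                lo, hi = co.oc_stop + off_lo, co.oc_stop + off_hi
            counts[label][0] += int(np.sum((det_e >= lo) & (det_e < hi)))
            counts[label][1] += int(np.sum((det_c >= lo) & (det_c < hi)))

    rows = []
    for label, _, _, reported in windows_spec:
        ce, cc = counts[label]
        if cc == 0:
            raise CalibrationError(
                f"no control-arm cases in window {label!r}"
            )
        rows.append(
            {"stratum": label, "reported_value": reported,
             "model_value": ce / cc, "exposed_cases": ce,
             "control_cases": cc}
        )
    return pd.DataFrame(rows)


def _neutral_oc(co: CohortArrays) -> CohortArrays:
    """Keep OC exposure, neutralize the other calibrated behaviours so the
    trial isolates the OC contrast."""
    n = co.n
    return co.replace_fields(
        breastfeeds=np.zeros(n, dtype=bool),
        smoker=np.zeros(n, dtype=bool),
        grams_per_day=np.zeros(n),
        bmi_category=np.array(["normal"] * n, dtype=object),
        ht_duration=np.zeros(n, dtype=np.int64),
        brca1=np.zeros(n, dtype=bool),
    )


def simulate_ht_trial(
    params: RateParameters,
    effects: EffectParameters,
    n_per_arm: int,
    seed: int,
    *,
    config: PopulationConfig | None = None,
    horizon: int = HORIZON,
    n_replicates: int = 1,
    strata: str = "all",
    _cache: dict | None = None,
) -> pd.DataFrame:
    """Paired counterfactual hormone-therapy trial.

    Treatment arm: the population's HT users (use starts at menopause,
    duration from the four-quantile scheme).  Control arm: the same women
    with the HT growth effect nullified.  Relative risks are reported by
    duration of use (cases during the use window, within each duration
    stratum), by time since first use and by time since last use, next to
    the published estimates.
    """
    config = config or default_config()
    cache = _cache if _cache is not None else {}

    duration_strata = [("1-4", 1, 4, 1.05), ("5-9", 5, 9, None),
                       ("10-14", 10, 14, 1.09), ("15_plus", 15, 99, None)]
    first_use = [("lt5", 0, 5, 0.99), ("5-9", 5, 10, 1.11),
                 ("10-14", 10, 15, 1.19), ("15-19", 15, 20, 1.22),
                 ("20_plus", 20, 999, 1.20)]
    last_use = [("1-4", 1, 5, 1.10), ("5-9", 5, 10, 1.01),
                ("10-14", 10, 15, 1.05), ("15_plus", 15, 999, 1.12)]
    if strata == "duration":
        first_use = last_use = []
    elif strata != "all":
        raise ValueError(f"unknown strata selection {strata!r}")

    counts: dict[tuple[str, str], list] = {}

    def tally(kind, label, ce, cc):
        counts.setdefault((kind, label), [0, 0])
        counts[(kind, label)][0] += ce
        counts[(kind, label)][1] += cc

    for r in range(n_replicates):
        rseed = seed + 7919 * r
        key = ("ht_cohort", r)
        if key not in cache:
            ctx = CalibrationContext(params, effects, config, rseed)
            base = ctx.base_cohort(n_per_arm)
            users = base.ht_duration > 0
            if not users.any():
                raise CalibrationError("population has no HT users")
            co = _subset(base, users)
            n = co.n
            cache[key] = co.replace_fields(
                breastfeeds=np.zeros(n, dtype=bool),
                smoker=np.zeros(n, dtype=bool),
                grams_per_day=np.zeros(n),
                bmi_category=np.array(["normal"] * n, dtype=object),
                oc_start=np.full(n, -1),
                oc_stop=np.full(n, -1),
                brca1=np.zeros(n, dtype=bool),
            )
        co = cache[key]

        out_e = _simulate(co, params, effects, seed=rseed, horizon=horizon)
        ckey = ("ht_control", r)
        if ckey not in cache:
            e0 = copy.deepcopy(effects)
            e0.m_ht = 1.0
            cache[ckey] = _simulate(co, params, e0, seed=rseed,
                                    horizon=horizon)
        out_c = cache[ckey]

        det_e = np.nan_to_num(out_e.detection_time, nan=-1.0)
        det_c = np.nan_to_num(out_c.detection_time, nan=-1.0)
        meno = co.menopause
        stop = co.menopause + co.ht_duration

        for label, dlo, dhi, _ in duration_strata:
            sel = (co.ht_duration >= dlo) & (co.ht_duration <= dhi)
            if not sel.any():
                continue
            ce = int(np.sum((det_e[sel] >= meno[sel])
                            & (det_e[sel] < stop[sel])))
            cc = int(np.sum((det_c[sel] >= meno[sel])
                            & (det_c[sel] < stop[sel])))
            tally("duration_of_use", label, ce, cc)
        for label, wlo, whi, _ in first_use:
            ce = int(np.sum((det_e >= meno + wlo) & (det_e < meno + whi)))
            cc = int(np.sum((det_c >= meno + wlo) & (det_c < meno + whi)))
            tally("time_since_first_use", label, ce, cc)
        for label, wlo, whi, _ in last_use:
            ce = int(np.sum((det_e >= stop + wlo) & (det_e < stop + whi)))
            cc = int(np.sum((det_c >= stop + wlo) & (det_c < stop + whi)))
            tally("time_since_last_use", label, ce, cc)

    reported_map = {
        ("duration_of_use", lab): rep for lab, _, _, rep in duration_strata
    }
    reported_map.update(
        {("time_since_first_use", lab): rep
         for lab, _, _, rep in first_use}
    )
    reported_map.update(
        {("time_since_last_use", lab): rep for lab, _, _, rep in last_use}
    )
    rows = []
    for (kind, label), (ce, cc) in counts.items():
        if cc == 0:
            raise CalibrationError(
                f"no control-arm cases in stratum {kind}/{label}"
            )
        rows.append({"stratum_type": kind, "stratum": label,
                     "reported_value": reported_map[(kind, label)],
                     "model_value": ce / cc, "exposed_cases": ce,
                     "control_cases": cc})
    return pd.DataFrame(rows)


def simulate_screening_trial(
    params: RateParameters,
    effects: EffectParameters,
    n_per_arm: int,
    seed: int,
    *,
    config: PopulationConfig | None = None,
    age_groups: tuple[tuple[int, int], ...] = ((40, 49), (50, 59)),
    screening_years: int = 5,
) -> pd.DataFrame:
    """Simulated annual-screening trial in the style of the Canadian
    National Breast Screening Study.

    For each age group the treatment arm is screened annually for
    ``screening_years`` years from the group's entry age; the control arm
    is never screened.  Relative risks of detected cancer are reported for
    the first screening year and for years 2-5.  Used to tune the
    detection thresholds and malignant growth rate; the reported trial
    values are shown for context.
    """
    config = config or default_config()
    ctx = CalibrationContext(params, effects, config, seed)
    reported = {(40, "year_1"): 3.1, (40, "years_2_5"): 1.25,
                (50, "year_1"): 3.6, (50, "years_2_5"): 1.25}
    rows = []
    for lo, hi in age_groups:
        co = ctx.base_cohort(n_per_arm)
        entry = lo
        horizon = entry + screening_years
        ages = tuple(range(entry, entry + screening_years))
        out_t = simulate_cohort(
            co, params, effects, mode="stochastic", seed=seed,
            horizon=horizon, use_screening=False, force_survival=True,
            forced_screening_ages=ages,
        )
        out_c = simulate_cohort(
            co, params, effects, mode="stochastic", seed=seed,
            horizon=horizon, use_screening=False, force_survival=True,
        )
        det_t = np.nan_to_num(out_t.detection_age, nan=-1.0)
        det_c = np.nan_to_num(out_c.detection_age, nan=-1.0)
        for label, wlo, whi in [("year_1", entry, entry + 1),
                                ("years_2_5", entry + 1,
                                 entry + screening_years)]:
            ce = int(np.sum((det_t >= wlo) & (det_t < whi)))
            cc = int(np.sum((det_c >= wlo) & (det_c < whi)))
            if cc == 0:
                raise CalibrationError(
                    f"no control-arm cases for ages {lo}-{hi} {label}"
                )
            rows.append({"age_group": f"{lo}-{hi}", "window": label,
                         "reported_value": reported.get((lo, label)),
                         "model_value": ce / cc,
                         "treatment_cases": ce, "control_cases": cc})
    return pd.DataFrame(rows)
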