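"""Stochastic multistage physiology engine.

Breast tissue is tracked as a dense (susceptible) pool whose volume follows
the deterministic life-course trajectory, plus six ordered pools of
transformed tissue; the sixth pool is malignant.  Each model year:

1. the dense pool is set from the dense-volume trajectory;
2. transformation fluxes are drawn from start-of-year volumes (Jacobi
   update: volume cannot transform twice in one year) — influx to class 1
   is proportional to the dense pool, flux from class k to k+1 to v[k];
3. every transformed pool then grows/decays by exp(growth - loss).

In ``stochastic`` mode each flux moves n*q volume where
n ~ Poisson(rate * source / q) and q is the clone quantum, preserving the
branching-process character of clonal expansion; ``mean_field`` mode moves
the expected flux and is used for fast calibration.  Fluxes are capped at
the source volume so pools never go negative.

Cancer is recorded when the malignant pool reaches a clinical threshold, or
a smaller screening threshold in years when the woman is screened.  In the
small-rate limit the cascade reduces to the classical multistage
(Armitage–Doll) hazard ~ (prod rates) * t^(k-1)/(k-1)!, which serves as an
analytic oracle for the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exposure_effects import (
    EffectParameters,
    ModifierSet,
    modifiers_for,
    N_CLASSES,
    N_STEPS,
)
from .life_course import Individual, dense_volume, pike_growth_multiplier

__all__ = [
    "RateParameters",
    "TissueState",
    "LifeOutcome",
    "EffectiveRates",
    "default_loss_fraction",
    "effective_rates",
    "annual_update",
    "detect",
    "simulate_individual",
    "armitage_doll_hazard",
    "SCREENING_START_AGE",
]

SCREENING_START_AGE = 40


def default_loss_fraction() -> np.ndarray:
    """Per-class loss multipliers: linear 1.0 -> 0.48 over classes 1..5,
    and 0.25 for the malignant class."""
    frac = np.empty(N_CLASSES)
    frac[:5] = np.linspace(1.0, 0.48, 5)
    frac[5] = 0.25
    return frac


@dataclass
class RateParameters:
    """Baseline physiology rates, thresholds and structural constants.

    All rates are per year and act on abstract volume units.  ``tau`` is
    the common rate of the first five transformation steps; ``tau_final``
    the rate of the last (pre-malignant -> malignant) step, tuned
    separately so the age-incidence log-slope lands between the pure five-
    and six-step values.  ``growth_rate_attenuation`` scales growth
    geometrically across classes 1..5 (1 = equal rates).  Loss rates
    decline linearly across classes; all of them are multiplied by
    ``bf_loss_factor`` in breastfeeding years and by ``late_loss_factor``
    from ``late_loss_onset_age`` onward (the old-age incidence downturn).
    ``quantum`` is the clone volume unit of one stochastic transformation
    event.
    """

    tau: float = 5.1e-3
    tau_final: float = 0.3
    g0: float = 0.08
    growth_rate_attenuation: float = 1.0
    g_malignant: float = 1.2
    lambda0: float = 0.045
    loss_fraction: np.ndarray = field(default_factory=default_loss_fraction)
    bf_loss_factor: float = 100.0
    late_loss_onset_age: int = 74
    late_loss_factor: float = 3.0
    theta_clinical: float = 1.0
    theta_screen: float = 0.25
    quantum: float = 1e-4
    baseline_volume: float = 1.0

    def __post_init__(self) -> None:
        self.loss_fraction = np.asarray(self.loss_fraction, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("tau", "tau_final", "g0", "g_malignant", "lambda0",
                     "bf_loss_factor", "late_loss_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.theta_screen < self.theta_clinical:
            raise ValueError("theta_screen must be < theta_clinical")
        if self.quantum <= 0:
            raise ValueError("quantum must be > 0")
        if self.baseline_volume <= 0:
            raise ValueError("baseline_volume must be > 0")
        if len(self.loss_fraction) != N_CLASSES:
            raise ValueError("loss_fraction needs one entry per class")
        if np.any(np.diff(self.loss_fraction) > 1e-12):
            raise ValueError("loss_fraction must be non-increasing")


@dataclass
class TissueState:
    """Dense-pool volume plus the six transformed-tissue pools."""

    dense: float = 0.0
    classes: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    detected: bool = False
    detection_age: int | None = None

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=float)
        if self.classes.shape != (N_CLASSES,):
            raise ValueError(f"classes must have shape ({N_CLASSES},)")
        if self.dense < 0 or np.any(self.classes < 0):
            raise ValueError("volumes must be >= 0")

    @property
    def malignant(self) -> float:
        return float(self.classes[5])


@dataclass
class LifeOutcome:
    """What population bookkeeping needs from one simulated life."""

    cancer_detected: bool
    detection_age: int | None
    detected_by_screening: bool
    death_age: int

    def __post_init__(self) -> None:
        if self.detection_age is not None and self.detection_age > self.death_age:
            raise ValueError("detection_age must be <= death_age")


@dataclass
class EffectiveRates:
    """Per-class (growth, loss) and per-step transformation rates for one
    model year, after all life-stage and exposure modifiers."""

    growth: np.ndarray  # shape (6,)
    loss: np.ndarray  # shape (6,)
    transform: np.ndarray  # shape (6,): steps healthy->1 ... 5->6


def effective_rates(
    params: RateParameters,
    modifiers: ModifierSet,
    age: int,
    individual: Individual,
) -> EffectiveRates:
    """Rates for one model year of one woman.

    growth_k = g0 * attenuation^(k-1) * Pike(age) * growth modifier for
    classes 1..5; the malignant class grows at ``g_malignant`` times its
    modifier (hormonal life stage no longer limits an established tumor).
    Loss combines the linear class profile, the breastfeeding elevation,
    the late-age elevation and the exposure loss modifiers.  Transformation
    is ``tau`` for the first five steps and ``tau_final`` for the last,
    times the per-step modifiers.
    """
    if np.any(modifiers.growth_mult < 0) or np.any(
        modifiers.loss_mult < 0
    ) or np.any(modifiers.transform_mult < 0):
        raise ValueError("modifiers must be >= 0")

    pike = pike_growth_multiplier(age, individual)
    k = np.arange(5)
    growth = np.empty(N_CLASSES)
    growth[:5] = params.g0 * params.growth_rate_attenuation**k * pike
    growth[5] = params.g_malignant
    growth = growth * modifiers.growth_mult

    loss = params.lambda0 * params.loss_fraction * modifiers.loss_mult
    if individual.breastfeeding_at(age):
        loss = loss * params.bf_loss_factor
    if age >= params.late_loss_onset_age:
        loss = loss * params.late_loss_factor

    transform = np.full(N_STEPS, params.tau)
    transform[5] = params.tau_final
    transform = transform * modifiers.transform_mult

    return EffectiveRates(growth=growth, loss=loss, transform=transform)


def annual_update(
    state: TissueState,
    rates: EffectiveRates,
    mode: str = "stochastic",
    rng: np.random.Generator | None = None,
    quantum: float = 1e-5,
) -> TissueState:
    """Advance the tissue pools by one year.

    Transformation fluxes are drawn from start-of-year volumes, so mass
    leaving class k arrives in class k+1 within the same step (conserved
    before growth/loss scaling) and no volume transforms twice in a year.
    """
    if not np.isfinite(state.dense) or not np.all(np.isfinite(state.classes)):
        raise FloatingPointError("non-finite tissue volumes")
    if mode not in ("stochastic", "mean_field"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")

    v = state.classes
    sources = np.concatenate(([state.dense], v[:5]))  # step k source volume
    expected = rates.transform * sources
    if mode == "mean_field":
        flux = np.minimum(expected, sources)
    else:
        n = rng.poisson(expected / quantum)
        flux = np.minimum(n * quantum, sources)

    new_v = v.copy()
    new_v += flux  # arrival into classes 1..6
    new_v[:5] -= flux[1:]  # departure from classes 1..5
    # dense pool is trajectory-driven, not depleted by transformation
    new_v = np.maximum(new_v, 0.0)
    new_v *= np.exp(rates.growth - rates.loss)
    if not np.all(np.isfinite(new_v)):
        raise FloatingPointError("non-finite tissue volumes after update")
    return TissueState(
        dense=state.dense,
        classes=new_v,
        detected=state.detected,
        detection_age=state.detection_age,
    )


def detect(
    state: TissueState, screened_this_year: bool, params: RateParameters
) -> bool:
    """True iff the malignant pool crosses the clinical threshold, or the
    screening threshold in a screened year."""
    if state.malignant >= params.theta_clinical:
        return True
    return screened_this_year and state.malignant >= params.theta_screen


def simulate_individual(
    individual: Individual,
    params: RateParameters,
    effects: EffectParameters,
    rng: np.random.Generator,
    mode: str = "stochastic",
    seed_schedule: dict[int, tuple[int, float]] | None = None,
) -> LifeOutcome:
    """Simulate one life course year by year; stop at detection or death.

    ``seed_schedule`` optionally injects transformed volume at given ages
    (``{age: (class_index, volume)}``), used for damage-exposure scenarios
    and the BRCA1 birth-seeding mechanism.  Deterministic given
    (individual, params, effects, rng state, mode).
    """
    state = TissueState()
    schedule = dict(seed_schedule or {})

    mods0 = modifiers_for(individual, 0, effects)
    if mods0.seed_at_birth is not None:
        cls, vol = mods0.seed_at_birth
        prev = schedule.get(0, (cls, 0.0))
        if prev[0] != cls:
            raise ValueError("conflicting birth-seed classes")
        schedule[0] = (cls, prev[1] + vol)

    for age in range(individual.death_age + 1):
        if age in schedule:
            cls, vol = schedule[age]
            classes = state.classes.copy()
            classes[cls - 1] += vol
            state = replace(state, classes=classes)
        state = replace(
            state,
            dense=dense_volume(age, individual, params.baseline_volume),
        )
        mods = modifiers_for(individual, age, effects)
        rates = effective_rates(params, mods, age, individual)
        state = annual_update(
            state, rates, mode=mode, rng=rng, quantum=params.quantum
        )
        screened = False
        if age >= SCREENING_START_AGE and individual.screening_frequency > 0:
            screened = rng.random() < individual.screening_frequency / 7.0
        if detect(state, screened, params):
            return LifeOutcome(
                cancer_detected=True,
                detection_age=age,
                detected_by_screening=(
                    screened and state.malignant < params.theta_clinical
                ),
                death_age=individual.death_age,
            )
    return LifeOutcome(
        cancer_detected=False,
        detection_age=None,
        detected_by_screening=False,
        death_age=individual.death_age,
    )


def armitage_doll_hazard(t: float, rates: "np.ndarray | list[float]") -> float:
    """Classical multistage hazard approximation for small rates:
    h(t) = (prod rates) * t^(k-1) / (k-1)!.

    Valid when every rate * t << 1; its log-log slope in t is k-1, the
    analytic limit the simulation engine must reproduce with growth and
    loss switched off.
    """
    rates = np.asarray(rates, dtype=float)
    k = len(rates)
    if t < 0:
        raise ValueError("t must be >= 0")
    if k == 0:
        raise ValueError("need at least one step rate")
    return float(np.prod(rates) * t ** (k - 1) / math.factorial(k - 1))
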