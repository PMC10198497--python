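"""Chemical-exposure scenario experiments.

Each scenario contrasts two arms of an idealized, perfectly uniform cohort
(identical life histories, shared random streams): a control arm and an
exposed arm in which one mechanistic insult is applied —

1. prenatal exposure seeding damaged tissue at birth;
2. prenatal exposure that reprograms rates for life (transformation boost);
3. a single-year boost of first-class damage accumulation at age 20;
4. a sustained accumulation boost from ages 20-29 at half the single-year
   magnitude per year;
5. scenarios 3/4 applied to the fifth (pre-malignant) class;
6. a lifelong estrogen-like increase in damaged-tissue growth rates.

A removal-reduction variant (lifelong decrease of cell-loss rates) is also
expressible.  Magnitudes are deliberately uncalibrated configuration
inputs: the interesting output is the timing of excess incidence, not its
absolute size, except that equal total seeded volumes may be compared.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .calibration_trials import replace_params
from .cohort import cohort_from_individuals, simulate_cohort
from .epi_stats import IncidenceCurve, age_specific_incidence
from .exposure_effects import EffectParameters
from .life_course import Individual
from .tissue_dynamics import RateParameters

__all__ = [
    "Mechanism",
    "Timing",
    "ScenarioSpec",
    "scenario_spec",
    "idealized_individual",
    "run_scenario",
    "ScenarioResult",
]


class Mechanism(str, enum.Enum):
    SEED_DAMAGE = "seed_damage"
    TRANSFORM_BOOST = "transform_boost"
    GROWTH_BOOST = "growth_boost"
    REMOVAL_REDUCTION = "removal_reduction"


class Timing(str, enum.Enum):
    PRENATAL = "prenatal"
    AGE20_SINGLE_YEAR = "age20_single_year"
    AGES20_29 = "ages20_29"
    LIFELONG = "lifelong"


# ratio of yearly magnitude for the 10-year insult to the 1-year insult
SUSTAINED_YEARLY_FRACTION = 0.5


@dataclass
class ScenarioSpec:
    """One chemical-exposure experiment.

    ``magnitude`` is a seeded volume (seed_damage) or a rate multiplier
    (other mechanisms).  ``damage_class`` (1 or 5) applies to seeding
    only."""

    id: int
    mechanism: Mechanism
    magnitude: float
    damage_class: int | None = None
    timing: Timing = Timing.LIFELONG
    lifelong: bool = True

    def validate(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.mechanism is Mechanism.SEED_DAMAGE:
            if self.damage_class not in (1, 5):
                raise ValueError("seed_damage requires damage_class 1 or 5")
            if self.timing is Timing.LIFELONG:
                raise ValueError("seed_damage requires a seeding time")
        else:
            if self.damage_class is not None:
                raise ValueError(
                    f"damage_class is only meaningful for seed_damage, "
                    f"not {self.mechanism.value}"
                )


def scenario_spec(scenario_id: int, magnitude: float) -> ScenarioSpec:
    """The six canonical scenarios by id (see module docstring)."""
    canon = {
        1: dict(mechanism=Mechanism.SEED_DAMAGE, damage_class=1,
                timing=Timing.PRENATAL),
        2: dict(mechanism=Mechanism.TRANSFORM_BOOST, timing=Timing.LIFELONG),
        3: dict(mechanism=Mechanism.SEED_DAMAGE, damage_class=1,
                timing=Timing.AGE20_SINGLE_YEAR),
        4: dict(mechanism=Mechanism.SEED_DAMAGE, damage_class=1,
                timing=Timing.AGES20_29),
        5: dict(mechanism=Mechanism.SEED_DAMAGE, damage_class=5,
                timing=Timing.AGE20_SINGLE_YEAR),
        6: dict(mechanism=Mechanism.GROWTH_BOOST, timing=Timing.LIFELONG),
    }
    if scenario_id not in canon:
        raise ValueError(
            f"unknown scenario id {scenario_id}; valid ids are 1..6"
        )
    spec = ScenarioSpec(id=scenario_id, magnitude=magnitude, **canon[scenario_id])
    spec.validate()
    return spec


def idealized_individual(death_age: int = 90) -> Individual:
    """The uniform scenario fixture: menarche 12, menopause 45,
    nulliparous, no BRCA1, polygenic score 0.69, non-smoker, normal BMI,
    no OC/HT/breastfeeding."""
    return Individual(
        menarche_age=12,
        menopause_age=45,
        birth_ages=(),
        breastfeeds=False,
        smoker=False,
        drinks_per_year=0.0,
        bmi_category="normal",
        brca1=False,
        prs=0.69,
        screening_frequency=0,
        death_age=death_age,
    )


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    exposed: IncidenceCurve
    control: IncidenceCurve
    peak_excess_age: float
    cumulative_excess: float
    relative_risk: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, curve in (("exposed", self.exposed),
                           ("control", self.control)):
            for s, e, r in zip(curve.bin_start, curve.bin_end,
                               curve.rate_per_100k):
                rows.append({"scenario_id": self.spec.id, "arm": arm,
                             "age": (s + e) / 2, "rate_per_100k": r})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "scenario_id": self.spec.id,
            "mechanism": self.spec.mechanism.value,
            "timing": self.spec.timing.value,
            "magnitude": self.spec.magnitude,
            "peak_excess_age": self.peak_excess_age,
            "cumulative_excess": self.cumulative_excess,
            "relative_risk": self.relative_risk,
        }


def _exposed_configuration(
    spec: ScenarioSpec,
    params: RateParameters,
    effects: EffectParameters,
):
    """(params, effects, seed_schedule) for the exposed arm."""
    schedule: dict[int, tuple[int, float]] = {}
    if spec.mechanism is Mechanism.SEED_DAMAGE:
        if spec.timing is Timing.PRENATAL:
            schedule[0] = (spec.damage_class, spec.magnitude)
        elif spec.timing is Timing.AGE20_SINGLE_YEAR:
            schedule[20] = (spec.damage_class, spec.magnitude)
        elif spec.timing is Timing.AGES20_29:
            yearly = spec.magnitude * SUSTAINED_YEARLY_FRACTION
            for age in range(20, 30):
                schedule[age] = (spec.damage_class, yearly)
        return params, effects, schedule
    if spec.mechanism is Mechanism.TRANSFORM_BOOST:
        p = replace_params(params, "tau", params.tau * spec.magnitude)
        p = replace_params(p, "tau_final", params.tau_final * spec.magnitude)
        return p, effects, schedule
    if spec.mechanism is Mechanism.GROWTH_BOOST:
        p = replace_params(params, "g0", params.g0 * spec.magnitude)
        return p, effects, schedule
    if spec.mechanism is Mechanism.REMOVAL_REDUCTION:
        p = replace_params(params, "lambda0", params.lambda0 / spec.magnitude)
        return p, effects, schedule
    raise ValueError(f"unknown mechanism {spec.mechanism!r}")


def run_scenario(
    spec: ScenarioSpec,
    params: RateParameters,
    effects: EffectParameters,
    n_per_arm: int = 50_000,
    seed: int = 0,
    horizon: int = 90,
) -> ScenarioResult:
    """Run one paired scenario experiment on the idealized cohort.

    Both arms share women and random streams; only the exposed arm applies
    the mechanism.  Returns paired incidence curves and a summary: the age
    bin of the largest excess rate, the cumulative excess incidence to the
    horizon and the exposed/control cumulative-incidence ratio.
    """
    spec.validate()
    fixture = idealized_individual(death_age=horizon)
    co = cohort_from_individuals([fixture] * n_per_arm)

    p_e, e_e, schedule = _exposed_configuration(spec, params, effects)
    common = dict(mode="stochastic", seed=seed, horizon=horizon,
                  use_screening=False, force_survival=True)
    out_c = simulate_cohort(co, params, effects, **common)
    out_e = simulate_cohort(co, p_e, e_e, seed_schedule=schedule or None,
                            **common)

    bins = np.arange(0, horizon + 5, 5)
    curve_c = age_specific_incidence(out_c, bins=bins)
    curve_e = age_specific_incidence(out_e, bins=bins)

    excess = curve_e.rate - curve_c.rate
    peak_age = float(curve_e.midpoints[int(np.argmax(excess))])
    ci_e = float(np.mean(out_e.detection_age <= horizon))
    ci_c = float(np.mean(out_c.detection_age <= horizon))
    rr = ci_e / ci_c if ci_c > 0 else np.inf
    return ScenarioResult(
        spec=spec,
        exposed=curve_e,
        control=curve_c,
        peak_excess_age=peak_age,
        cumulative_excess=ci_e - ci_c,
        relative_risk=rr,
    )
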