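"""Exposure effects: multiplicative rate modifiers per tissue class.

Each exposure acts on one of three rate channels — tissue growth, cell
loss, or transformation — as a per-class multiplicative modifier, composed
elementwise.  The channels follow the etiologic pathway each exposure is
believed to act through:

* smoking and alcohol accelerate transformation (genotoxic);
* BMI (post-menopause only), oral contraceptives and hormone therapy raise
  growth rates (hormonal);
* breastfeeding raises cell-loss rates in the year after each birth
  (handled by the physiology engine's loss channel, see
  :mod:`mammosim.tissue_dynamics`);
* BRCA1 acts through one of four alternative mechanisms (damage at birth,
  faster accumulation, reduced removal, faster growth), selectable for
  comparison; the default is faster accumulation (raised transformation
  rates);
* a normally distributed polygenic risk score (PRS) acts through the same
  channel as the chosen BRCA1 mechanism, as exp(scale * score).

Modifiers form a commutative monoid under elementwise multiplication with
identity "all ones"; birth-seeding volumes add under composition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .life_course import Individual

__all__ = [
    "BrcaVariant",
    "ModifierSet",
    "EffectParameters",
    "modifiers_for",
    "brca1_effect",
    "prs_multiplier",
    "bmi_growth_multiplier",
    "BMI_MIDPOINTS",
    "BMI_REFERENCE",
    "SMOKING_START_AGE",
]

N_CLASSES = 6
N_STEPS = 6  # healthy->1, 1->2, ..., 5->6

SMOKING_START_AGE = 15

# WHO category midpoints used to translate the per-5-unit risk gradient
# into category-level growth multipliers.
BMI_MIDPOINTS = {
    "underweight": 17.0,
    "normal": 21.75,
    "overweight": 27.5,
    "obese": 33.0,
}
BMI_REFERENCE = BMI_MIDPOINTS["normal"]


class BrcaVariant(str, enum.Enum):
    SEED_EARLY = "seed_early"
    FASTER_ACCUMULATION = "faster_accumulation"
    REDUCED_REMOVAL = "reduced_removal"
    FASTER_GROWTH = "faster_growth"


@dataclass
class ModifierSet:
    """Per-class multiplicative modifiers on growth, loss and transformation.

    ``growth_mult`` and ``loss_mult`` have one entry per tissue class
    (1..6); ``transform_mult`` one per transformation step (healthy->1
    through 5->6).  ``seed_at_birth`` optionally places transformed volume
    at birth as ``(class_index, volume)`` with class_index in 1..6.
    """

    growth_mult: np.ndarray = field(
        default_factory=lambda: np.ones(N_CLASSES)
    )
    loss_mult: np.ndarray = field(default_factory=lambda: np.ones(N_CLASSES))
    transform_mult: np.ndarray = field(
        default_factory=lambda: np.ones(N_STEPS)
    )
    seed_at_birth: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        self.growth_mult = np.asarray(self.growth_mult, dtype=float)
        self.loss_mult = np.asarray(self.loss_mult, dtype=float)
        self.transform_mult = np.asarray(self.transform_mult, dtype=float)
        for arr in (self.growth_mult, self.loss_mult, self.transform_mult):
            if np.any(arr < 0):
                raise ValueError("modifier multipliers must be >= 0")

    @classmethod
    def identity(cls) -> "ModifierSet":
        return cls()

    def compose(self, other: "ModifierSet") -> "ModifierSet":
        """Elementwise product; seeding volumes add (same class required)."""
        seed = self.seed_at_birth
        if other.seed_at_birth is not None:
            if seed is None:
                seed = other.seed_at_birth
            elif seed[0] == other.seed_at_birth[0]:
                seed = (seed[0], seed[1] + other.seed_at_birth[1])
            else:
                raise ValueError(
                    "cannot compose birth seeds in different classes"
                )
        return ModifierSet(
            growth_mult=self.growth_mult * other.growth_mult,
            loss_mult=self.loss_mult * other.loss_mult,
            transform_mult=self.transform_mult * other.transform_mult,
            seed_at_birth=seed,
        )

    def is_identity(self) -> bool:
        return (
            np.all(self.growth_mult == 1.0)
            and np.all(self.loss_mult == 1.0)
            and np.all(self.transform_mult == 1.0)
            and self.seed_at_birth is None
        )


@dataclass
class EffectParameters:
    """Calibrated effect sizes for the exposure submodels.

    Multiplier-type fields default to literature-initialized values and are
    refined by :func:`mammosim.calibration_trials.calibrate_exposure`.
    """

    sigma_smoke: float = 1.05  # transformation multiplier, smokers
    beta_alcohol: float = 0.002  # per (gram/day) transformation increment
    grams_per_drink: float = 14.0
    bmi_per5_growth: float = 1.02  # growth multiplier per +5 BMI units
    m_oc: float = 1.05  # growth multiplier during OC use
    m_ht: float = 1.05  # growth multiplier during HT use
    brca_variant: BrcaVariant = BrcaVariant.FASTER_ACCUMULATION
    brca_mult: float = 2.0  # effect size of chosen BRCA1 mechanism
    brca_seed_class: int = 1
    brca_seed_volume: float = 1e-4
    prs_scale: float = 0.08  # log-multiplier per PRS standard deviation
    alcohol_on_growth: bool = False  # alternative pathway switch

    def validate(self) -> None:
        for name in ("sigma_smoke", "bmi_per5_growth", "m_oc", "m_ht",
                     "brca_mult", "grams_per_drink"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def bmi_growth_mult(self, category: str) -> float:
        return bmi_growth_multiplier(category, self.bmi_per5_growth)


def bmi_growth_multiplier(category: str, per5: float) -> float:
    """Growth multiplier for a BMI category.

    The per-5-unit multiplier is raised to the category midpoint's distance
    from the normal-weight midpoint (21.75), in 5-unit steps, so one
    calibrated number generates all four category multipliers.
    """
    try:
        mid = BMI_MIDPOINTS[category]
    except KeyError:
        raise ValueError(f"unknown BMI category {category!r}") from None
    return per5 ** ((mid - BMI_REFERENCE) / 5.0)


def _channel_modifier(
    variant: BrcaVariant, mult: float,
    seed_class: int, seed_volume: float,
) -> ModifierSet:
    if variant is BrcaVariant.SEED_EARLY:
        return ModifierSet(seed_at_birth=(seed_class, seed_volume * mult))
    if variant is BrcaVariant.FASTER_ACCUMULATION:
        return ModifierSet(transform_mult=np.full(N_STEPS, mult))
    if variant is BrcaVariant.REDUCED_REMOVAL:
        return ModifierSet(loss_mult=np.full(N_CLASSES, 1.0 / mult))
    if variant is BrcaVariant.FASTER_GROWTH:
        gm = np.ones(N_CLASSES)
        gm[:5] = mult  # malignant growth is governed separately
        return ModifierSet(growth_mult=gm)
    raise ValueError(f"unknown BRCA1 variant {variant!r}")


def brca1_effect(
    variant: BrcaVariant | str,
    brca_mult: float,
    carrier: bool,
    *,
    seed_class: int = 1,
    seed_volume: float = 1e-4,
) -> ModifierSet:
    """ModifierSet for BRCA1 carrier status under one of four mechanisms.

    Mechanisms: damaged cells present at birth; increased accumulation of
    damage (transformation; the default); reduced removal of damaged tissue
    (loss divided by the multiplier); increased growth of damaged tissue.
    Non-carriers get the identity.
    """
    if brca_mult <= 0:
        raise ValueError("brca_mult must be > 0")
    variant = BrcaVariant(variant)
    if not carrier:
        return ModifierSet.identity()
    return _channel_modifier(variant, brca_mult, seed_class, seed_volume)


def prs_multiplier(
    prs: float,
    prs_scale: float,
    variant: BrcaVariant | str = BrcaVariant.FASTER_ACCUMULATION,
) -> ModifierSet:
    """Polygenic-score modifier: exp(prs_scale * prs) on the same channel
    as the chosen BRCA1 mechanism.  Identity at score 0 or scale 0."""
    variant = BrcaVariant(variant)
    if variant is BrcaVariant.SEED_EARLY:
        # a continuous score cannot seed discrete damage; fall back to the
        # accumulation channel, the model's default mechanism
        variant = BrcaVariant.FASTER_ACCUMULATION
    mult = float(np.exp(prs_scale * prs))
    return _channel_modifier(variant, mult, 1, 0.0)


def modifiers_for(
    individual: Individual, age: int, effects: EffectParameters
) -> ModifierSet:
    """Compose all of an individual's exposure modifiers at ``age``.

    Breastfeeding's loss elevation is applied by the physiology engine
    (it is a physiological constant of lactation, kept with the rate
    parameters), so it does not appear here.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    mods = ModifierSet.identity()

    transform = np.ones(N_STEPS)
    if individual.smoker and age >= SMOKING_START_AGE:
        transform *= effects.sigma_smoke
    grams_day = individual.grams_alcohol_per_day(effects.grams_per_drink)
    alcohol_mult = 1.0 + effects.beta_alcohol * grams_day
    if grams_day > 0 and age >= SMOKING_START_AGE:
        if not effects.alcohol_on_growth:
            transform *= alcohol_mult
    mods = mods.compose(ModifierSet(transform_mult=transform))

    growth = np.ones(N_CLASSES)
    if age >= individual.menopause_age:
        growth *= effects.bmi_growth_mult(individual.bmi_category)
        if individual.ht_duration > 0 and (
            age < individual.menopause_age + individual.ht_duration
        ):
            growth *= effects.m_ht
    if (
        individual.oc_start_age is not None
        and individual.oc_start_age <= age < individual.oc_stop_age
    ):
        growth *= effects.m_oc
    if effects.alcohol_on_growth and grams_day > 0 and age >= SMOKING_START_AGE:
        growth *= alcohol_mult
    mods = mods.compose(ModifierSet(growth_mult=growth))

    mods = mods.compose(
        brca1_effect(
            effects.brca_variant,
            effects.brca_mult,
            individual.brca1,
            seed_class=effects.brca_seed_class,
            seed_volume=effects.brca_seed_volume,
        )
    )
    mods = mods.compose(
        prs_multiplier(individual.prs, effects.prs_scale, effects.brca_variant)
    )
    return mods
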