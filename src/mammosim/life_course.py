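"""Fixed life-history structure of a simulated woman.

Each agent carries a deterministic set of reproductive milestones and
exposure attributes fixed at sampling time.  Two deterministic functions of
age are derived from them and consumed by the physiology engine:

* the Pike growth-rate multiplier, a piecewise-constant scaling of
  breast-tissue growth over hormonal life stages (0 before menarche, 1 while
  nulliparous and premenopausal, 2.2 in the year of the first full-term
  birth, 0.70 from then until menopause, 0.105 after menopause);
* the dense-tissue volume trajectory (0 before menarche, a constant baseline
  until menopause, a 5% point drop at menopause, then a 1% decline per
  completed post-menopausal year).

Ages live on an integer annual grid: all life events happen at integer ages
and each model step advances one year.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Individual",
    "LifeStage",
    "life_stage",
    "pike_growth_multiplier",
    "dense_volume",
    "PIKE_PRE_MENARCHE",
    "PIKE_NULLIPAROUS",
    "PIKE_FIRST_BIRTH",
    "PIKE_PAROUS",
    "PIKE_POST_MENOPAUSE",
    "MENOPAUSE_VOLUME_DROP",
    "POST_MENOPAUSE_ANNUAL_DECLINE",
]

# Pike et al. life-stage growth multipliers.
PIKE_PRE_MENARCHE = 0.0
PIKE_NULLIPAROUS = 1.0
PIKE_FIRST_BIRTH = 2.2
PIKE_PAROUS = 0.70
PIKE_POST_MENOPAUSE = 0.105

# Dense-volume trajectory constants.
MENOPAUSE_VOLUME_DROP = 0.05  # point drop at menopause
POST_MENOPAUSE_ANNUAL_DECLINE = 0.01  # per completed year after menopause


class LifeStage(enum.Enum):
    """Partition of the life course; exactly one stage per (woman, age)."""

    PRE_MENARCHE = "pre_menarche"
    NULLIPAROUS_PREMENOPAUSE = "nulliparous_premenopause"
    FIRST_BIRTH_YEAR = "first_birth_year"
    PAROUS_PREMENOPAUSE = "parous_premenopause"
    POST_MENOPAUSE = "post_menopause"


@dataclass
class Individual:
    """A simulated woman's fixed life-course attributes and exposures.

    All ages are integer years.  ``birth_ages`` is strictly increasing and
    bounded between menarche and menopause; ``oc_start_age``/``oc_stop_age``
    are present only for ever-users, as is a positive ``ht_duration`` (HT use
    always begins at menopause).  ``screening_frequency`` counts mammograms
    per seven years (0..7).
    """

    id: int = 0
    birth_year: int = 1960
    race_ethnicity: str = "white"
    rural: bool = False
    menarche_age: int = 13
    birth_ages: tuple[int, ...] = ()
    breastfeeds: bool = False
    menopause_age: int = 50
    smoker: bool = False
    drinks_per_year: float = 0.0
    bmi_category: str = "normal"
    oc_start_age: int | None = None
    oc_stop_age: int | None = None
    ht_duration: int = 0
    brca1: bool = False
    prs: float = 0.0
    screening_frequency: int = 0
    death_age: int = 85
    education: str = "unspecified"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.menarche_age >= self.menopause_age:
            raise ValueError(
                f"menarche_age {self.menarche_age} must precede "
                f"menopause_age {self.menopause_age}"
            )
        if self.death_age <= 0:
            raise ValueError("death_age must be positive")
        if self.birth_ages:
            ba = tuple(self.birth_ages)
            if any(b2 <= b1 for b1, b2 in zip(ba, ba[1:])):
                raise ValueError("birth_ages must be strictly increasing")
            if ba[0] <= self.menarche_age:
                raise ValueError("first birth must come after menarche")
        if (self.oc_start_age is None) != (self.oc_stop_age is None):
            raise ValueError("oc_start_age and oc_stop_age must come together")
        if self.oc_start_age is not None:
            if self.oc_start_age < self.menarche_age:
                raise ValueError("OC start must be at or after menarche")
            if self.oc_stop_age > self.menopause_age:
                raise ValueError("OC stop must be at or before menopause")
            if self.oc_stop_age < self.oc_start_age:
                raise ValueError("OC stop before start")
        if self.ht_duration < 0:
            raise ValueError("ht_duration must be >= 0")
        if not 0 <= self.screening_frequency <= 7:
            raise ValueError("screening_frequency must be in 0..7")
        if self.drinks_per_year < 0:
            raise ValueError("drinks_per_year must be >= 0")

    @property
    def parous(self) -> bool:
        return len(self.birth_ages) > 0

    @property
    def first_birth_age(self) -> int | None:
        return self.birth_ages[0] if self.birth_ages else None

    def breastfeeding_at(self, age: int) -> bool:
        """True in the single model year following each birth, if she
        breastfeeds at all."""
        if not self.breastfeeds:
            return False
        return any(age == b + 1 for b in self.birth_ages)

    def grams_alcohol_per_day(self, grams_per_drink: float = 14.0) -> float:
        return self.drinks_per_year * grams_per_drink / 365.0


def life_stage(age: int, individual: Individual) -> LifeStage:
    """Unique hormonal life stage of ``individual`` at ``age``."""
    if age < individual.menarche_age:
        return LifeStage.PRE_MENARCHE
    if age >= individual.menopause_age:
        return LifeStage.POST_MENOPAUSE
    fb = individual.first_birth_age
    if fb is None or age < fb:
        return LifeStage.NULLIPAROUS_PREMENOPAUSE
    if age == fb:
        return LifeStage.FIRST_BIRTH_YEAR
    return LifeStage.PAROUS_PREMENOPAUSE


_STAGE_MULTIPLIER = {
    LifeStage.PRE_MENARCHE: PIKE_PRE_MENARCHE,
    LifeStage.NULLIPAROUS_PREMENOPAUSE: PIKE_NULLIPAROUS,
    LifeStage.FIRST_BIRTH_YEAR: PIKE_FIRST_BIRTH,
    LifeStage.PAROUS_PREMENOPAUSE: PIKE_PAROUS,
    LifeStage.POST_MENOPAUSE: PIKE_POST_MENOPAUSE,
}


def pike_growth_multiplier(age: int, individual: Individual) -> float:
    """Pike life-stage multiplier on breast-tissue growth rates at ``age``.

    Total function of (age, menarche, first birth, menopause); its image is
    exactly {0, 1, 2.2, 0.70, 0.105}.  Births after the first do not change
    the multiplier.
    """
    return _STAGE_MULTIPLIER[life_stage(age, individual)]


def dense_volume(
    age: int, individual: Individual, baseline_volume: float = 1.0
) -> float:
    """Dense (susceptible) breast-tissue volume at ``age``, abstract units.

    Zero before menarche; the constant baseline from menarche to the year
    before menopause; 0.95 x baseline at menopause (a point-in-time drop);
    thereafter multiplied by 0.99 for each completed post-menopausal year.
    """
    if baseline_volume <= 0:
        raise ValueError("baseline_volume must be positive")
    if age < individual.menarche_age:
        return 0.0
    if age < individual.menopause_age:
        return baseline_volume
    k = age - individual.menopause_age
    return (
        baseline_volume
        * (1.0 - MENOPAUSE_VOLUME_DROP)
        * (1.0 - POST_MENOPAUSE_ANNUAL_DECLINE) ** k
    )


# ---------------------------------------------------------------------------
# Vectorized forms used by the cohort engine.  Same contracts as above, on
# arrays of individuals at a common age.
# ---------------------------------------------------------------------------

def pike_multiplier_array(
    age: int,
    menarche: np.ndarray,
    first_birth: np.ndarray,
    menopause: np.ndarray,
) -> np.ndarray:
    """Pike multiplier for many women at one age.

    ``first_birth`` uses -1 for nulliparous women.
    """
    out = np.full(menarche.shape, PIKE_NULLIPAROUS)
    out[age < menarche] = PIKE_PRE_MENARCHE
    parous_mask = first_birth >= 0
    out[parous_mask & (age == first_birth)] = PIKE_FIRST_BIRTH
    out[parous_mask & (age > first_birth) & (age < menopause)] = PIKE_PAROUS
    out[age >= menopause] = PIKE_POST_MENOPAUSE
    # pre-menarche beats everything (cannot be parous pre-menarche anyway)
    out[age < menarche] = PIKE_PRE_MENARCHE
    return out


def dense_volume_array(
    age: int,
    menarche: np.ndarray,
    menopause: np.ndarray,
    baseline_volume: float,
) -> np.ndarray:
    """Dense-volume trajectory for many women at one age."""
    out = np.full(menarche.shape, baseline_volume)
    out[age < menarche] = 0.0
    post = age >= menopause
    k = np.where(post, age - menopause, 0)
    out[post] = (
        baseline_volume
        * (1.0 - MENOPAUSE_VOLUME_DROP)
        * (1.0 - POST_MENOPAUSE_ANNUAL_DECLINE) ** k[post]
    )
    return out
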