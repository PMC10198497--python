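"""Vectorized cohort engine.

Runs the annual physiology update of :mod:`mammosim.tissue_dynamics` for a
whole cohort at once, holding tissue pools in an ``(n, 6)`` array and
advancing all women one calendar year per step.  The per-individual scalar
path (:func:`mammosim.tissue_dynamics.simulate_individual`) and this engine
implement the same update; the scalar path is the readable reference, this
one is what calibration, trials and population runs actually call.

Randomness is drawn per model year from a counter-based (Philox) generator
keyed by ``(master_seed, age)``, with individual *i* always consuming the
*i*-th draw of the year.  Growing the cohort therefore extends the
population without reshuffling the histories of women already in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.special import ndtri

from .exposure_effects import BrcaVariant, EffectParameters, N_CLASSES
from .life_course import (
    Individual,
    dense_volume_array,
    pike_multiplier_array,
)
from .tissue_dynamics import RateParameters, SCREENING_START_AGE

__all__ = ["CohortArrays", "CohortOutcomes", "cohort_from_individuals",
           "simulate_cohort", "poisson_inverse_cdf"]


def poisson_inverse_cdf(u: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Poisson quantile function, elementwise: smallest k with CDF(k) >= u.

    Used to drive transformation-event draws from common uniform streams,
    so paired counterfactual arms share randomness exactly and the drawn
    counts respond monotonically to rate changes (common random numbers).
    Exact summation below ``lam`` = 30; a continuity-corrected normal
    quantile above, where the approximation error is well under one count
    in a hundred.
    """
    u = np.asarray(u, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = np.zeros(lam.shape, dtype=np.int64)

    big = lam >= 30.0
    if big.any():
        lb = lam[big]
        out[big] = np.maximum(
            np.rint(lb + np.sqrt(lb) * ndtri(u[big])), 0
        ).astype(np.int64)

    small = (lam > 0) & ~big
    if small.any():
        idx = np.flatnonzero(small.ravel())
        flat = out.ravel()
        ls = lam.ravel()[idx]
        us = u.ravel()[idx]
        term = np.exp(-ls)
        cdf = term.copy()
        k = 0
        kmax = int(np.ceil(ls.max() + 12 * np.sqrt(ls.max()) + 20))
        # iterate the CDF recurrence only on still-unresolved entries
        while k < kmax:
            hit = us < cdf
            flat[idx[hit]] = k
            keep = ~hit
            if not keep.any():
                break
            idx, ls, us = idx[keep], ls[keep], us[keep]
            term, cdf = term[keep], cdf[keep]
            k += 1
            term = term * ls / k
            cdf = cdf + term
        else:
            flat[idx] = kmax  # u in the far tail: cap
    return out

_MAX_BIRTHS = 8


@dataclass
class CohortArrays:
    """Struct-of-arrays form of a list of Individuals."""

    menarche: np.ndarray
    menopause: np.ndarray
    first_birth: np.ndarray  # -1 when nulliparous
    birth_ages: np.ndarray  # (n, _MAX_BIRTHS), padded with -9
    breastfeeds: np.ndarray  # bool
    smoker: np.ndarray  # bool
    grams_per_day: np.ndarray
    bmi_category: np.ndarray  # object/str array
    oc_start: np.ndarray  # -1 for never-users
    oc_stop: np.ndarray
    ht_duration: np.ndarray
    brca1: np.ndarray  # bool
    prs: np.ndarray
    screening_frequency: np.ndarray
    death_age: np.ndarray
    bmi_midpoint: np.ndarray | None = None  # overrides category when set

    @property
    def n(self) -> int:
        return len(self.menarche)

    def replace_fields(self, **kwargs) -> "CohortArrays":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class CohortOutcomes:
    """Detection and survival bookkeeping for a simulated cohort.

    ``detection_time`` refines the integer detection age by the fraction
    of the year at which the malignant pool crossed the clinical
    threshold (the pool grows exponentially within a year, so the
    crossing instant is well defined); windowed trial statistics use it
    so relative risks respond continuously to rate changes.  Screen
    detections occur at the screening visit and carry fraction zero.
    """

    detection_age: np.ndarray  # float; NaN = never detected
    detected_by_screening: np.ndarray  # bool
    death_age: np.ndarray
    detection_time: np.ndarray | None = None  # age + within-year fraction

    @property
    def n(self) -> int:
        return len(self.detection_age)

    @property
    def detected(self) -> np.ndarray:
        return ~np.isnan(self.detection_age)


def cohort_from_individuals(
    individuals: "list[Individual]",
    grams_per_drink: float = 14.0,
) -> CohortArrays:
    n = len(individuals)
    birth_ages = np.full((n, _MAX_BIRTHS), -9, dtype=np.int64)
    for i, ind in enumerate(individuals):
        ba = ind.birth_ages[:_MAX_BIRTHS]
        birth_ages[i, : len(ba)] = ba
    return CohortArrays(
        menarche=np.array([i.menarche_age for i in individuals]),
        menopause=np.array([i.menopause_age for i in individuals]),
        first_birth=np.array(
            [i.first_birth_age if i.parous else -1 for i in individuals]
        ),
        birth_ages=birth_ages,
        breastfeeds=np.array([i.breastfeeds for i in individuals]),
        smoker=np.array([i.smoker for i in individuals]),
        grams_per_day=np.array(
            [i.grams_alcohol_per_day(grams_per_drink) for i in individuals]
        ),
        bmi_category=np.array([i.bmi_category for i in individuals]),
        oc_start=np.array(
            [i.oc_start_age if i.oc_start_age is not None else -1
             for i in individuals]
        ),
        oc_stop=np.array(
            [i.oc_stop_age if i.oc_stop_age is not None else -1
             for i in individuals]
        ),
        ht_duration=np.array([i.ht_duration for i in individuals]),
        brca1=np.array([i.brca1 for i in individuals]),
        prs=np.array([i.prs for i in individuals]),
        screening_frequency=np.array(
            [i.screening_frequency for i in individuals]
        ),
        death_age=np.array([i.death_age for i in individuals]),
    )


def _year_rng(master_seed: int, age: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=np.array([master_seed, age], dtype=np.uint64))
    )


def simulate_cohort(
    cohort: CohortArrays,
    params: RateParameters,
    effects: EffectParameters,
    *,
    mode: str = "mean_field",
    seed: int = 0,
    horizon: int | None = None,
    use_screening: bool = True,
    force_survival: bool = False,
    seed_schedule: "dict[int, tuple[int, np.ndarray | float]] | None" = None,
    forced_screening_ages: "tuple[int, ...] | None" = None,
) -> CohortOutcomes:
    """Simulate every woman in ``cohort`` from birth to death/horizon.

    ``seed_schedule`` maps an age to ``(class_index, volume)`` injections
    of transformed tissue (scenario exposures).  ``force_survival`` ignores
    sampled death ages up to ``horizon`` — used by trial and calibration
    cohorts so relative risks are not confounded by competing mortality.
    ``use_screening=False`` disables screening detection (calibration runs
    use the clinical threshold only); ``forced_screening_ages`` screens every
    woman at exactly those ages (trial protocols), on top of ``use_screening``.
    """
    if mode not in ("stochastic", "mean_field"):
        raise ValueError(f"unknown mode {mode!r}")
    effects.validate()
    n = cohort.n
    death = cohort.death_age.astype(np.int64)
    if horizon is None:
        horizon = int(death.max()) if n else 0
    if force_survival:
        death = np.full(n, horizon, dtype=np.int64)
    last_age = min(horizon, int(death.max()) if n else 0)

    detection_age = np.full(n, np.nan)
    detection_time = np.full(n, np.nan)
    screen_detected = np.zeros(n, dtype=bool)
    if n == 0:
        return CohortOutcomes(detection_age, screen_detected, death,
                              detection_time)

    v = np.zeros((n, N_CLASSES))

    # --- static per-individual modifier pieces -----------------------------
    variant = BrcaVariant(effects.brca_variant)
    prs_mult = np.exp(effects.prs_scale * cohort.prs)
    carrier = cohort.brca1

    # transformation channel (applies to all six steps uniformly)
    tm_genetic = np.ones(n)
    if variant is BrcaVariant.FASTER_ACCUMULATION:
        tm_genetic = np.where(carrier, effects.brca_mult, 1.0)
    prs_variant = (
        BrcaVariant.FASTER_ACCUMULATION
        if variant is BrcaVariant.SEED_EARLY
        else variant
    )
    if prs_variant is BrcaVariant.FASTER_ACCUMULATION:
        tm_genetic = tm_genetic * prs_mult

    tm_behaviour = np.ones(n)
    tm_behaviour[cohort.smoker] *= effects.sigma_smoke
    alcohol_mult = 1.0 + effects.beta_alcohol * cohort.grams_per_day
    if not effects.alcohol_on_growth:
        tm_behaviour = tm_behaviour * alcohol_mult

    # loss channel
    lm_static = np.ones(n)
    if variant is BrcaVariant.REDUCED_REMOVAL:
        lm_static = np.where(carrier, 1.0 / effects.brca_mult, 1.0)
    if prs_variant is BrcaVariant.REDUCED_REMOVAL:
        lm_static = lm_static / prs_mult

    # growth channel, classes 1..5 (genetic) and hormonal (all classes)
    gm_genetic = np.ones(n)
    if variant is BrcaVariant.FASTER_GROWTH:
        gm_genetic = np.where(carrier, effects.brca_mult, 1.0)
    if prs_variant is BrcaVariant.FASTER_GROWTH:
        gm_genetic = gm_genetic * prs_mult

    if cohort.bmi_midpoint is not None:
        from .exposure_effects import BMI_REFERENCE

        bmi_mult = effects.bmi_per5_growth ** (
            (cohort.bmi_midpoint - BMI_REFERENCE) / 5.0
        )
    else:
        bmi_mult = np.ones(n)
        for cat in np.unique(cohort.bmi_category):
            bmi_mult[cohort.bmi_category == cat] = effects.bmi_growth_mult(
                str(cat)
            )

    schedule: dict[int, list[tuple[int, "np.ndarray | float"]]] = {}
    for age_key, (cls, vol) in (seed_schedule or {}).items():
        schedule.setdefault(int(age_key), []).append((int(cls), vol))
    if variant is BrcaVariant.SEED_EARLY:
        seed_vol = np.where(
            carrier, effects.brca_seed_volume * effects.brca_mult, 0.0
        )
        schedule.setdefault(0, []).append((effects.brca_seed_class, seed_vol))

    k5 = np.arange(5)
    atten = params.growth_rate_attenuation**k5  # shape (5,)
    loss_frac = params.loss_fraction  # shape (6,)
    ever_bf = cohort.breastfeeds & (cohort.first_birth >= 0)
    tau_vec = np.full(6, params.tau)
    tau_vec[5] = params.tau_final

    for age in range(last_age + 1):
        alive = np.isnan(detection_age) & (age <= death)
        if not alive.any():
            break
        for cls, vol in schedule.get(age, ()):  # scenario / genetic seeding
            if np.isscalar(vol):
                v[alive, cls - 1] += vol
            else:
                v[alive, cls - 1] += np.asarray(vol)[alive]

        dense = dense_volume_array(
            age, cohort.menarche, cohort.menopause, params.baseline_volume
        )
        pike = pike_multiplier_array(
            age, cohort.menarche, cohort.first_birth, cohort.menopause
        )

        post_menop = age >= cohort.menopause
        gm_hormonal = np.ones(n)
        np.multiply(
            gm_hormonal, bmi_mult, out=gm_hormonal, where=post_menop
        )
        on_ht = post_menop & (age < cohort.menopause + cohort.ht_duration)
        gm_hormonal[on_ht] *= effects.m_ht
        on_oc = (cohort.oc_start >= 0) & (age >= cohort.oc_start) & (
            age < cohort.oc_stop
        )
        gm_hormonal[on_oc] *= effects.m_oc

        tm = tm_genetic.copy()
        if age >= 15:
            tm *= tm_behaviour
            if effects.alcohol_on_growth:
                gm_hormonal = gm_hormonal * alcohol_mult

        lm = lm_static.copy()
        bf_now = ever_bf & np.any(cohort.birth_ages + 1 == age, axis=1)
        lm[bf_now] *= params.bf_loss_factor
        if age >= params.late_loss_onset_age:
            lm = lm * params.late_loss_factor

        # effective rates, shape (n, 6)
        growth = np.empty((n, 6))
        growth[:, :5] = (
            params.g0 * atten * (pike * gm_genetic * gm_hormonal)[:, None]
        )
        growth[:, 5] = params.g_malignant * gm_hormonal
        loss = (params.lambda0 * lm)[:, None] * loss_frac

        sources = np.concatenate((dense[:, None], v[:, :5]), axis=1)
        expected = (tau_vec * tm[:, None]) * sources
        if mode == "mean_field":
            flux = np.minimum(expected, sources)
        else:
            rng = _year_rng(seed, age)
            u = rng.random((n, 6))
            counts = poisson_inverse_cdf(u, expected / params.quantum)
            flux = np.minimum(counts * params.quantum, sources)
        flux[~alive] = 0.0

        arrivals = flux.copy()
        if mode == "stochastic":
            # malignant clones are seeded at a uniform instant within the
            # year and experience only the remaining fraction of that
            # year's growth: without this, single-clone tumors detected
            # after a fixed sojourn would sit on an integer time lattice
            u6 = _year_rng(seed ^ 0x77C10, age).random(n)
            g6_net = growth[:, 5] - loss[:, 5]
            arrivals[:, 5] = flux[:, 5] * np.exp(-g6_net * u6)
        v[:, :] += arrivals
        v[:, :5] -= flux[:, 1:]
        np.maximum(v, 0.0, out=v)
        v6_pre = v[:, 5].copy()  # post-flux, pre-growth malignant volume
        factor = np.exp(growth - loss)
        v[alive] *= factor[alive]
        if not np.all(np.isfinite(v[alive])):
            raise FloatingPointError("non-finite tissue volumes")

        malignant = v[:, 5]
        if use_screening:
            rng_s = _year_rng(seed ^ 0x5C12EE, age)
            u = rng_s.random(n)
            screened = (
                (age >= SCREENING_START_AGE)
                & (u < cohort.screening_frequency / 7.0)
            )
        else:
            screened = np.zeros(n, dtype=bool)
        if forced_screening_ages is not None and age in forced_screening_ages:
            screened = np.ones(n, dtype=bool)
        clinical = malignant >= params.theta_clinical
        by_screen = screened & (malignant >= params.theta_screen) & ~clinical
        newly = alive & (clinical | by_screen)
        detection_age[newly] = age
        screen_detected[newly & by_screen] = True
        new_clin = newly & clinical
        if new_clin.any():
            # fraction of the year at which v6 crossed the threshold
            g6 = growth[new_clin, 5] - loss[new_clin, 5]
            pre = v6_pre[new_clin]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(
                    (pre > 0) & (pre < params.theta_clinical) & (g6 > 0),
                    np.log(params.theta_clinical / np.maximum(pre, 1e-300))
                    / np.maximum(g6, 1e-300),
                    0.0,
                )
            detection_time[new_clin] = age + np.clip(frac, 0.0, 1.0)
        new_scr = newly & by_screen
        detection_time[new_scr] = age

    return CohortOutcomes(detection_age, screen_detected, death,
                          detection_time)
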