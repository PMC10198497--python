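"""Synthetic population generator.

Samples cohorts of :class:`~mammosim.life_course.Individual` whose marginal
and joint exposure distributions are set entirely by a
:class:`PopulationConfig` — age pyramid, reproductive milestones, parity
and birth ages, breastfeeding, smoking, alcohol, BMI category, oral
contraceptive and hormone-therapy use (via the four-quantile joint
age-sampling scheme), BRCA1 prevalence by race/ethnicity, a normal
polygenic score, screening frequency stratified by race/ethnicity and
rural/urban residence, and an all-cause life table.

The packaged default tables are plausible synthetic US-female values chosen
by the package authors (clearly labelled synthetic); users substitute their
own survey-derived CSV summary tables through
:func:`load_population_tables`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .life_course import Individual

__all__ = [
    "PopulationConfig",
    "default_config",
    "sample_population",
    "quantile_joint_sample",
    "conditional_quantile_sample",
    "assign_screening",
    "load_population_tables",
    "save_population_tables",
    "sample_death_ages",
    "gompertz_life_table",
]


class ConfigError(ValueError):
    """A population configuration failed validation."""


def _check_dist(name: str, dist: dict) -> None:
    probs = np.array(list(dist.values()), dtype=float)
    if len(probs) == 0:
        raise ConfigError(f"{name}: empty distribution")
    if np.any(probs < 0):
        raise ConfigError(f"{name}: negative probability")
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ConfigError(
            f"{name}: probabilities sum to {probs.sum():.6f}, not 1"
        )


@dataclass
class PopulationConfig:
    """Distribution parameters for population sampling.

    Categorical distributions are ``{level: probability}`` dicts;
    ``oc_pairs`` holds (start_age, stop_age) observations and ``ht_pairs``
    (start_age, duration_years) observations feeding the four-quantile
    joint sampler; ``mortality_table`` is annual survival probability
    indexed by age.
    """

    age_pyramid: dict[int, float]
    race_ethnicity_probs: dict[str, float]
    rural_prob_by_race: dict[str, float]
    menarche_dist: dict[int, float]
    menopause_dist: dict[int, float]
    parity_dist: dict[int, float]
    birth_age_mean: float
    birth_age_sd: float
    ever_breastfed_prob: float
    smoker_prob: float
    drinks_per_year_dist: dict[float, float]
    bmi_category_probs: dict[str, float]
    oc_ever_prob: float
    oc_pairs: np.ndarray
    ht_ever_prob: float
    ht_pairs: np.ndarray
    brca1_prev_by_race: dict[str, float]
    prs_mean: float
    prs_sd: float
    screening_freq_dist: dict[tuple[str, bool], np.ndarray]
    mortality_table: np.ndarray
    n_quantiles: int = 4

    def validate(self) -> None:
        for name in ("age_pyramid", "race_ethnicity_probs", "menarche_dist",
                     "menopause_dist", "parity_dist", "drinks_per_year_dist",
                     "bmi_category_probs"):
            dist = getattr(self, name)
            if name == "age_pyramid":
                w = np.array(list(dist.values()), dtype=float)
                if len(w) == 0 or w.sum() <= 0 or np.any(w < 0):
                    raise ConfigError("age_pyramid weights must be positive")
                continue
            _check_dist(name, dist)
        for p_name in ("ever_breastfed_prob", "smoker_prob", "oc_ever_prob",
                       "ht_ever_prob"):
            p = getattr(self, p_name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{p_name} must be in [0, 1]")
        for race, p in {**self.rural_prob_by_race,
                        **self.brca1_prev_by_race}.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"probability for {race!r} out of [0, 1]")
        if max(self.menarche_dist) >= min(self.menopause_dist):
            raise ConfigError(
                "menopause distribution must lie strictly above the "
                "menarche support"
            )
        for key, dist in self.screening_freq_dist.items():
            dist = np.asarray(dist, dtype=float)
            if dist.shape != (8,) or np.any(dist < 0) or not np.isclose(
                dist.sum(), 1.0, atol=1e-6
            ):
                raise ConfigError(
                    f"screening distribution for stratum {key} must be 8 "
                    "non-negative probabilities summing to 1"
                )
        surv = np.asarray(self.mortality_table, dtype=float)
        if np.any((surv < 0) | (surv > 1)):
            raise ConfigError("mortality_table entries must be in [0, 1]")
        if len(self.oc_pairs) == 0 or len(self.ht_pairs) == 0:
            raise ConfigError("oc_pairs and ht_pairs must be non-empty")
        if self.prs_sd < 0 or self.birth_age_sd <= 0:
            raise ConfigError("scale parameters must be positive")


# ---------------------------------------------------------------------------
# Quantile-based joint sampling (OC start/stop, HT start/duration)
# ---------------------------------------------------------------------------

def _quantile_bins(values: np.ndarray, n_quantiles: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin assignment and per-bin medians for one margin."""
    edges = np.quantile(values, np.linspace(0, 1, n_quantiles + 1)[1:-1])
    bins = np.digitize(values, edges, right=True)
    medians = np.array([
        np.median(values[bins == b]) if np.any(bins == b)
        else np.median(values)
        for b in range(n_quantiles)
    ])
    return bins, medians


def quantile_joint_sample(
    pairs: np.ndarray,
    n_quantiles: int = 4,
    rng: np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw (start, stop) values via the joint-quantile aggregation scheme.

    Each margin is cut into ``n_quantiles`` quantile bins; a (start-bin,
    stop-bin) cell is drawn with its empirical frequency and the margin
    medians of the drawn bins are returned, so the output support has at
    most ``n_quantiles`` distinct values per margin.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("quantile_joint_sample: empty input")
    if rng is None:
        rng = np.random.default_rng()
    scalar = size is None
    m = 1 if scalar else size

    start_bins, start_medians = _quantile_bins(pairs[:, 0], n_quantiles)
    stop_bins, stop_medians = _quantile_bins(pairs[:, 1], n_quantiles)
    cell = start_bins * n_quantiles + stop_bins
    counts = np.bincount(cell, minlength=n_quantiles**2).astype(float)
    probs = counts / counts.sum()

    draws = rng.choice(n_quantiles**2, size=m, p=probs)
    out = np.column_stack(
        (start_medians[draws // n_quantiles], stop_medians[draws % n_quantiles])
    )
    return out[0] if scalar else out


def conditional_quantile_sample(
    pairs: np.ndarray,
    given_start: np.ndarray,
    n_quantiles: int = 4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the second margin's quantile median conditional on the first.

    Used for hormone therapy: the duration quantile is drawn from its
    empirical distribution *given* the quantile of the starting age, which
    for every user equals her age at menopause.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("conditional_quantile_sample: empty input")
    if rng is None:
        rng = np.random.default_rng()
    given_start = np.atleast_1d(np.asarray(given_start, dtype=float))

    start_bins, _ = _quantile_bins(pairs[:, 0], n_quantiles)
    dur_bins, dur_medians = _quantile_bins(pairs[:, 1], n_quantiles)

    # conditional P(duration bin | start bin), with marginal fallback
    cond = np.zeros((n_quantiles, n_quantiles))
    for i in range(n_quantiles):
        sel = start_bins == i
        if sel.any():
            cond[i] = np.bincount(dur_bins[sel], minlength=n_quantiles)
        else:
            cond[i] = np.bincount(dur_bins, minlength=n_quantiles)
        cond[i] /= cond[i].sum()

    edges = np.quantile(pairs[:, 0], np.linspace(0, 1, n_quantiles + 1)[1:-1])
    given_bins = np.digitize(given_start, edges, right=True)
    u = rng.random(len(given_start))
    cum = np.cumsum(cond, axis=1)
    drawn = (u[:, None] > cum[given_bins]).sum(axis=1)
    return dur_medians[drawn]


def assign_screening(
    race: str,
    rural: bool,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> int:
    """Draw screenings-per-7-years (0..7) from the stratum's distribution."""
    key = (race, bool(rural))
    if key not in config.screening_freq_dist:
        raise KeyError(f"no screening distribution for stratum {key}")
    dist = np.asarray(config.screening_freq_dist[key], dtype=float)
    if not np.isclose(dist.sum(), 1.0, atol=1e-6):
        raise ConfigError(f"screening probabilities for {key} do not sum to 1")
    return int(rng.choice(8, p=dist))


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

def gompertz_life_table(
    a: float = 2.0e-5, b: float = 0.097, max_age: int = 110
) -> np.ndarray:
    """Annual survival by age under a Gompertz hazard h(t) = a * exp(b t).

    The defaults give a life expectancy near 81 years, a plausible value
    for a contemporary US female population.
    """
    ages = np.arange(max_age + 1)
    hazard = a * np.exp(b * ages)
    return np.exp(-hazard)


def sample_death_ages(
    mortality_table: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample integer death ages from an annual-survival life table."""
    surv = np.asarray(mortality_table, dtype=float)
    cum = np.cumprod(surv)
    u = rng.random(size)
    death = np.searchsorted(-cum, -u, side="right")  # first age with S < u
    return np.clip(death, 1, len(surv) - 1)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def _draw_categorical(
    dist: dict, size: int, rng: np.random.Generator
) -> np.ndarray:
    levels = list(dist.keys())
    probs = np.array([dist[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(levels), size=size, p=probs)
    return np.array(levels, dtype=object)[idx]


def _sample_birth_ages(
    parity: int,
    menarche: int,
    menopause: int,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Birth ages as rounded order statistics of a truncated normal."""
    if parity == 0:
        return ()
    lo, hi = menarche + 1, menopause - 1
    draws = rng.normal(config.birth_age_mean, config.birth_age_sd, parity * 3)
    draws = draws[(draws >= lo) & (draws <= hi)]
    while len(draws) < parity:
        extra = rng.normal(config.birth_age_mean, config.birth_age_sd, parity * 3)
        draws = np.concatenate([draws, extra[(extra >= lo) & (extra <= hi)]])
        if len(draws) == 0 and hi - lo < 1:
            break
    ages = np.sort(np.round(draws[:parity]).astype(int))
    # enforce strict increase within the fertile window
    out: list[int] = []
    for a in ages:
        a = max(a, (out[-1] + 1) if out else lo)
        if a > hi:
            break
        out.append(int(a))
    return tuple(out)


def sample_population(
    config: PopulationConfig, n: int, seed: int
) -> list[Individual]:
    """Sample ``n`` Individuals; reproducible given ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    if n == 0:
        return []

    birth_years = _draw_categorical(config.age_pyramid, n, rng).astype(int)
    races = _draw_categorical(config.race_ethnicity_probs, n, rng)
    rural_p = np.array(
        [config.rural_prob_by_race.get(r, 0.0) for r in races]
    )
    rural = rng.random(n) < rural_p
    menarche = _draw_categorical(config.menarche_dist, n, rng).astype(int)
    menopause = _draw_categorical(config.menopause_dist, n, rng).astype(int)
    menopause = np.maximum(menopause, menarche + 2)
    parity = _draw_categorical(config.parity_dist, n, rng).astype(int)
    breastfeeds = rng.random(n) < config.ever_breastfed_prob
    smoker = rng.random(n) < config.smoker_prob
    drinks = _draw_categorical(config.drinks_per_year_dist, n, rng).astype(
        float
    )
    bmi = _draw_categorical(config.bmi_category_probs, n, rng)
    brca_p = np.array([config.brca1_prev_by_race.get(r, 0.0) for r in races])
    brca = rng.random(n) < brca_p
    prs = rng.normal(config.prs_mean, config.prs_sd, n)
    death = sample_death_ages(config.mortality_table, n, rng)

    oc_user = rng.random(n) < config.oc_ever_prob
    oc_draws = quantile_joint_sample(
        config.oc_pairs, config.n_quantiles, rng, size=n
    )
    ht_user = rng.random(n) < config.ht_ever_prob
    ht_durations = conditional_quantile_sample(
        config.ht_pairs, menopause.astype(float), config.n_quantiles, rng
    )

    individuals: list[Individual] = []
    for i in range(n):
        births = _sample_birth_ages(
            int(parity[i]), int(menarche[i]), int(menopause[i]), config, rng
        )
        oc_start = oc_stop = None
        if oc_user[i]:
            s = int(round(oc_draws[i, 0]))
            t = int(round(oc_draws[i, 1]))
            s = max(s, int(menarche[i]))
            t = min(max(t, s), int(menopause[i]))
            oc_start, oc_stop = s, t
        ht_dur = int(round(ht_durations[i])) if ht_user[i] else 0
        individuals.append(
            Individual(
                id=i,
                birth_year=int(birth_years[i]),
                race_ethnicity=str(races[i]),
                rural=bool(rural[i]),
                menarche_age=int(menarche[i]),
                birth_ages=births,
                breastfeeds=bool(breastfeeds[i]) and len(births) > 0,
                menopause_age=int(menopause[i]),
                smoker=bool(smoker[i]),
                drinks_per_year=float(drinks[i]),
                bmi_category=str(bmi[i]),
                oc_start_age=oc_start,
                oc_stop_age=oc_stop,
                ht_duration=max(ht_dur, 0),
                brca1=bool(brca[i]),
                prs=float(prs[i]),
                screening_frequency=assign_screening(
                    str(races[i]), bool(rural[i]), config, rng
                ),
                death_age=int(death[i]),
            )
        )
    return individuals


# ---------------------------------------------------------------------------
# CSV configuration tables
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "age_pyramid": "age_pyramid.csv",
    "race_ethnicity": "race_ethnicity.csv",
    "rural_by_race": "rural_by_race.csv",
    "menarche": "menarche.csv",
    "menopause": "menopause.csv",
    "parity": "parity.csv",
    "drinks_per_year": "drinks_per_year.csv",
    "bmi_category": "bmi_category.csv",
    "oc_pairs": "oc_pairs.csv",
    "ht_pairs": "ht_pairs.csv",
    "brca1_by_race": "brca1_by_race.csv",
    "screening": "screening.csv",
    "mortality": "mortality.csv",
    "scalars": "population_scalars.csv",
}


def _read_dist(path: Path, key_col: str, key_type=float) -> dict:
    df = pd.read_csv(path)
    if key_col not in df.columns or "probability" not in df.columns:
        raise ConfigError(
            f"{path}: expected columns ({key_col}, probability), got "
            f"{list(df.columns)}"
        )
    return {key_type(r[key_col]): float(r["probability"])
            for _, r in df.iterrows()}


def load_population_tables(directory: str | Path) -> PopulationConfig:
    """Load a population configuration from a directory of CSV tables.

    Expected files and schemas (UTF-8, header row required): see the
    packaged defaults under ``mammosim/data`` for a complete example.
    Raises :class:`ConfigError` naming the offending file and rows.
    """
    d = Path(directory)
    for f in _TABLE_FILES.values():
        if not (d / f).exists():
            raise ConfigError(f"missing population table {f} in {d}")

    pyramid_df = pd.read_csv(d / _TABLE_FILES["age_pyramid"])
    if pyramid_df["weight"].sum() <= 0:
        raise ConfigError("age_pyramid.csv: weights sum to zero")
    age_pyramid = {
        int(r.birth_year): float(r.weight) for r in pyramid_df.itertuples()
    }

    rural_df = pd.read_csv(d / _TABLE_FILES["rural_by_race"])
    brca_df = pd.read_csv(d / _TABLE_FILES["brca1_by_race"])
    screening_df = pd.read_csv(d / _TABLE_FILES["screening"])
    screening: dict[tuple[str, bool], np.ndarray] = {}
    for (race, rural), grp in screening_df.groupby(["race", "rural"]):
        dist = np.zeros(8)
        dist[grp["frequency"].to_numpy(dtype=int)] = grp[
            "probability"
        ].to_numpy(dtype=float)
        screening[(str(race), bool(rural))] = dist

    mort_df = pd.read_csv(d / _TABLE_FILES["mortality"])
    max_age = int(mort_df["age"].max())
    mortality = np.ones(max_age + 1)
    mortality[mort_df["age"].to_numpy(dtype=int)] = mort_df[
        "annual_survival"
    ].to_numpy(dtype=float)

    scalars = pd.read_csv(d / _TABLE_FILES["scalars"]).set_index("name")[
        "value"
    ]

    oc_pairs = pd.read_csv(d / _TABLE_FILES["oc_pairs"])[
        ["start", "stop"]
    ].to_numpy(dtype=float)
    ht_pairs = pd.read_csv(d / _TABLE_FILES["ht_pairs"])[
        ["start", "stop"]
    ].to_numpy(dtype=float)

    config = PopulationConfig(
        age_pyramid=age_pyramid,
        race_ethnicity_probs=_read_dist(
            d / _TABLE_FILES["race_ethnicity"], "level", str
        ),
        rural_prob_by_race={
            str(r.race): float(r.probability) for r in rural_df.itertuples()
        },
        menarche_dist=_read_dist(d / _TABLE_FILES["menarche"], "level", int),
        menopause_dist=_read_dist(d / _TABLE_FILES["menopause"], "level", int),
        parity_dist=_read_dist(d / _TABLE_FILES["parity"], "level", int),
        birth_age_mean=float(scalars["birth_age_mean"]),
        birth_age_sd=float(scalars["birth_age_sd"]),
        ever_breastfed_prob=float(scalars["ever_breastfed_prob"]),
        smoker_prob=float(scalars["smoker_prob"]),
        drinks_per_year_dist=_read_dist(
            d / _TABLE_FILES["drinks_per_year"], "level", float
        ),
        bmi_category_probs=_read_dist(
            d / _TABLE_FILES["bmi_category"], "level", str
        ),
        oc_ever_prob=float(scalars["oc_ever_prob"]),
        oc_pairs=oc_pairs,
        ht_ever_prob=float(scalars["ht_ever_prob"]),
        ht_pairs=ht_pairs,
        brca1_prev_by_race={
            str(r.race): float(r.prevalence) for r in brca_df.itertuples()
        },
        prs_mean=float(scalars["prs_mean"]),
        prs_sd=float(scalars["prs_sd"]),
        screening_freq_dist=screening,
        mortality_table=mortality,
    )
    config.validate()
    return config


def save_population_tables(config: PopulationConfig, directory: str | Path) -> None:
    """Write a configuration back to its CSV-table form (round-trips with
    :func:`load_population_tables`)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def _write_dist(dist: dict, key_col: str, fname: str) -> None:
        pd.DataFrame(
            {key_col: list(dist.keys()), "probability": list(dist.values())}
        ).to_csv(d / fname, index=False)

    pd.DataFrame(
        {"birth_year": list(config.age_pyramid.keys()),
         "weight": list(config.age_pyramid.values())}
    ).to_csv(d / _TABLE_FILES["age_pyramid"], index=False)
    _write_dist(config.race_ethnicity_probs, "level",
                _TABLE_FILES["race_ethnicity"])
    pd.DataFrame(
        {"race": list(config.rural_prob_by_race.keys()),
         "probability": list(config.rural_prob_by_race.values())}
    ).to_csv(d / _TABLE_FILES["rural_by_race"], index=False)
    _write_dist(config.menarche_dist, "level", _TABLE_FILES["menarche"])
    _write_dist(config.menopause_dist, "level", _TABLE_FILES["menopause"])
    _write_dist(config.parity_dist, "level", _TABLE_FILES["parity"])
    _write_dist(config.drinks_per_year_dist, "level",
                _TABLE_FILES["drinks_per_year"])
    _write_dist(config.bmi_category_probs, "level",
                _TABLE_FILES["bmi_category"])
    pd.DataFrame(config.oc_pairs, columns=["start", "stop"]).to_csv(
        d / _TABLE_FILES["oc_pairs"], index=False
    )
    pd.DataFrame(config.ht_pairs, columns=["start", "stop"]).to_csv(
        d / _TABLE_FILES["ht_pairs"], index=False
    )
    pd.DataFrame(
        {"race": list(config.brca1_prev_by_race.keys()),
         "prevalence": list(config.brca1_prev_by_race.values())}
    ).to_csv(d / _TABLE_FILES["brca1_by_race"], index=False)
    rows = []
    for (race, rural), dist in config.screening_freq_dist.items():
        for f, p in enumerate(dist):
            rows.append({"race": race, "rural": rural, "frequency": f,
                         "probability": p})
    pd.DataFrame(rows).to_csv(d / _TABLE_FILES["screening"], index=False)
    pd.DataFrame(
        {"age": np.arange(len(config.mortality_table)),
         "annual_survival": config.mortality_table}
    ).to_csv(d / _TABLE_FILES["mortality"], index=False)
    pd.DataFrame(
        {"name": ["birth_age_mean", "birth_age_sd", "ever_breastfed_prob",
                  "smoker_prob", "oc_ever_prob", "ht_ever_prob", "prs_mean",
                  "prs_sd"],
         "value": [config.birth_age_mean, config.birth_age_sd,
                   config.ever_breastfed_prob, config.smoker_prob,
                   config.oc_ever_prob, config.ht_ever_prob,
                   config.prs_mean, config.prs_sd]}
    ).to_csv(d / _TABLE_FILES["scalars"], index=False)


def default_config() -> PopulationConfig:
    """The packaged synthetic default configuration."""
    data_dir = importlib.resources.files("mammosim") / "data" / "population"
    return load_population_tables(str(data_dir))
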