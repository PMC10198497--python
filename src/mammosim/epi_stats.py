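"""Population incidence statistics from simulated life outcomes.

Turns cohorts of life outcomes into age-specific incidence curves,
cumulative incidence, relative risks and log-slope diagnostics, with a
comparison hook for an external registry reference curve.

Person-time convention: a woman contributes one person-year for every
completed year before her exit (detection or death) and half a year in the
exit year, the standard actuarial correction.  Cumulative incidence uses
the discrete product-limit estimator with death treated as censoring, so
it is robust to the mortality table; a simple-proportion mode is available
for trial cohorts whose survival is forced to the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortOutcomes
from .tissue_dynamics import LifeOutcome

__all__ = [
    "IncidenceCurve",
    "age_specific_incidence",
    "cumulative_incidence",
    "relative_risk",
    "log_slope",
    "compare_to_reference",
    "outcome_arrays",
]


def outcome_arrays(
    outcomes: "CohortOutcomes | list[LifeOutcome]",
) -> tuple[np.ndarray, np.ndarray]:
    """(detection_age with NaN for censored, exit_age) from either form."""
    if isinstance(outcomes, CohortOutcomes):
        det = outcomes.detection_age
        death = outcomes.death_age
    else:
        det = np.array(
            [o.detection_age if o.cancer_detected else np.nan
             for o in outcomes],
            dtype=float,
        )
        death = np.array([o.death_age for o in outcomes], dtype=float)
    exit_age = np.where(np.isnan(det), death, det)
    return det, exit_age


@dataclass
class IncidenceCurve:
    """Age-binned incidence: half-open bins [start, end), rates per
    person-year (reported per 100,000)."""

    bin_start: np.ndarray
    bin_end: np.ndarray
    person_years: np.ndarray
    cases: np.ndarray

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.person_years > 0, self.cases / self.person_years, 0.0
            )

    @property
    def rate_per_100k(self) -> np.ndarray:
        return self.rate * 1e5

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_start + self.bin_end) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_end": self.bin_end,
                "person_years": self.person_years,
                "cases": self.cases,
                "rate_per_100k": self.rate_per_100k,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceCurve":
        return cls(
            bin_start=df["bin_start"].to_numpy(dtype=float),
            bin_end=df["bin_end"].to_numpy(dtype=float),
            person_years=df["person_years"].to_numpy(dtype=float),
            cases=df["cases"].to_numpy(dtype=float),
        )


def age_specific_incidence(
    outcomes: "CohortOutcomes | list[LifeOutcome]",
    bins: np.ndarray | None = None,
) -> IncidenceCurve:
    """Age-specific incidence with 5-year default bins [0,5), ..., [95,100).

    Person-years accumulate until detection or death (half a year in the
    exit year); cases are assigned to the bin of the detection age.
    """
    det, exit_age = outcome_arrays(outcomes)
    if len(exit_age) == 0:
        raise ValueError("age_specific_incidence: empty cohort")
    if bins is None:
        bins = np.arange(0, 105, 5)
    bins = np.asarray(bins, dtype=float)

    max_age = int(bins[-1])
    ages = np.arange(max_age + 1)
    # at age a: full year if exit > a, half year if exit == a
    n_full = np.array([(exit_age > a).sum() for a in ages], dtype=float)
    n_half = np.array([(exit_age == a).sum() for a in ages], dtype=float)
    py_by_age = n_full + 0.5 * n_half

    py = np.array(
        [
            py_by_age[int(lo): int(hi)].sum()
            for lo, hi in zip(bins[:-1], bins[1:])
        ]
    )
    cases, _ = np.histogram(det[~np.isnan(det)], bins=bins)
    return IncidenceCurve(
        bin_start=bins[:-1],
        bin_end=bins[1:],
        person_years=py,
        cases=cases.astype(float),
    )


def cumulative_incidence(
    outcomes: "CohortOutcomes | list[LifeOutcome]",
    up_to_age: float,
    method: str = "product_limit",
) -> float:
    """Cumulative incidence of detected cancer by ``up_to_age``.

    ``product_limit``: 1 - prod over single years of age of (1 - d_a/n_a),
    with deaths treated as censoring at their year of age.  ``proportion``:
    detected fraction, appropriate when survival is forced to the horizon.
    """
    if up_to_age <= 0:
        raise ValueError("up_to_age must be positive")
    det, exit_age = outcome_arrays(outcomes)
    if len(exit_age) == 0:
        raise ValueError("cumulative_incidence: empty cohort")
    if method == "proportion":
        return float(np.mean(det <= up_to_age))
    if method != "product_limit":
        raise ValueError(f"unknown method {method!r}")

    surv = 1.0
    last = int(np.ceil(up_to_age))
    for a in range(last):
        if a >= up_to_age:
            break
        at_risk = (exit_age >= a).sum()
        if at_risk == 0:
            break
        d = np.sum(det == a)
        surv *= 1.0 - d / at_risk
    return float(1.0 - surv)


def relative_risk(
    exposed: "CohortOutcomes | list[LifeOutcome]",
    unexposed: "CohortOutcomes | list[LifeOutcome]",
    up_to_age: float = 75.0,
    method: str = "product_limit",
) -> float:
    """Ratio of cumulative incidences to ``up_to_age`` (exposed over
    unexposed)."""
    ci_u = cumulative_incidence(unexposed, up_to_age, method)
    if ci_u == 0:
        raise ZeroDivisionError("no cases in the unexposed arm")
    return cumulative_incidence(exposed, up_to_age, method) / ci_u


def log_slope(
    curve: IncidenceCurve,
    age_range: tuple[float, float] = (30.0, 55.0),
    offset: float = 0.0,
) -> float:
    """Least-squares slope of log(rate) against log(age - offset) over
    bins whose midpoint falls in ``age_range``.

    ``offset`` subtracts a tissue-age origin (e.g. a common menarche age)
    before taking logs; 0 fits against chronological age.
    """
    mids = curve.midpoints
    sel = (
        (mids >= age_range[0])
        & (mids <= age_range[1])
        & (curve.rate > 0)
        & (mids > offset)
    )
    if sel.sum() < 2:
        raise ValueError("log_slope needs at least two bins with cases")
    x = np.log(mids[sel] - offset)
    y = np.log(curve.rate[sel])
    return float(np.polyfit(x, y, 1)[0])


def compare_to_reference(
    model: IncidenceCurve, reference: "IncidenceCurve | pd.DataFrame"
) -> pd.DataFrame:
    """Per-bin model/reference rate ratios plus a person-year-weighted RMS
    log-ratio summary (no fitting).

    The reference is a curve with identical bins, e.g. loaded from a
    registry CSV with the incidence-curve schema.  Raises on bin mismatch,
    naming the offending bins.
    """
    if isinstance(reference, pd.DataFrame):
        reference = IncidenceCurve.from_frame(reference)
    if not (
        np.array_equal(model.bin_start, reference.bin_start)
        and np.array_equal(model.bin_end, reference.bin_end)
    ):
        missing = sorted(
            set(map(tuple, np.c_[model.bin_start, model.bin_end]))
            ^ set(map(tuple, np.c_[reference.bin_start, reference.bin_end]))
        )
        raise ValueError(f"bin mismatch between curves: {missing}")

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            reference.rate > 0, model.rate / reference.rate, np.nan
        )
    ok = ~np.isnan(ratio) & (ratio > 0)
    w = model.person_years[ok]
    rms = float(
        np.sqrt(np.average(np.log(ratio[ok]) ** 2, weights=w))
        if ok.any()
        else np.nan
    )
    out = pd.DataFrame(
        {
            "bin_start": model.bin_start,
            "bin_end": model.bin_end,
            "model_rate_per_100k": model.rate_per_100k,
            "reference_rate_per_100k": reference.rate_per_100k,
            "ratio": ratio,
        }
    )
    out.attrs["weighted_rms_log_ratio"] = rms
    return out
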