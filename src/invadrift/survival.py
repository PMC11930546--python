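"""Constant-hazard larval survival estimation and passive-drift dispersal.

Free-swimming cryptoniscan larvae of the bopyrid isopod *Orthione griffenis*
cannot feed; how long they survive bounds how far coastal currents can carry
them.  This module estimates the per-day mortality hazard ``b`` from
interval-censored laboratory survival experiments under an exponential
(constant-hazard) lifetime model, attaches an exact Poisson confidence
interval to the death count, and propagates the estimate to

* the population half-life ``H = ln 2 / b`` (days), and
* a drift-dispersal index ``D = H * V`` (km) at a prevailing current
  velocity ``V`` (km/day; default 50, a strong Davidson Current).

The hazard MLE is the classical person-time estimator: deaths divided by
exposure, where exposure is the summed at-risk time of every individual
(deaths contribute their time to death, survivors their full observation
time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TreatmentLabel",
    "SurvivalRecord",
    "MortalityEstimate",
    "DispersalEstimate",
    "SurvivalReport",
    "DEFAULT_VELOCITY_KM_PER_DAY",
    "compute_exposure",
    "estimate_mortality",
    "half_life",
    "dispersal_distance",
    "summarize_experiment",
]

#: Prevailing coastal current velocity used for the drift index, km/day.
#: The northeast-Pacific Davidson Current can exceed this during strong
#: El Niño winters.
DEFAULT_VELOCITY_KM_PER_DAY = 50.0

_LIGHT_REGIMES = ("dark", "diel")


@dataclass(frozen=True, order=True)
class TreatmentLabel:
    """An experimental treatment: holding temperature and light regime."""

    temperature_c: float
    light: str

    def __post_init__(self) -> None:
        if self.temperature_c <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature_c}")
        if self.light not in _LIGHT_REGIMES:
            raise ValueError(f"light must be one of {_LIGHT_REGIMES}, got {self.light!r}")

    def __str__(self) -> str:
        temp = int(self.temperature_c) if float(self.temperature_c).is_integer() else self.temperature_c
        return f"{temp}C {self.light}"


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual's observed lifetime (death) or censoring time.

    ``event_day`` is days since experiment start: for deaths, the inspection
    day at which the individual was found dead; for censored individuals,
    the last day it was observed alive (usually the experiment horizon).
    """

    individual_id: str
    replicate_id: str
    treatment: TreatmentLabel
    outcome: str  # "died" | "censored"
    event_day: float
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in ("died", "censored"):
            raise ValueError(f"outcome must be 'died' or 'censored', got {self.outcome!r}")
        if not math.isfinite(self.event_day) or self.event_day < 0:
            raise ValueError(f"event_day must be finite and >= 0, got {self.event_day}")

    @property
    def died(self) -> bool:
        return self.outcome == "died"


@dataclass(frozen=True)
class MortalityEstimate:
    """Hazard-rate MLE ``rate_b = deaths / exposure`` with exact Poisson CI."""

    deaths: int
    exposure: float
    rate_b: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


@dataclass(frozen=True)
class DispersalEstimate:
    """Half-life and drift distance, optionally with interval bounds."""

    half_life_days: float
    velocity_km_per_day: float
    distance_km: float
    half_life_interval: tuple[float, float] | None = None
    distance_interval: tuple[float, float] | None = None


@dataclass
class SurvivalReport:
    """Per-replicate and pooled mortality/half-life/drift summary.

    ``table`` holds full-precision values, one row per (treatment,
    replicate) plus a final pooled row carrying CI columns.  Use
    :meth:`to_display` for printed-precision formatting.
    """

    table: pd.DataFrame
    velocity_km_per_day: float
    ci_level: float = 0.95

    def to_display(self) -> pd.DataFrame:
        """Render with reporting precision: rates to 3 decimals, half-lives
        truncated to whole days, distances = truncated half-life x V."""
        disp = self.table.copy()
        disp["rate_b"] = disp["rate_b"].round(3)
        for col in ("half_life_days", "half_life_low", "half_life_high"):
            if col in disp:
                disp[col] = disp[col].apply(
                    lambda h: math.floor(h) if pd.notna(h) and math.isfinite(h) else h
                )
        disp["drift_km"] = disp["half_life_days"] * self.velocity_km_per_day
        if "half_life_low" in disp:
            disp["drift_low"] = disp["half_life_low"] * self.velocity_km_per_day
            disp["drift_high"] = disp["half_life_high"] * self.velocity_km_per_day
        return disp


def _validate_records(records: Sequence[SurvivalRecord]) -> None:
    if len(records) == 0:
        raise ValueError("no records")
    seen = set()
    for r in records:
        key = (r.experiment_id, r.replicate_id, r.individual_id)
        if key in seen:
            raise ValueError(f"duplicate record for individual {key}")
        seen.add(key)


def compute_exposure(records: Iterable[SurvivalRecord]) -> float:
    """Total exposure in individual-days: the summed observed survival time
    of all individuals (deaths to their death day, survivors to censoring)."""
    records = list(records)
    _validate_records(records)
    return float(sum(r.event_day for r in records))


def _poisson_rate_ci(deaths: int, exposure: float, ci_level: float) -> tuple[float, float]:
    """Exact (Garwood) two-sided CI for a Poisson count, scaled by exposure.

    lower = qchisq(alpha/2, 2d)/2, upper = qchisq(1-alpha/2, 2d+2)/2; zero
    deaths give a one-sided interval with lower bound 0.
    """
    alpha = 1.0 - ci_level
    if deaths == 0:
        low = 0.0
    else:
        low = stats.chi2.ppf(alpha / 2.0, 2 * deaths) / 2.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * deaths + 2) / 2.0
    return low / exposure, high / exposure


def estimate_mortality(
    records: Iterable[SurvivalRecord], ci_level: float = 0.95
) -> MortalityEstimate:
    """MLE of the constant hazard: deaths / exposure, with exact Poisson CI.

    Under an exponential lifetime model with right censoring the
    log-likelihood is ``d log b - b * E`` (d deaths, E exposure), maximised
    at ``b = d/E``.  Zero deaths return rate 0 with a one-sided upper bound.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    records = list(records)
    exposure = compute_exposure(records)
    if exposure <= 0:
        raise ValueError("total exposure is zero: all records censored at time 0")
    deaths = sum(1 for r in records if r.died)
    rate = deaths / exposure
    ci_low, ci_high = _poisson_rate_ci(deaths, exposure, ci_level)
    return MortalityEstimate(
        deaths=deaths,
        exposure=exposure,
        rate_b=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
    )


def half_life(rate_b: float) -> float:
    """Half-life in days under constant hazard ``rate_b``: ln 2 / b.

    The time at which the surviving fraction of a cohort reaches 50%.
    """
    if rate_b <= 0:
        raise ValueError(f"non-positive hazard: {rate_b}")
    return math.log(2.0) / rate_b


def dispersal_distance(half_life_days, velocity_km_per_day: float):
    """Drift-dispersal index D = H * V in km.

    ``half_life_days`` may be a scalar or an ``(low, high)`` interval, in
    which case the interval is scaled endpoint-wise.
    """
    if velocity_km_per_day < 0:
        raise ValueError(f"negative velocity: {velocity_km_per_day}")
    if isinstance(half_life_days, (tuple, list)):
        lo, hi = half_life_days
        if lo < 0 or hi < 0:
            raise ValueError("negative half-life")
        return (lo * velocity_km_per_day, hi * velocity_km_per_day)
    if half_life_days < 0:
        raise ValueError(f"negative half-life: {half_life_days}")
    return half_life_days * velocity_km_per_day


_TREATMENT_ORDER = [(12.0, "dark"), (20.0, "dark"), (20.0, "diel")]


def _treatment_sort_key(t: TreatmentLabel):
    try:
        rank = _TREATMENT_ORDER.index((float(t.temperature_c), t.light))
    except ValueError:
        rank = len(_TREATMENT_ORDER)
    return (rank, t.temperature_c, t.light)


def summarize_experiment(
    records: Iterable[SurvivalRecord],
    velocity_km_per_day: float = DEFAULT_VELOCITY_KM_PER_DAY,
    ci_level: float = 0.95,
    allow_pooling_experiments: bool = False,
) -> SurvivalReport:
    """Per-replicate mortality/half-life/drift rows plus a pooled row.

    Replicate rows carry point estimates only; the pooled row (deaths and
    exposure summed over all replicates, not rates averaged) carries the
    Poisson CI for the rate mapped through ``H = ln2/b`` (order-reversed,
    the map being decreasing) and ``D = H * V``.  Rows are ordered 12C dark,
    20C dark, 20C diel, then pooled.
    """
    records = list(records)
    _validate_records(records)
    experiment_ids = {r.experiment_id for r in records}
    if len(experiment_ids) > 1 and not allow_pooling_experiments:
        raise ValueError(
            f"records span multiple experiments {sorted(experiment_ids)}; "
            "pass allow_pooling_experiments=True to pool them"
        )

    groups: dict[tuple[TreatmentLabel, str], list[SurvivalRecord]] = {}
    for r in records:
        groups.setdefault((r.treatment, r.replicate_id), []).append(r)

    rows = []
    for (treatment, replicate_id) in sorted(
        groups, key=lambda k: (_treatment_sort_key(k[0]), str(k[1]))
    ):
        grp = groups[(treatment, replicate_id)]
        deaths = sum(1 for r in grp if r.died)
        exposure = compute_exposure(grp)
        rate = deaths / exposure if exposure > 0 else math.nan
        h = half_life(rate) if rate > 0 else math.inf
        rows.append(
            {
                "treatment": str(treatment),
                "replicate": replicate_id,
                "n_initial": len(grp),
                "deaths": deaths,
                "exposure_days": exposure,
                "rate_b": rate,
                "half_life_days": h,
                "drift_km": dispersal_distance(h, velocity_km_per_day)
                if math.isfinite(h)
                else math.inf,
                "ci_low": math.nan,
                "ci_high": math.nan,
                "half_life_low": math.nan,
                "half_life_high": math.nan,
            }
        )

    pooled = estimate_mortality(records, ci_level=ci_level)
    pooled_h = half_life(pooled.rate_b) if pooled.rate_b > 0 else math.inf
    # b -> ln2/b is decreasing, so the rate CI maps to (ln2/hi, ln2/lo).
    h_low = half_life(pooled.ci_high) if pooled.ci_high > 0 else math.inf
    h_high = half_life(pooled.ci_low) if pooled.ci_low > 0 else math.inf
    rows.append(
        {
            "treatment": "pooled",
            "replicate": "",
            "n_initial": len(records),
            "deaths": pooled.deaths,
            "exposure_days": pooled.exposure,
            "rate_b": pooled.rate_b,
            "half_life_days": pooled_h,
            "drift_km": dispersal_distance(pooled_h, velocity_km_per_day)
            if math.isfinite(pooled_h)
            else math.inf,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "half_life_low": h_low,
            "half_life_high": h_high,
        }
    )
    table = pd.DataFrame(rows)
    return SurvivalReport(table=table, velocity_km_per_day=velocity_km_per_day, ci_level=ci_level)
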