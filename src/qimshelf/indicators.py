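"""Spoilage-indicator engine: limit rules, limit-crossing days, biogenic-amine
quality classes, and correlation of indicators with the sensory QI.

Microbial counts (log CFU/g), total volatile basic nitrogen (TVB-N,
mg N/100 g), lipid-oxidation TBARS (mg MDA/kg) and biogenic amines (mg/kg)
each carry an acceptability threshold from the predictive-microbiology and
seafood-quality literature; the engine detects when a stored-fish series
first violates its rule, both on the raw observations (discrete) and on a
fitted trend line (continuous).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import LinearFit, fit_line


class IndicatorError(ValueError):
    pass


class Direction(str, Enum):
    AT_OR_ABOVE = "at_or_above"
    ABOVE = "above"
    AT_OR_BELOW = "at_or_below"


@dataclass(frozen=True)
class IndicatorSeries:
    """A named time series of one spoilage indicator over storage days."""

    name: str
    units: str
    observations: tuple[tuple[float, float], ...]  # (day, value), days increasing

    def __post_init__(self) -> None:
        if not self.units:
            raise IndicatorError(f"series {self.name!r}: units must be non-empty")
        days = [d for d, _ in self.observations]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise IndicatorError(f"series {self.name!r}: days must strictly increase")
        if not all(np.isfinite(v) for _, v in self.observations):
            raise IndicatorError(f"series {self.name!r}: non-finite value")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(d for d, _ in self.observations)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.observations)

    def fit(self) -> LinearFit:
        return fit_line(self.days, self.values)


@dataclass(frozen=True)
class LimitRule:
    """Acceptability rule: an indicator violates it when its value satisfies
    `direction` relative to `threshold`."""

    indicator: str
    threshold: float
    direction: Direction = Direction.AT_OR_ABOVE
    source: str = ""
    units: str | None = None
    #: rejection rules feed the shelf-life decision; informational rules
    #: (rejection=False, e.g. the putrescine quality band) are reported as
    #: crossings only
    rejection: bool = True

    def satisfied(self, value: float) -> bool:
        if self.direction is Direction.AT_OR_ABOVE:
            return value >= self.threshold
        if self.direction is Direction.ABOVE:
            return value > self.threshold
        return value <= self.threshold


#: Default acceptability limits for ice-stored fish. Microbial plate counts
#: use the ICMSF refrigerated-fish ceiling of 7 log CFU/g (reaching it counts
#: as rejection); TVB-N uses the stricter 30 mg N/100 g of the two customary
#: limits (30 and 35); TBARS uses 5 mg MDA/kg, the low end of the 5-8 range
#: cited for sensory acceptance; putrescine above 20 mg/kg marks low quality.
DEFAULT_LIMITS: tuple[LimitRule, ...] = (
    LimitRule("mesophilic", 7.0, Direction.AT_OR_ABOVE, "ICMSF plate-count limit", "log CFU/g"),
    LimitRule("psychrotrophic", 7.0, Direction.AT_OR_ABOVE, "ICMSF plate-count limit", "log CFU/g"),
    LimitRule("tvb_n", 30.0, Direction.AT_OR_ABOVE, "TVB-N limit, stricter of 30/35", "mg N/100 g"),
    LimitRule("tbars", 5.0, Direction.AT_OR_ABOVE, "TBARS sensory-acceptance low bound", "mg MDA/kg"),
    LimitRule("putrescine", 20.0, Direction.ABOVE, "putrescine low-quality bound",
              "mg/kg", rejection=False),
)


def first_crossing_day(series: IndicatorSeries, rule: LimitRule) -> float | None:
    """Smallest observation day whose value satisfies the rule; None if the
    series never does. Fails if series and rule declare different units."""
    if not series.observations:
        raise IndicatorError("empty series")
    if rule.units is not None and rule.units != series.units:
        raise IndicatorError(
            f"units mismatch: series {series.name!r} in {series.units!r}, "
            f"rule expects {rule.units!r}"
        )
    for day, value in series.observations:
        if rule.satisfied(value):
            return day
    return None


def crossing_day_continuous(fit: LinearFit, rule: LimitRule) -> float | None:
    """Day at which a fitted straight trend crosses the rule threshold.

    Returns 0.0 when the rule already holds at day 0, None when the trend
    moves away from the threshold (or the slope is zero).
    """
    if rule.satisfied(fit.intercept):  # already violated at day 0
        return 0.0
    if fit.slope == 0.0:
        return None
    t = (rule.threshold - fit.intercept) / fit.slope
    if t < 0:
        return None
    moving_up = fit.slope > 0
    wants_up = rule.direction in (Direction.AT_OR_ABOVE, Direction.ABOVE)
    return t if moving_up == wants_up else None


class AmineQuality(str, Enum):
    FRESH = "fresh"
    INTERMEDIATE = "intermediate"
    LOW_QUALITY = "low_quality"


def classify_amine(value: float, kind: str = "putrescine") -> AmineQuality:
    """Quality class from a putrescine level (mg/kg): below 10 is fresh
    high-quality fish, above 20 is low quality, boundaries inclusive fall in
    the intermediate band."""
    if kind != "putrescine":
        raise IndicatorError(f"no quality bands defined for amine {kind!r}")
    if value < 0:
        raise IndicatorError("amine concentration cannot be negative")
    if value < 10.0:
        return AmineQuality.FRESH
    if value > 20.0:
        return AmineQuality.LOW_QUALITY
    return AmineQuality.INTERMEDIATE


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation; fails on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise IndicatorError("need two equal-length series of >= 3 values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise IndicatorError("undefined correlation: constant input")
    return float(stats.pearsonr(a, b).statistic)


def correlation_matrix(
    panel_qi: Sequence, indicators: Iterable[IndicatorSeries]
) -> pd.DataFrame:
    """Pearson correlation matrix of panel QI against each indicator.

    Series are aligned by exact inner join on day values (no interpolation:
    study designs share one sampling grid). Requires >= 3 common days.
    """
    cols = {"qi": pd.Series({p.storage_day: p.qi_mean for p in panel_qi})}
    for s in indicators:
        cols[s.name] = pd.Series(dict(s.observations))
    df = pd.DataFrame(cols).dropna()
    if len(df) < 3:
        raise IndicatorError(
            f"only {len(df)} common days across series; need at least 3"
        )
    return df.corr(method="pearson")


# ---------------------------------------------------------------------------
# Indicator CSV dialect: `day,indicator,value,units`


def read_indicator_csv(path: str | Path) -> list[IndicatorSeries]:
    df = pd.read_csv(path)
    missing = {"day", "indicator", "value", "units"} - set(df.columns)
    if missing:
        raise IndicatorError(f"indicator CSV missing columns {sorted(missing)}")
    out = []
    for name, grp in df.groupby("indicator", sort=True):
        grp = grp.sort_values("day")
        units = grp["units"].iloc[0]
        out.append(
            IndicatorSeries(
                name=str(name),
                units=str(units),
                observations=tuple(
                    (float(d), float(v)) for d, v in zip(grp["day"], grp["value"])
                ),
            )
        )
    return out


def write_indicator_csv(series: Iterable[IndicatorSeries], path: str | Path) -> None:
    rows = [
        (day, s.name, value, s.units)
        for s in series
        for day, value in s.observations
    ]
    pd.DataFrame(rows, columns=["day", "indicator", "value", "units"]).to_csv(
        path, index=False
    )
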