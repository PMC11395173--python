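"""Synthetic spoilage-study generator: panel score sheets and spoilage
indicator series with the statistical structure the analysis pipeline assumes.

The generator emulates an ice-storage shelf-life assay of whole fish sampled
on a fixed day grid. A latent freshness score grows linearly with days in ice
(slope ~0.93 demerit/day for the winter lot of the bundled protocol); each
referee observes it with Gaussian noise and fills a complete demerit sheet
whose integer scores sum to the discretized latent score. Spoilage indicators
follow the trend shapes typical of ice-stored fish: log-linear bacterial
growth (mesophilic, psychrotrophic), linear TVB-N and TBARS accumulation,
and near-exponential putrescine build-up.

Default trajectories are anchored so that the noiseless simulator reproduces
the study conditions exactly: QI 18 at day 18, mesophilic 5.68 log CFU/g at
day 18, TVB-N below its 30 mg N/100 g limit across the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import _round_half_away
from .indicators import IndicatorSeries
from .protocol import Assessment, QimProtocol, max_qi


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class QiLine:
    slope: float  # demerit points per day
    intercept: float  # demerit points at day 0

    def __call__(self, day: float) -> float:
        return self.slope * day + self.intercept


@dataclass(frozen=True)
class IndicatorModel:
    """Generating model for one indicator.

    kind:
      - "linear" / "loglinear": value = slope*day + intercept + N(0, noise_sd)
        (loglinear marks that the response is already on a log10 scale,
        e.g. plate counts in log CFU/g; the arithmetic is the same)
      - "exponential": value = exp(slope*day + intercept) * exp(N(0, noise_sd))
        (multiplicative log-normal noise)
    """

    kind: str
    slope: float
    intercept: float
    noise_sd: float
    units: str

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "loglinear", "exponential"):
            raise SimulationError(f"unknown indicator model kind {self.kind!r}")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")

    def mean(self, day: float) -> float:
        """Noiseless trajectory value at a day."""
        lin = self.slope * day + self.intercept
        return math.exp(lin) if self.kind == "exponential" else lin


# Putrescine kinetics: log-linear OLS fit to a published ice-storage series
# (mg/kg at days 1,4,8,11,14), frozen at implementation time; natural-log scale.
PUTRESCINE_LOG_SLOPE = 0.3364892045549073
PUTRESCINE_LOG_INTERCEPT = 0.8839738726333981


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated shelf-life assay.

    Defaults reproduce the reference ice-storage study design: sampling on
    days {1,4,8,11,14,18}, 4 referees x 3 fish per day, the winter-lot QI
    calibration line, and the published indicator trend lines (microbial and
    TVB-N intercepts sign-corrected to positive so the noiseless trajectories
    pass through the study's reported endpoints; the source prints them with
    a minus sign).
    """

    sampling_days: tuple[float, ...] = (1, 4, 8, 11, 14, 18)
    n_referees: int = 4
    n_fish_per_day: int = 3
    qi_line: QiLine = QiLine(slope=0.9281, intercept=1.3378)
    referee_noise_sd: float = 0.5  # latent demerit points per sheet
    indicator_models: dict[str, IndicatorModel] = field(
        default_factory=lambda: {
            "mesophilic": IndicatorModel("loglinear", 0.1229, 3.4642, 0.15, "log CFU/g"),
            "psychrotrophic": IndicatorModel("loglinear", 0.1593, 4.5679, 0.15, "log CFU/g"),
            "tvb_n": IndicatorModel("linear", 0.9577, 8.0379, 1.0, "mg N/100 g"),
            "tbars": IndicatorModel("linear", 0.0034, 0.2253, 0.01, "mg MDA/kg"),
            "putrescine": IndicatorModel(
                "exponential", PUTRESCINE_LOG_SLOPE, PUTRESCINE_LOG_INTERCEPT, 0.3, "mg/kg"
            ),
        }
    )
    lot: str = "lot4"
    seed: int = 0

    def __post_init__(self) -> None:
        days = self.sampling_days
        if any(b <= a for a, b in zip(days, days[1:])) or any(d < 0 for d in days):
            raise SimulationError("sampling_days must be strictly increasing and >= 0")
        if self.n_referees < 1 or self.n_fish_per_day < 1:
            raise SimulationError("n_referees and n_fish_per_day must be >= 1")
        if self.referee_noise_sd < 0:
            raise SimulationError("referee_noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedStudy:
    assessments: tuple[Assessment, ...]
    indicator_series: tuple[IndicatorSeries, ...]
    truth: dict


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions (see SimulationConfig)."""
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# Seeding: one root seed; children are spawned from its SeedSequence in a
# fixed order (panel first, then indicators in sorted name order) so panel
# and indicator noise are independent, reproducible streams.


def _child_rngs(config: SimulationConfig) -> tuple[np.random.Generator, dict[str, np.random.Generator]]:
    names = sorted(config.indicator_models)
    children = np.random.SeedSequence(config.seed).spawn(1 + len(names))
    panel = np.random.default_rng(children[0])
    per_indicator = {
        name: np.random.default_rng(child)
        for name, child in zip(names, children[1:])
    }
    return panel, per_indicator


def _apportion(total: int, caps: list[int]) -> list[int]:
    """Split an integer demerit total across parameters proportionally to
    their maxima (largest-remainder method, capped per parameter).

    Sum-preserving by construction, which keeps the noiseless sheet QI equal
    to the rounded latent score; ties in the fractional remainders break by
    protocol order.
    """
    weight = sum(caps)
    if total > weight:
        raise SimulationError(f"total {total} exceeds protocol maximum {weight}")
    quotas = [total * c / weight for c in caps]
    base = [min(int(math.floor(q)), c) for q, c in zip(quotas, caps)]
    left = total - sum(base)
    order = sorted(
        range(len(caps)), key=lambda j: (-(quotas[j] - math.floor(quotas[j])), j)
    )
    shares = list(base)
    while left > 0:
        for j in order:
            if left == 0:
                break
            if shares[j] < caps[j]:
                shares[j] += 1
                left -= 1
    return shares


def simulate_panel_scores(
    config: SimulationConfig, protocol: QimProtocol
) -> list[Assessment]:
    """Generate complete demerit sheets for every day x fish x referee.

    Each sheet draws one latent freshness score from the QI line plus
    Gaussian referee noise, rounds it to an integer total (half away from
    zero, clamped to [0, protocol maximum]) and apportions the total over
    the protocol parameters. With referee_noise_sd = 0 the sheet QI equals
    the rounded line value exactly.
    """
    rng, _ = _child_rngs(config)
    params = protocol.parameters
    caps = [p.max_demerit for p in params]
    top = max_qi(protocol)
    out: list[Assessment] = []
    for day in config.sampling_days:
        for fish in range(1, config.n_fish_per_day + 1):
            for ref in range(1, config.n_referees + 1):
                latent = config.qi_line(day)
                if config.referee_noise_sd > 0:
                    latent += rng.normal(0.0, config.referee_noise_sd)
                total = max(0, min(top, _round_half_away(latent)))
                shares = _apportion(total, caps)
                out.append(
                    Assessment(
                        lot=config.lot,
                        fish_id=f"F{fish}",
                        referee_id=f"R{ref}",
                        storage_day=float(day),
                        scores={
                            p.parameter_name: s for p, s in zip(params, shares)
                        },
                    )
                )
    return out


def simulate_indicators(config: SimulationConfig) -> list[IndicatorSeries]:
    """Generate one series per configured indicator model over the sampling
    grid. With noise_sd = 0 the values equal the generating function exactly,
    independent of the seed."""
    _, rngs = _child_rngs(config)
    out: list[IndicatorSeries] = []
    for name in sorted(config.indicator_models):
        model = config.indicator_models[name]
        rng = rngs[name]
        obs = []
        for day in config.sampling_days:
            value = model.mean(day)
            if model.noise_sd > 0:
                eps = rng.normal(0.0, model.noise_sd)
                value = value * math.exp(eps) if model.kind == "exponential" else value + eps
            obs.append((float(day), float(value)))
        out.append(IndicatorSeries(name=name, units=model.units, observations=tuple(obs)))
    return out


def simulate_study(config: SimulationConfig, protocol: QimProtocol) -> SimulatedStudy:
    """Full synthetic assay: panel sheets + indicator series + generating truth."""
    return SimulatedStudy(
        assessments=tuple(simulate_panel_scores(config, protocol)),
        indicator_series=tuple(simulate_indicators(config)),
        truth=asdict(config),
    )
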