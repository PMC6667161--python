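"""Reported screening metrics from paired scenario results.

All formulas operate on the weighted national series produced by the
engine: annual and cumulative mortality reduction (overall and by smoker
type), deaths avoided, life-years gained, life-years per death prevented,
screens, and the screening-eligible share of the population.  Deaths are
attributed to the calendar year of death, with smoker type evaluated in
the death year; percentages are reported to two decimals like the source
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ScenarioResult
from .smoking import CURRENT, FORMER, NEVER

UNDEFINED = np.nan


def annual_mortality_reduction(screen_deaths, noscreen_deaths) -> np.ndarray:
    """Percent reduction per year: 100 * (noscreen - screen) / noscreen.

    Years with a zero baseline are returned as NaN (undefined marker) and
    excluded from cumulative series.
    """
    screen = np.asarray(screen_deaths, dtype=float)
    base = np.asarray(noscreen_deaths, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (base - screen) / base
    return np.where(base > 0, out, UNDEFINED)


def cumulative_mortality_reduction(screen_deaths, noscreen_deaths,
                                   through_index: int | None = None) -> float:
    """Percent reduction over the window: 100 * (sum N - sum S) / sum N."""
    screen = np.asarray(screen_deaths, dtype=float)[:_end(through_index, screen_deaths)]
    base = np.asarray(noscreen_deaths, dtype=float)[:_end(through_index, noscreen_deaths)]
    if screen.size == 0 or base.size == 0:
        raise ValueError("empty window")
    total = base.sum()
    return float(100.0 * (total - screen.sum()) / total) if total > 0 else UNDEFINED


def _end(through_index, arr):
    return None if through_index is None else through_index + 1


def life_years_gained(screen_py, noscreen_py) -> float:
    """Cumulative population difference, screening minus no screening."""
    screen_py = np.asarray(screen_py, dtype=float)
    noscreen_py = np.asarray(noscreen_py, dtype=float)
    if screen_py.shape != noscreen_py.shape:
        raise ValueError("person-years series are misaligned")
    return float(screen_py.sum() - noscreen_py.sum())


def ly_per_death_prevented(life_years: float, deaths_prevented: float) -> float:
    """Life-years saved per lung-cancer death prevented, 2-dp reporting."""
    if deaths_prevented <= 0:
        raise ValueError("deaths_prevented must be positive")
    return round(life_years / deaths_prevented, 2)


def eligibility_fraction(screens: float, adult_population: float) -> float:
    """Percent of the (adult, by default) population screened in a year."""
    if adult_population <= 0:
        raise ValueError("population denominator must be positive")
    return 100.0 * screens / adult_population


@dataclass(frozen=True)
class OutcomeReport:
    """Everything reported for one country's paired runs, 2020-2040."""

    country: str
    scenario: str
    years: np.ndarray
    annual_reduction_pct: np.ndarray            # per year
    cumulative_reduction_pct: np.ndarray        # through each year
    cumulative_reduction_total: float
    reduction_by_type: dict                     # label -> percent
    deaths_avoided_by_type: dict                # label -> weighted count
    deaths_avoided_total: float
    life_years_gained: float
    ly_per_death_prevented: float
    screens_per_year: np.ndarray
    eligibility_fraction_pct: np.ndarray

    def summary(self) -> dict:
        return {
            "country": self.country,
            "scenario": self.scenario,
            "cumulative_mortality_reduction_pct": round(self.cumulative_reduction_total, 2),
            "deaths_avoided": round(self.deaths_avoided_total),
            "life_years_gained": round(self.life_years_gained),
            "ly_per_death_prevented": self.ly_per_death_prevented,
            "reduction_by_smoker_type_pct": {k: round(v, 2)
                                             for k, v in self.reduction_by_type.items()},
        }


def build_report(screen: ScenarioResult, noscreen: ScenarioResult,
                 total_population_denominator: bool = False) -> OutcomeReport:
    """Compute every reported metric from one paired (screen, none) run.

    ``total_population_denominator`` switches the eligibility fraction from
    the adult (18+) denominator to the total national population, the
    variant used when cross-checking against printed total-population
    anchors.
    """
    for name in ("country", "scenario", "seed"):
        if getattr(screen, name) != getattr(noscreen, name):
            raise ValueError(f"paired results disagree on {name}")
    s_total = screen.total_lc_deaths
    n_total = noscreen.total_lc_deaths
    annual = annual_mortality_reduction(s_total, n_total)
    cum = np.array([cumulative_mortality_reduction(s_total, n_total, i)
                    for i in range(len(screen.years))])
    by_type, avoided = {}, {}
    for t, label in ((CURRENT, "current"), (FORMER, "former"), (NEVER, "never")):
        base = noscreen.lc_deaths[:, t].sum()
        avoided[label] = float(base - screen.lc_deaths[:, t].sum())
        by_type[label] = float(100.0 * avoided[label] / base) if base > 0 else UNDEFINED
    deaths_avoided = float(n_total.sum() - s_total.sum())
    lyg = life_years_gained(screen.person_years, noscreen.person_years)
    if total_population_denominator:
        denom = noscreen.person_years  # total national population variant
    else:
        denom = noscreen.adult_population
    elig = 100.0 * screen.screens / denom
    return OutcomeReport(
        country=screen.country, scenario=screen.scenario, years=screen.years,
        annual_reduction_pct=annual, cumulative_reduction_pct=cum,
        cumulative_reduction_total=float(cum[-1]), reduction_by_type=by_type,
        deaths_avoided_by_type=avoided, deaths_avoided_total=deaths_avoided,
        life_years_gained=lyg,
        ly_per_death_prevented=(ly_per_death_prevented(lyg, deaths_avoided)
                                if deaths_avoided > 0 else UNDEFINED),
        screens_per_year=screen.screens, eligibility_fraction_pct=elig)
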