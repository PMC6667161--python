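"""Multiple-birth-cohort scenario runner with paired common random numbers.

Birth cohorts 1910-2022 are simulated from birth so that everyone alive
between the calibration era and the 2040 horizon is represented.  Every
stochastic process draws one uniform per person from a purpose-keyed
stream seeded by ``(seed, purpose)``, and event ages are obtained by
inverting the cumulative discrete hazards -- exactly equivalent to running
the annual Bernoulli transitions, but with no time loop.  Because the
draws depend only on ``(seed, purpose, person index)``, a screening and a
no-screening run at the same seed share every draw: the scenario
difference isolates the policy effect (common random numbers), and a
screen-detected person's lung-cancer death clock still starts at their
counterfactual clinical surfacing year, so the only pathway for benefit is
the stage shift.

Population scale: per-(cohort, sex) weights anchored on the first
projection year's pyramid, with a deterministic per-year factor aligning
the model-implied total (including post-2022 virtual child cohorts) to the
linearly interpolated national projections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import demog
from .config import MAX_AGE, SEXES, CountryConfig, PopulationProjection
from .nathist import onset_hazard
from .screening import ScreeningPolicy, eligibility_window
from .smoking import (CURRENT, FORMER, NEVER, ORIGINAL, SMOKER_TYPE_LABELS,
                      SensitivityScenario, SmokingHistory, simulate_smoking,
                      smoker_type)

RESULT_YEARS = np.arange(2020, 2041)

# purpose keys for the per-person uniform streams
_P_OC, _P_ONSET, _P_SOJOURN, _P_STAGE, _P_DETECT, _P_LCDEATH = 201, 202, 203, 204, 205, 206
_P_CURE = 207

_INF = np.inf


def interpolate_population(proj: PopulationProjection, year: int) -> float:
    """Total national population, linear between the printed anchors."""
    years = sorted(proj.anchors)
    if not years[0] <= year <= years[-1]:
        raise ValueError(f"year {year} outside anchor range [{years[0]}, {years[-1]}]")
    return float(np.interp(year, years, [proj.anchors[y] for y in years]))


#: Stratified-oversampling factor for the birth cohorts that carry nearly
#: all 2020-2040 lung-cancer deaths; per-cohort weights compensate exactly,
#: so tallies stay unbiased while death statistics gain precision.
_DEATH_COHORTS = (1925, 1990)
_DEATH_COHORT_BOOST = 4.0


def _allocate_cohorts(cfg: CountryConfig, n_persons: int,
                      birth_range: tuple[int, int] | None = None,
                      cohort_boost: tuple[tuple[int, int], float] | None = None):
    """Deterministic largest-remainder allocation of persons to (cohort, sex)."""
    sizes = demog.newborn_cohort_sizes(cfg)
    cohorts = demog.cohort_years()
    if birth_range is not None:
        sizes = np.where(((cohorts >= birth_range[0]) & (cohorts <= birth_range[1]))[:, None],
                         sizes, 0.0)
    boost = np.where((cohorts >= _DEATH_COHORTS[0]) & (cohorts <= _DEATH_COHORTS[1]),
                     _DEATH_COHORT_BOOST, 1.0)[:, None]
    if cohort_boost is not None:
        (lo, hi), factor = cohort_boost
        boost = boost * np.where((cohorts >= lo) & (cohorts <= hi),
                                 factor, 1.0)[:, None]
    intensity = sizes * boost  # sampling intensity only; weights use sizes
    quota = intensity / intensity.sum() * n_persons
    counts = np.floor(quota).astype(int)
    short = n_persons - counts.sum()
    if short > 0:
        frac = (quota - counts).ravel()
        counts.ravel()[np.argsort(-frac, kind="stable")[:short]] += 1
    birth, sex, weight = [], [], []
    for i, c in enumerate(cohorts):
        for j in range(2):
            k = counts[i, j]
            if k == 0:
                continue
            birth.append(np.full(k, c))
            sex.append(np.full(k, j, dtype=np.int8))
            weight.append(np.full(k, sizes[i, j] / k))
    return (np.concatenate(birth), np.concatenate(sex), np.concatenate(weight))


@dataclass
class PopulationBase:
    """Policy-independent part of a simulated population (shared by arms)."""

    cfg: CountryConfig
    scenario: SensitivityScenario
    seed: int
    birth: np.ndarray
    sex: np.ndarray
    weight: np.ndarray
    history: SmokingHistory
    oc_year: np.ndarray        # calendar year of other-cause death
    onset_year: np.ndarray     # inf if cancer never starts
    t_clin: np.ndarray         # counterfactual clinical surfacing year; inf
    stage_u: np.ndarray
    detect_u: np.ndarray
    cure_u: np.ndarray
    lcdeath_u: np.ndarray

    def __len__(self) -> int:
        return self.birth.size


def build_population(cfg: CountryConfig, scenario: SensitivityScenario,
                     n_persons: int, seed: int,
                     peak_rate: dict | None = None,
                     with_cancer: bool = True,
                     birth_range: tuple[int, int] | None = None,
                     cohort_boost: tuple[tuple[int, int], float] | None = None,
                     ) -> PopulationBase:
    """Sample everything that does not depend on the screening policy.

    ``birth_range`` restricts the allocation to a band of birth cohorts
    (used to concentrate simulation effort on a trial-age cohort);
    ``cohort_boost`` oversamples a band (weights compensate), used when a
    contrast touches only a few cohorts, e.g. sensitivity scenarios.
    Weights remain nationally scaled either way.
    """
    if n_persons < 10_000:
        warnings.warn(f"n_persons={n_persons} is small; Monte Carlo noise will "
                      "dominate paired comparisons", RuntimeWarning, stacklevel=2)
    birth, sex, weight = _allocate_cohorts(cfg, n_persons, birth_range, cohort_boost)
    history = simulate_smoking(cfg, birth, sex, scenario, seed, peak_rate=peak_rate)
    n = birth.size

    def stream(purpose: int) -> np.ndarray:
        return np.random.default_rng([int(seed), purpose]).uniform(size=n)

    # other-cause death age: inverse of the accumulated per-person hazard.
    # Smokers carry a CPD-scaled excess, normalized by the cohort-average
    # multiplier so the population-level schedule stays the configured one;
    # everyone dies by age MAX_AGE + 1.
    from .smoking import mean_oc_multiplier, smoker_oc_rr
    e_oc = -np.log(stream(_P_OC))
    oc_age = np.full(n, MAX_AGE + 1.0)
    for j, sexname in enumerate(SEXES):
        rates = cfg.other_cause.rate_array(sexname, warn_clip=False)
        pr = (peak_rate[sexname] if peak_rate is not None
              else float(cfg.calibrated.initiation_peak_rate[sexname]))
        mbar = mean_oc_multiplier(cfg, sexname, pr)
        sel = np.flatnonzero(sex == j)
        init = history.init_age[sel]
        quit = history.quit_age[sel]
        excess = smoker_oc_rr(cfg, history.cpd[sel]) - 1.0
        mult = history.cpd_mult[sel]
        msy = history.mult_start_year
        hl = cfg.other_cause.quit_rr_halflife
        cum = np.zeros(sel.size)
        pending = np.ones(sel.size, dtype=bool)
        for a in range(MAX_AGE + 1):
            frac = np.where((init <= a) & (a < quit), 1.0,
                            np.where(quit <= a,
                                     0.5 ** (np.clip(a - quit, 0.0, None) / hl), 0.0))
            exc_a = excess * np.where(birth[sel] + a >= msy, mult, 1.0)
            h = np.clip(rates[a] * (1.0 + exc_a * frac) / mbar[a], 0.0, 1.0 - 1e-12)
            cum += -np.log1p(-h)
            hit = pending & (cum >= e_oc[sel])
            if hit.any():
                oc_age[sel[hit]] = a
                pending &= ~hit
            if not pending.any():
                break
    oc_year = birth + oc_age

    onset_year = np.full(n, _INF)
    t_clin = np.full(n, _INF)
    if with_cancer:
        if cfg.calibrated is None or cfg.calibrated.baseline_scale is None:
            raise ValueError("config has no calibrated natural history; "
                             "run calibrate_mortality first")
        params = cfg.natural_history
        e_onset = -np.log(stream(_P_ONSET))
        onset_age = np.full(n, _INF)
        for j, sexname in enumerate(SEXES):
            scale = float(cfg.calibrated.baseline_scale[sexname])
            sel = np.flatnonzero(sex == j)
            cum = np.zeros(sel.size)
            pending = np.ones(sel.size, dtype=bool)
            sub = SmokingHistory(birth[sel], sex[sel], history.init_age[sel],
                                 history.quit_age[sel], history.cpd[sel],
                                 history.cpd_mult[sel], history.mult_start_year)
            for a in range(20, MAX_AGE + 1):
                h = onset_hazard(params, scale, sub, float(a))
                cum += -np.log1p(-np.clip(h, 0.0, 1.0 - 1e-12))
                hit = pending & (cum >= e_onset[sel])
                if hit.any():
                    onset_age[sel[hit]] = a
                    pending &= ~hit
                if not pending.any():
                    break
        onset_year = birth + onset_age
        p_surface = 1.0 / params.sojourn_mean
        u = stream(_P_SOJOURN)
        sojourn = np.ceil(np.log(u) / math.log(1.0 - p_surface)) if p_surface < 1.0 \
            else np.ones(n)
        t_clin = onset_year + np.maximum(sojourn, 1.0)

    return PopulationBase(cfg=cfg, scenario=scenario, seed=int(seed),
                          birth=birth, sex=sex, weight=weight, history=history,
                          oc_year=oc_year, onset_year=onset_year, t_clin=t_clin,
                          stage_u=stream(_P_STAGE), detect_u=stream(_P_DETECT),
                          cure_u=stream(_P_CURE), lcdeath_u=stream(_P_LCDEATH))


def detection_and_death(base: PopulationBase,
                        opp_start: np.ndarray | None,
                        opp_end: np.ndarray | None,
                        sensitivity: float | None,
                        early_frac_screen: float | None):
    """Resolve detection mode, stage, and death for one arm.

    ``opp_start``/``opp_end`` bound the calendar years of screening
    opportunities per person (``None`` for a no-screening arm).  Screens can
    find disease from its onset year up to (and including) the year it
    would surface clinically; the lung-cancer death clock starts at the
    counterfactual surfacing year in both arms, with the stage-specific
    annual death probability.  Returns ``(det_year, early, lc_year,
    death_year, lc_death)`` arrays.
    """
    params = base.cfg.natural_history
    n = len(base)
    det_year = np.full(n, _INF)
    if opp_start is not None:
        lo = np.maximum(opp_start, base.onset_year)
        hi = np.minimum.reduce([opp_end, base.t_clin, base.oc_year - 1.0])
        if sensitivity >= 1.0:
            g = np.ones(n)
        else:
            g = np.ceil(np.log(base.detect_u) / math.log(1.0 - sensitivity))
        cand = lo + g - 1.0
        det_year = np.where(cand <= hi, cand, _INF)
    screen_detected = np.isfinite(det_year)
    frac = np.where(screen_detected,
                    early_frac_screen if early_frac_screen is not None else np.nan,
                    params.early_frac_clinical)
    early = base.stage_u < frac
    # mixture-cure survival: a stage-dependent fraction never dies of the
    # cancer; the rest die at the stage-specific annual rate.  Shared
    # uniforms make both layers monotone in the stage shift.
    cured = base.cure_u < np.where(early, params.cure_early, params.cure_late)
    q = np.where(early, params.q_early, params.q_late)
    with np.errstate(divide="ignore"):
        delay = np.where(q >= 1.0, 0.0, np.floor(np.log(base.lcdeath_u) / np.log(1.0 - q)))
        delay = np.where(q <= 0.0, _INF, delay)
    delay = np.where(cured, _INF, delay)
    lc_year = base.t_clin + delay
    death_year = np.minimum(base.oc_year, lc_year)
    lc_death = lc_year < base.oc_year  # same-year ties go to other causes
    return det_year, early, lc_year, death_year, lc_death


@dataclass
class ScenarioResult:
    """Per-calendar-year national outputs for one scenario arm, 2020-2040."""

    country: str
    scenario: str
    screened: bool
    seed: int
    n_persons: int
    years: np.ndarray                       # 2020..2040
    lc_deaths: np.ndarray                   # (21, 3): never/current/former, weighted
    screens: np.ndarray                     # (21,) weighted
    person_years: np.ndarray                # (21,) weighted alive persons
    adult_population: np.ndarray            # (21,) weighted alive aged 18+

    def __post_init__(self) -> None:
        if not np.array_equal(self.years, RESULT_YEARS):
            raise ValueError("results must cover calendar years 2020-2040 exactly")
        for name in ("lc_deaths", "screens", "person_years"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} contains negative counts")

    @property
    def total_lc_deaths(self) -> np.ndarray:
        return self.lc_deaths.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, y in enumerate(self.years):
            for t, label in SMOKER_TYPE_LABELS.items():
                rows.append({"year": int(y), "smoker_type": label,
                             "deaths": self.lc_deaths[i, t],
                             "screens": self.screens[i] if t == NEVER else np.nan,
                             "person_years": self.person_years[i] if t == NEVER else np.nan})
        return pd.DataFrame(rows)


def _year_scale(cfg: CountryConfig) -> np.ndarray:
    """Deterministic factor aligning model totals to interpolated anchors."""
    return np.array([interpolate_population(cfg.population, int(y))
                     / demog.expected_total_population(cfg, int(y))
                     for y in RESULT_YEARS])


def tally(base: PopulationBase, policy: ScreeningPolicy | None,
          det_year, lc_year, death_year, lc_death) -> ScenarioResult:
    w = base.weight
    scale = _year_scale(base.cfg)
    deaths = np.zeros((RESULT_YEARS.size, 3))
    screens = np.zeros(RESULT_YEARS.size)
    py = np.zeros(RESULT_YEARS.size)
    adults = np.zeros(RESULT_YEARS.size)
    if policy is not None:
        e_start, e_end = eligibility_window(base.history, policy)
        pool_end = np.minimum.reduce([e_end, base.t_clin, np.minimum(det_year, _INF)])
    for i, y in enumerate(RESULT_YEARS):
        age = y - base.birth
        alive = (age >= 0) & (y < death_year)
        died_lc = lc_death & (death_year == y)
        if died_lc.any():
            stype = smoker_type(base.history, int(y))
            for t in (NEVER, CURRENT, FORMER):
                deaths[i, t] = w[died_lc & (stype == t)].sum()
        py[i] = w[alive].sum()
        adults[i] = w[alive & (age >= 18)].sum()
        if policy is not None:
            screened = (e_start <= y) & (y <= pool_end) & (y < base.oc_year)
            screens[i] = w[screened].sum()
    return ScenarioResult(
        country=base.cfg.country, scenario=base.scenario.label,
        screened=policy is not None, seed=base.seed, n_persons=len(base),
        years=RESULT_YEARS.copy(), lc_deaths=deaths * scale[:, None],
        screens=screens * scale, person_years=py * scale,
        adult_population=adults * scale)


def run_arm(base: PopulationBase, policy: ScreeningPolicy | None) -> ScenarioResult:
    """One arm (screening or not) on an already-sampled population."""
    cal = base.cfg.calibrated
    if policy is None:
        det, early, lc_year, death_year, lc_death = detection_and_death(
            base, None, None, None, None)
    else:
        if cal is None or not cal.has_screening_benefit:
            raise ValueError("config has no calibrated screening benefit; "
                             "run calibrate_screening_benefit first")
        e_start, e_end = eligibility_window(base.history, policy)
        det, early, lc_year, death_year, lc_death = detection_and_death(
            base, e_start, e_end, cal.screen_sensitivity, cal.early_frac_screen)
    return tally(base, policy, det, lc_year, death_year, lc_death)


def run_scenario(cfg: CountryConfig, policy: ScreeningPolicy | None,
                 scenario: SensitivityScenario | str = ORIGINAL,
                 n_persons: int = 500_000, seed: int = 1,
                 cohort_boost=None) -> ScenarioResult:
    """Simulate one scenario arm from scratch (bitwise reproducible)."""
    from .smoking import apply_sensitivity
    cfg, scenario = apply_sensitivity(cfg, scenario)
    base = build_population(cfg, scenario, n_persons, seed,
                            cohort_boost=cohort_boost)
    return run_arm(base, policy)


def run_paired(cfg: CountryConfig, policy: ScreeningPolicy,
               scenario: SensitivityScenario | str = ORIGINAL,
               n_persons: int = 500_000, seed: int = 1,
               cohort_boost=None) -> tuple[ScenarioResult, ScenarioResult]:
    """(screening, no-screening) arms on one shared population sample."""
    from .smoking import apply_sensitivity
    cfg, scenario = apply_sensitivity(cfg, scenario)
    base = build_population(cfg, scenario, n_persons, seed,
                            cohort_boost=cohort_boost)
    return run_arm(base, policy), run_arm(base, None)


# -- calibration-facing helpers --------------------------------------------

def weighted_smoking_prevalence(base: PopulationBase, year: int, sex: str,
                                adult_age: int = 18) -> float:
    """Weighted current-smoking share of alive adults (other-cause survival)."""
    j = SEXES.index(sex)
    age = year - base.birth
    alive = (base.sex == j) & (age >= adult_age) & (age <= MAX_AGE) \
        & (year < base.oc_year)
    cur = smoker_type(base.history, year) == CURRENT
    den = base.weight[alive].sum()
    return float(base.weight[alive & cur].sum() / den) if den > 0 else 0.0


class SimulatedPopulation:
    """No-screening life histories with convenience accessors (used by
    synthetic-data target generation and the mortality calibration)."""

    def __init__(self, base: PopulationBase):
        self.base = base
        (_, _, self.lc_year, self.death_year, self.lc_death) = \
            detection_and_death(base, None, None, None, None)

    def weighted_lung_cancer_deaths(self, year: int, sex: str | None = None,
                                    half_window: int = 4) -> float:
        """Annual national lung-cancer deaths around ``year``.

        Estimated as the mean over the centered window ``year +/-
        half_window``: annual counts change slowly on that time scale while
        the window multiplies the effective number of simulated deaths, so
        this is a much tighter estimator of the single-year count than the
        raw one-year tally (``half_window=0``).
        """
        m = self.lc_death & (self.death_year >= year - half_window) \
            & (self.death_year <= year + half_window)
        if sex is not None:
            m &= self.base.sex == SEXES.index(sex)
        return float(self.base.weight[m].sum()) / (2 * half_window + 1)


def simulate_population(cfg: CountryConfig, scenario: SensitivityScenario,
                        n_persons: int, seed: int) -> SimulatedPopulation:
    base = build_population(cfg, scenario, n_persons, seed)
    return SimulatedPopulation(base)
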