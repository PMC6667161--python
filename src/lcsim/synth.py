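"""Synthetic fixtures: population pyramids, survey series, toy countries.

Everything here is a pure function of its arguments (including the seed),
so generated artifacts are reproducible and usable as test fixtures without
shipping data files.  The pyramids stand in for published single-year-of-age
population detail, which the national sources summarize only as totals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .config import (MAX_AGE, SEXES, CalibrationTargets, CessationSchedule,
                     ConfigError, CountryConfig, CpdDistribution,
                     InitiationModel, OtherCauseMortalityTable,
                     PopulationProjection)

#: Reference Gompertz-Makeham other-cause schedule (A, B, c) per sex; a
#: synthetic high-income life table with male excess mortality.
REFERENCE_MAKEHAM = {
    "male": (0.0008, 4.0e-05, 1.092),
    "female": (0.0005, 2.0e-05, 1.096),
}


def _age_density(scale: float, shape: float = 3.0) -> np.ndarray:
    ages = np.arange(MAX_AGE + 1, dtype=float)
    return np.exp(-((ages / scale) ** shape))


def _discrete_median(dens: np.ndarray) -> float:
    cdf = np.cumsum(dens) / dens.sum()
    return float(np.searchsorted(cdf, 0.5))


def pyramid_shares(median_age: float, seed: int, noise_sd: float = 0.02) -> np.ndarray:
    """Single-year-of-age population shares, shape (101, 2), summing to 1.

    The age density is a two-parameter stretched-exponential survival-like
    curve whose scale is solved so the discrete median age matches
    ``median_age``; a small seeded lognormal perturbation makes the pyramid
    survey-like rather than perfectly smooth.  The male fraction declines
    linearly with age (male excess mortality).
    """
    if not 15.0 <= median_age <= 60.0:
        raise ConfigError(f"median_age {median_age} outside supported range [15, 60]")
    lo, hi = 20.0, 150.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _discrete_median(_age_density(mid)) < median_age:
            lo = mid
        else:
            hi = mid
    dens = _age_density(0.5 * (lo + hi))
    rng = np.random.default_rng([int(seed), 9001])
    dens = dens * np.exp(rng.normal(0.0, noise_sd, size=dens.shape))
    male_frac = 0.512 - 0.112 * np.arange(MAX_AGE + 1) / MAX_AGE
    shares = np.stack([dens * male_frac, dens * (1.0 - male_frac)], axis=1)
    return shares / shares.sum()


def make_population_pyramid(total: int, median_age: float, seed: int) -> PopulationProjection:
    """A :class:`PopulationProjection` with flat anchors at ``total``."""
    if total <= 0:
        raise ValueError(f"total population must be positive, got {total}")
    return PopulationProjection(
        anchors={2020: int(total), 2030: int(total), 2040: int(total)},
        median_age=float(median_age), pyramid_seed=int(seed))


@dataclass(frozen=True)
class SyntheticSurveySeries:
    """Survey-like prevalence observations: (year, sex, prevalence, n_eff)."""

    entries: tuple[tuple[int, str, float, int], ...]

    def __post_init__(self) -> None:
        years = [y for y, *_ in self.entries]
        if sorted(set(years)) != years:
            raise ValueError("survey years must be strictly increasing")
        for _, _, p, _ in self.entries:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")


def make_survey_series(true_prevalence_curve, n_per_wave: int | None,
                       seed: int, sex: str = "male") -> SyntheticSurveySeries:
    """Binomial survey observations around a true prevalence curve.

    ``true_prevalence_curve`` maps calendar year to proportion.  With
    ``n_per_wave=None`` the observations equal the curve exactly (the
    no-noise / infinite-sample limit); otherwise each wave draws
    Binomial(n, p)/n.
    """
    if n_per_wave is not None and n_per_wave < 1:
        raise ValueError("n_per_wave must be >= 1")
    rng = np.random.default_rng([int(seed), 9002])
    entries = []
    for year in sorted(true_prevalence_curve):
        p = float(true_prevalence_curve[year])
        if n_per_wave is None:
            obs, n_eff = p, np.iinfo(np.int64).max
        else:
            obs = rng.binomial(n_per_wave, p) / n_per_wave
            n_eff = int(n_per_wave)
        entries.append((int(year), sex, float(obs), n_eff))
    return SyntheticSurveySeries(tuple(entries))


def make_toy_country(seed: int, n_target_sim: int = 200_000) -> CountryConfig:
    """A small, fully valid country with *known* true parameters.

    The returned config carries its true initiation peak rates and
    natural-history baseline scales in ``calibrated`` (the ground truth),
    while its calibration targets are set to the quantities that truth
    implies -- the prevalence targets from the closed-form smoking
    expectation, the mortality targets from one simulated run at
    ``n_target_sim`` persons.  Stripping ``calibrated`` and re-running the
    calibration should therefore recover the truth, which is what the
    parameter-recovery tests check.
    """
    rng = np.random.default_rng([int(seed), 9003])
    quit_adult = round(float(rng.uniform(0.015, 0.035)), 4)
    quit_old = round(quit_adult * 1.5, 4)
    cess = CessationSchedule((
        ("male", 20, 30, 0.0), ("male", 30, 66, quit_adult), ("male", 66, 101, quit_old),
        ("female", 20, 36, 0.0), ("female", 36, 101, quit_adult),
    ))
    cpd = CpdDistribution({
        "male": {"bins": [[1, 9, 0.3], [10, 19, 0.4], [20, None, 0.3]]},
        "female": {"bins": [[1, 9, 0.6], [10, 19, 0.3], [20, None, 0.1]]},
    })
    pop = PopulationProjection(
        anchors={2020: 10_000_000, 2030: 10_200_000, 2040: 10_300_000},
        median_age=round(float(rng.uniform(36.0, 46.0)), 1), pyramid_seed=int(seed))
    other = OtherCauseMortalityTable(REFERENCE_MAKEHAM,
                                     {"male": 1.0, "female": 1.0})
    initiation = InitiationModel(peak_age={"male": 19.0, "female": 20.0})
    true_peak = {"male": round(float(rng.uniform(0.08, 0.14)), 5),
                 "female": round(float(rng.uniform(0.015, 0.04)), 5)}
    # deliberately cancer-dense relative to any real country so that the
    # single-year death targets carry little Monte Carlo noise
    true_scale = {"male": round(float(rng.uniform(4e-3, 8e-3)), 8),
                  "female": round(float(rng.uniform(3e-3, 6e-3)), 8)}

    from .smoking import ORIGINAL, expected_smoking_prevalence

    draft = CountryConfig(
        country=f"toyland-{seed}", cessation=cess, cpd=cpd,
        targets=CalibrationTargets(2010, {"male": 0.5, "female": 0.5}, 2012,
                                   {"male": 1, "female": 1}),
        population=pop, other_cause=other, initiation=initiation)
    prev = {sex: round(float(expected_smoking_prevalence(draft, 2010, sex,
                                                         true_peak[sex], ORIGINAL)), 4)
            for sex in SEXES}

    cal_draft = draft.with_calibrated(initiation_peak_rate=true_peak,
                                      baseline_scale=true_scale,
                                      screen_sensitivity=0.9,
                                      early_frac_screen=0.85)
    from .engine import simulate_population  # deferred: engine builds on config

    sim = simulate_population(cal_draft, ORIGINAL, n_target_sim, seed=int(seed) % (2**31))
    deaths = {sex: max(1, int(round(sim.weighted_lung_cancer_deaths(2012, sex))))
              for sex in SEXES}
    targets = CalibrationTargets(2010, prev, 2012, deaths)
    return dataclasses.replace(cal_draft, targets=targets)
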