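"""Cohort demography shared by the smoking expectation and the engine.

The multiple-birth-cohort design simulates people born 1910-2022 from birth.
National scale enters through per-cohort weights anchored on the pyramid in
the first projection year (2020): the national newborn-equivalent size of a
cohort is the 2020 head count in its age group divided by other-cause
survival to that age.  Expected alive counts in any calendar year follow by
applying other-cause survival forward or backward from birth; lung-cancer
mortality (a <0.5% perturbation at population level) is ignored here and
enters only through the simulated life histories themselves.
"""

from __future__ import annotations

import numpy as np

from .config import MAX_AGE, SEXES, CountryConfig

COHORT_FIRST = 1910
COHORT_LAST = 2022
ANCHOR_YEAR = 2020


def cohort_years() -> np.ndarray:
    return np.arange(COHORT_FIRST, COHORT_LAST + 1)


def oc_survival_curve(cfg: CountryConfig, sex: str) -> np.ndarray:
    """P(alive through attained age a) under other-cause mortality.

    Index a gives survival of the hazards of ages 0..a inclusive — the
    probability of being counted alive *during* the year of attained age a
    (death removes a person from the year it strikes).
    """
    h = cfg.other_cause.rate_array(sex, warn_clip=False)
    return np.cumprod(1.0 - h)


def newborn_cohort_sizes(cfg: CountryConfig) -> np.ndarray:
    """National newborn-equivalent cohort sizes, shape (n_cohorts, 2).

    Cohorts born after the anchor year reuse the age-0 share (stable recent
    birth counts).
    """
    total = float(cfg.population.anchors[ANCHOR_YEAR])
    shares = cfg.population.age_sex_shares
    cohorts = cohort_years()
    out = np.empty((cohorts.size, 2))
    # cohorts very old (or extinct) at the anchor are badly conditioned
    # (tiny share / tiny survival); reuse the age-95 cohort's newborn size
    ref_age = 95
    for j, sex in enumerate(SEXES):
        surv = oc_survival_curve(cfg, sex)
        age_at_anchor = ANCHOR_YEAR - cohorts
        capped = np.clip(age_at_anchor, 0, ref_age)
        out[:, j] = total * shares[capped, j] / surv[capped]
        old = age_at_anchor > ref_age
        out[old, j] = total * shares[ref_age, j] / surv[ref_age]
    return out


def expected_alive(cfg: CountryConfig, year: int,
                   min_age: int = 0) -> np.ndarray:
    """Expected national alive count per (cohort, sex) in ``year``.

    Other-cause survival only; zero for cohorts not yet born or older than
    ``MAX_AGE``.
    """
    cohorts = cohort_years()
    ages = year - cohorts
    sizes = newborn_cohort_sizes(cfg)
    out = np.zeros_like(sizes)
    ok = (ages >= min_age) & (ages <= MAX_AGE)
    for j, sex in enumerate(SEXES):
        surv = oc_survival_curve(cfg, sex)
        out[ok, j] = sizes[ok, j] * surv[np.clip(ages[ok], 0, MAX_AGE)]
    return out


def expected_total_population(cfg: CountryConfig, year: int) -> float:
    """Model-implied total population including post-2022 virtual births.

    Cohorts born after the simulated range contribute analytically (they are
    children throughout the horizon and carry no smoking or cancer risk).
    """
    total = float(expected_alive(cfg, year).sum())
    shares = cfg.population.age_sex_shares
    anchor_total = float(cfg.population.anchors[ANCHOR_YEAR])
    for j, sex in enumerate(SEXES):
        surv = oc_survival_curve(cfg, sex)
        for birth in range(COHORT_LAST + 1, year + 1):
            age = year - birth
            if 0 <= age <= MAX_AGE:
                total += anchor_total * shares[0, j] * surv[age] / surv[0]
    return total
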