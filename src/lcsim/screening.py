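"""CMS-style LDCT screening eligibility and the annual screening process.

Default policy: current and former smokers aged 55-77 with at least 30
pack-years and no more than 15 years since quitting, screened annually from
2020 through 2040 at 100% adherence.  The published rule is quoted both as
"fewer than 15 years since quitting" and "no more than 15 years"; the
inclusive reading (<= 15) matches the CMS regulation and is the default,
with ``strict_quit_years`` switching to the strict inequality (the two
differ only at exactly 15 years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .smoking import CURRENT, FORMER, SmokingHistory, pack_years, smoker_type


@dataclass(frozen=True)
class ScreeningPolicy:
    min_age: int = 55
    max_age: int = 77            # inclusive
    min_pack_years: float = 30.0
    max_years_since_quit: float = 15.0
    start_year: int = 2020
    end_year: int = 2040         # inclusive
    adherence: float = 1.0
    interval_years: int = 1
    strict_quit_years: bool = False

    def __post_init__(self) -> None:
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be below max_age")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")


CMS = ScreeningPolicy()


def is_eligible(history: SmokingHistory, year: int,
                policy: ScreeningPolicy) -> np.ndarray:
    """Screening eligibility this year (alive, undiagnosed people assumed).

    True iff the calendar year is inside the program window, age is within
    [min_age, max_age], accumulated pack-years reach the threshold, and the
    person is a current smoker or quit recently enough.
    """
    age = year - history.birth_year
    if not policy.start_year <= year <= policy.end_year:
        return np.zeros(len(history), dtype=bool)
    ok_age = (age >= policy.min_age) & (age <= policy.max_age)
    ok_py = pack_years(history, age) >= policy.min_pack_years
    stype = smoker_type(history, year)
    since_quit = age - history.quit_age
    if policy.strict_quit_years:
        ok_quit = since_quit < policy.max_years_since_quit
    else:
        ok_quit = since_quit <= policy.max_years_since_quit
    ok_smoke = (stype == CURRENT) | ((stype == FORMER) & ok_quit)
    return ok_age & ok_py & ok_smoke


def eligibility_window(history: SmokingHistory,
                       policy: ScreeningPolicy) -> tuple[np.ndarray, np.ndarray]:
    """Per-person closed-form eligibility interval in calendar years.

    Every criterion is an interval in time -- the age band, the program
    window, pack-years once reached stay reached, and quit recency holds
    from cessation until the cutoff -- so their intersection is an interval
    ``[start, end]`` (empty when start > end).  Used by the event-driven
    engine; :func:`is_eligible` is the year-by-year oracle it is tested
    against.
    """
    birth = history.birth_year.astype(float)
    # first age at which accumulated pack-years reach the threshold,
    # accounting for the scenario's piecewise intensity switch
    need = policy.min_pack_years * 20.0  # cpd-years
    switch_age = float(history.mult_start_year) - birth
    c0 = history.cpd
    c1 = history.cpd * history.cpd_mult
    with np.errstate(divide="ignore", invalid="ignore"):
        pre_years = np.clip(switch_age - history.init_age, 0.0, None)
        pre_cpd_years = c0 * np.where(np.isfinite(history.init_age), pre_years, 0.0)
        before = history.init_age + np.ceil(need / c0)
        after = np.maximum(history.init_age, switch_age) \
            + np.ceil(np.clip(need - pre_cpd_years, 0.0, None) / c1)
        age_py = np.where(pre_cpd_years >= need, before, after)
    age_py = np.where(history.cpd > 0, age_py, np.inf)
    # pack-years stop accruing at cessation
    capped = pack_years(history, history.quit_age)
    age_py = np.where(np.isfinite(history.quit_age) & (capped < policy.min_pack_years),
                      np.inf, age_py)
    start = np.maximum.reduce([np.full_like(birth, policy.start_year),
                               birth + policy.min_age, birth + age_py])
    cut = policy.max_years_since_quit - (1.0 if policy.strict_quit_years else 0.0)
    quit_limit = np.where(np.isfinite(history.quit_age),
                          birth + history.quit_age + cut, np.inf)
    end = np.minimum.reduce([np.full_like(birth, policy.end_year),
                             birth + policy.max_age, quit_limit])
    return start, end


def apply_screen(history: SmokingHistory, state, year: int,
                 policy: ScreeningPolicy, rng: np.random.Generator,
                 sensitivity: float, early_frac_screen: float,
                 undiagnosed: np.ndarray | None = None):
    """One annual screening round (step form, used for unit-level checks).

    Screens every eligible, undiagnosed person (a screen is counted whether
    or not anything is found); preclinical disease is detected with the
    per-screen ``sensitivity`` and, when detected, the stage is drawn from
    the screen-time distribution (early with probability
    ``early_frac_screen``).  Returns ``(screened_mask, detected_mask)``.
    """
    from .nathist import STAGE_EARLY, STAGE_LATE, STATE_CLINICAL, STATE_PRECLINICAL

    screened = is_eligible(history, year, policy)
    if undiagnosed is not None:
        screened &= undiagnosed
    if policy.adherence < 1.0:
        screened &= rng.uniform(size=len(history)) < policy.adherence
    detected = screened & (state.state == STATE_PRECLINICAL) \
        & (rng.uniform(size=len(history)) < sensitivity)
    state.state[detected] = STATE_CLINICAL
    state.detect_age[detected] = (year - history.birth_year)[detected]
    early = rng.uniform(size=len(history)) < early_frac_screen
    state.stage[detected] = np.where(early[detected], STAGE_EARLY, STAGE_LATE)
    return screened, detected
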