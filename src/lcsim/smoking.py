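"""Individual smoking life histories and the sensitivity-scenario transforms.

A person's trajectory is: possible initiation (a calibrated Gaussian-bump
hazard over ages 10-39), a single constant cigarettes-per-day intensity
drawn from the country's six-bin distribution, and possible cessation (the
published age-specific quit schedule).  There is no relapse: "former" is an
absorbing state.  Ages are integer attained ages; smoking status at age
``a`` means status at the start of that annual cycle, so a person who
initiates at age ``i`` can quit no earlier than age ``i + 1``.

Sampling is exactly equivalent to running the annual Bernoulli transitions:
each person carries one exponential threshold per process and the first age
at which the cumulative discrete hazard crosses it is the event age.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import MAX_AGE, SEXES, CountryConfig
from . import demog

NEVER = 0
CURRENT = 1
FORMER = 2
SMOKER_TYPE_LABELS = {NEVER: "never", CURRENT: "current", FORMER: "former"}

_NO_EVENT = np.inf


@dataclass(frozen=True)
class SensitivityScenario:
    """Future smoking-behavior scenario for birth cohorts after 1981.

    Multipliers act on the annual cessation probability and on cigarettes
    per day for people born after ``cohort_threshold``, from calendar year
    ``start_year`` onward; earlier cohorts and earlier calendar years are
    untouched, so an affected smoker's intensity is piecewise constant
    with a single switch at the start year.
    """

    label: str
    cessation_mult: float
    cpd_mult: float
    cohort_threshold: int = 1981
    start_year: int = 2011


ORIGINAL = SensitivityScenario("original", 1.0, 1.0)
OPTIMISTIC = SensitivityScenario("optimistic", 1.2, 0.8)
PESSIMISTIC = SensitivityScenario("pessimistic", 0.8, 1.2)
SCENARIOS = {s.label: s for s in (ORIGINAL, OPTIMISTIC, PESSIMISTIC)}


def apply_sensitivity(cfg: CountryConfig, scenario: SensitivityScenario | str):
    """Pair a config with a sensitivity scenario.

    Returns ``(cfg, scenario)`` with the label resolved to one of the three
    canonical scenarios; the transforms themselves are cohort- and
    calendar-year-conditional, so they are applied at sampling time via
    :func:`effective_quit_hazard` and the CPD multiplier rather than by
    rewriting the schedule in place.  People born in or before the threshold
    year, and years before the start year, are unaffected.
    """
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; have {sorted(SCENARIOS)}")
        scenario = SCENARIOS[scenario]
    return cfg, scenario


def effective_quit_hazard(cfg: CountryConfig, scenario: SensitivityScenario,
                          sex: str, birth_year: int) -> np.ndarray:
    """Annual quit probability by age for one birth cohort under a scenario."""
    q = cfg.cessation.quit_prob_array(sex).copy()
    if scenario.cessation_mult != 1.0 and birth_year > scenario.cohort_threshold:
        ages = np.arange(MAX_AGE + 1)
        affected = birth_year + ages >= scenario.start_year
        q[affected] = np.clip(q[affected] * scenario.cessation_mult, 0.0, 1.0)
    return q


def _cumhaz(prob: np.ndarray) -> np.ndarray:
    """Cumulative discrete hazard sum_{x<=a} -log(1 - p_x), shape (102,)."""
    with np.errstate(divide="ignore"):
        inc = -np.log1p(-np.clip(prob, 0.0, 1.0 - 1e-12))
    out = np.zeros(prob.size + 1)
    out[1:] = np.cumsum(inc)
    return out


@dataclass
class SmokingHistory:
    """Vectorized smoking trajectories for a block of simulated people.

    ``cpd`` is the intensity drawn at initiation.  Under a sensitivity
    scenario, affected people carry ``cpd_mult != 1`` from calendar year
    ``mult_start_year`` on (piecewise-constant intensity with one switch);
    in the base case every multiplier is 1 and intensity is constant.
    """

    birth_year: np.ndarray   # int
    sex: np.ndarray          # 0 = male, 1 = female
    init_age: np.ndarray     # float; inf = never initiated
    quit_age: np.ndarray     # float; inf = never quit
    cpd: np.ndarray          # cigarettes/day as drawn; 0 for never smokers
    cpd_mult: np.ndarray = None
    mult_start_year: int = 2011

    def __post_init__(self) -> None:
        smokers = np.isfinite(self.init_age)
        if np.any(self.quit_age[smokers] <= self.init_age[smokers]):
            raise ValueError("cessation age must exceed initiation age")
        if np.any((self.cpd > 0) != smokers):
            raise ValueError("cpd must be positive iff initiated")
        if self.cpd_mult is None:
            self.cpd_mult = np.ones_like(self.cpd)

    def __len__(self) -> int:
        return self.birth_year.size


def current_cpd(history: SmokingHistory, year) -> np.ndarray:
    """Intensity in effect during ``year`` (for someone smoking then)."""
    mult = np.where(np.asarray(year) >= history.mult_start_year,
                    history.cpd_mult, 1.0)
    return history.cpd * mult


def pack_years(history: SmokingHistory, age) -> np.ndarray:
    """Pack-years accumulated by the start of the cycle at ``age``.

    ``(cpd / 20) * years smoked``, from initiation to the earlier of
    ``age`` and cessation, with the scenario intensity multiplier applied
    only to smoking years from ``mult_start_year`` on.  Nondecreasing and
    piecewise linear in age.
    """
    age = np.asarray(age, dtype=float)
    switch_age = float(history.mult_start_year) - history.birth_year
    with np.errstate(invalid="ignore"):  # inf - inf for never smokers
        end = np.minimum(age, history.quit_age)
        pre = np.clip(np.minimum(end, switch_age) - history.init_age, 0.0, None)
        post = np.clip(end - np.maximum(history.init_age, switch_age), 0.0, None)
    smokers = np.isfinite(history.init_age)
    pre = np.where(smokers, pre, 0.0)
    post = np.where(smokers, post, 0.0)
    return history.cpd / 20.0 * (pre + history.cpd_mult * post)


def smoker_type(history: SmokingHistory, year: int) -> np.ndarray:
    """NEVER / CURRENT / FORMER status at the start of ``year``."""
    age = year - history.birth_year
    out = np.full(len(history), NEVER, dtype=np.int8)
    started = history.init_age <= age
    out[started & (history.quit_age > age)] = CURRENT
    out[started & (history.quit_age <= age)] = FORMER
    return out


def simulate_smoking(cfg: CountryConfig, birth_year: np.ndarray, sex: np.ndarray,
                     scenario: SensitivityScenario, seed: int,
                     peak_rate: dict | None = None) -> SmokingHistory:
    """Sample complete smoking histories for a block of people.

    ``peak_rate`` overrides the calibrated initiation peak rates (used by
    the calibration search); otherwise the config must be calibrated.
    Deterministic given ``(cfg, scenario, seed)`` and the person order.
    """
    if peak_rate is None:
        if cfg.calibrated is None:
            raise ValueError("config is uncalibrated: no initiation curves; "
                             "run calibrate_smoking or pass peak_rate")
        peak_rate = cfg.calibrated.initiation_peak_rate
    birth_year = np.asarray(birth_year)
    sex = np.asarray(sex)
    n = birth_year.size
    rng = np.random.default_rng([int(seed), 101])
    e_init = -np.log(rng.uniform(size=n))
    e_quit = -np.log(rng.uniform(size=n))
    u_cpd = rng.uniform(size=n)

    init_age = np.full(n, _NO_EVENT)
    quit_age = np.full(n, _NO_EVENT)
    cpd = np.zeros(n)

    for j, sexname in enumerate(SEXES):
        sel_sex = sex == j
        if not sel_sex.any():
            continue
        ch_init = _cumhaz(cfg.initiation.hazard_array(sexname, float(peak_rate[sexname])))
        pmf = cfg.cpd.integer_pmf(sexname)
        cum_pmf = np.cumsum(pmf[1:])
        # cessation hazard varies by cohort only when a scenario is active
        if scenario.cessation_mult == 1.0:
            groups = [(sel_sex, effective_quit_hazard(cfg, scenario, sexname, 1900))]
        else:
            groups = []
            pre = sel_sex & (birth_year <= scenario.cohort_threshold)
            if pre.any():
                groups.append((pre, effective_quit_hazard(cfg, scenario, sexname, 1900)))
            for by in np.unique(birth_year[sel_sex & (birth_year > scenario.cohort_threshold)]):
                groups.append((sel_sex & (birth_year == by),
                               effective_quit_hazard(cfg, scenario, sexname, int(by))))
        for sel, qhaz in groups:
            idx = np.flatnonzero(sel)
            if idx.size == 0:
                continue
            ia = np.searchsorted(ch_init[1:], e_init[idx], side="left").astype(float)
            never = ia > cfg.initiation.max_age  # hazard is zero beyond max_age
            ia[never] = _NO_EVENT
            init_age[idx] = ia
            ch_quit = _cumhaz(qhaz)
            smokers = idx[~never]
            ia_s = ia[~never].astype(int)
            # quitting can fire from the year after initiation onward
            target = ch_quit[ia_s + 1] + e_quit[smokers]
            qa = np.searchsorted(ch_quit[1:], target, side="left").astype(float)
            qa[qa > MAX_AGE] = _NO_EVENT
            quit_age[smokers] = qa
            drawn = 1.0 + np.searchsorted(cum_pmf, u_cpd[smokers], side="right").clip(0, cum_pmf.size - 1)
            cpd[smokers] = drawn
    cpd_mult = np.where((cpd > 0) & (birth_year > scenario.cohort_threshold),
                        scenario.cpd_mult, 1.0)
    return SmokingHistory(birth_year=birth_year, sex=sex, init_age=init_age,
                          quit_age=quit_age, cpd=cpd, cpd_mult=cpd_mult,
                          mult_start_year=scenario.start_year)


def smoker_oc_rr(cfg: CountryConfig, cpd) -> np.ndarray:
    """All-cause (non-lung-cancer) relative risk while smoking ``cpd``/day."""
    rr20 = cfg.other_cause.smoker_rr_20cpd
    return 1.0 + (rr20 - 1.0) * np.asarray(cpd, dtype=float) / 20.0


def oc_multiplier(cfg: CountryConfig, history: SmokingHistory, age) -> np.ndarray:
    """Per-person other-cause hazard multiplier at ``age`` (unnormalized).

    1 before initiation; the CPD-scaled relative risk while smoking; after
    quitting the excess decays with ``quit_rr_halflife``.
    """
    age = np.asarray(age, dtype=float)
    excess = smoker_oc_rr(cfg, history.cpd) - 1.0
    active = (history.init_age <= age) & (age < history.quit_age)
    quit = np.isfinite(history.quit_age) & (age >= history.quit_age)
    decay = np.power(0.5, np.clip(age - history.quit_age, 0.0, None)
                     / cfg.other_cause.quit_rr_halflife)
    frac = np.where(active, 1.0, np.where(quit, decay, 0.0))
    return 1.0 + excess * frac


def mean_oc_multiplier(cfg: CountryConfig, sex: str,
                       peak_rate: float | None = None) -> np.ndarray:
    """Expected (cohort-average) other-cause multiplier by age, one sex.

    Closed form over the initiation/cessation process with the mean smoker
    relative risk; used to renormalize the per-person multipliers so the
    population-average schedule remains the configured one.  Mortality
    selection (smokers dying out of the alive pool) is ignored here -- a
    second-order effect on the normalization.
    """
    if peak_rate is None:
        peak_rate = float(cfg.calibrated.initiation_peak_rate[sex])
    h_init = cfg.initiation.hazard_array(sex, peak_rate)
    surv_never = np.concatenate([[1.0], np.cumprod(1.0 - h_init)])
    p_init = h_init * surv_never[:-1]
    q = cfg.cessation.quit_prob_array(sex)
    qs = np.concatenate([[1.0], np.cumprod(1.0 - q)])   # no-quit through age x
    pmf = cfg.cpd.integer_pmf(sex)
    mean_cpd = float(np.sum(np.arange(pmf.size) * pmf))
    excess = float(smoker_oc_rr(cfg, mean_cpd) - 1.0)
    hl = cfg.other_cause.quit_rr_halflife
    d = 0.5 ** (1.0 / hl)
    # exact closed form via exponential-decay filters:
    #   E[m(a)] - 1 = excess * sum_i p_init[i]/qs[i+1] *
    #       (qs[a+1] + sum_{x=i+1..a} qs[x] q[x] d^(a-x))
    r = qs[:-1] * q                                  # quit-at-x mass factor
    G = np.empty(MAX_AGE + 1)
    G[0] = r[0]
    for x in range(1, MAX_AGE + 1):
        G[x] = G[x - 1] * d + r[x]
    c = np.where(qs[1:MAX_AGE + 2] > 0, p_init / qs[1:MAX_AGE + 2], 0.0)
    C = np.cumsum(c)
    S = np.cumsum(c * G * np.power(d, -np.arange(MAX_AGE + 1.0)))
    out = np.ones(MAX_AGE + 1)
    for a in range(MAX_AGE + 1):
        m = min(a, cfg.initiation.max_age - 1)
        out[a] = 1.0 + excess * (qs[a + 1] * C[m] + G[a] * C[m] - d ** a * S[m])
    return out


def expected_smoking_prevalence(cfg: CountryConfig, year: int, sex: str,
                                peak_rate: float | None = None,
                                scenario: SensitivityScenario = ORIGINAL,
                                adult_age: int = 18) -> float:
    """Closed-form expected adult current-smoking prevalence in ``year``.

    The exact expectation of the simulated proportion: cohorts are weighted
    by their national alive counts (other-cause survival applied to the
    anchored pyramid), and within each cohort the probability of being a
    current smoker sums initiation-age probabilities times quit survival.
    Used to generate self-consistent toy targets and as the independent
    cross-check for the simulation-based calibration.
    """
    if peak_rate is None:
        if cfg.calibrated is None:
            raise ValueError("config is uncalibrated; pass peak_rate")
        peak_rate = float(cfg.calibrated.initiation_peak_rate[sex])
    j = SEXES.index(sex)

    # forward recursion over (alive, smoking state), state = never / current /
    # former-quit-k-years-ago, with the smoking-dependent other-cause hazard
    # (mean CPD for the smoker excess; exact otherwise).  Mirrors the
    # sampling conventions: initiation at age i makes one current from i on,
    # quitting applies from the year after initiation, and being alive at
    # age a means surviving the hazards of ages 0..a.
    h_init = cfg.initiation.hazard_array(sex, peak_rate)
    base = cfg.other_cause.rate_array(sex, warn_clip=False)
    mbar = mean_oc_multiplier(cfg, sex, peak_rate)
    pmf = cfg.cpd.integer_pmf(sex)
    mean_cpd = float(np.sum(np.arange(pmf.size) * pmf))
    excess = float(smoker_oc_rr(cfg, mean_cpd) - 1.0)
    hl = cfg.other_cause.quit_rr_halflife

    def status_shares(a_target: int, birth_year: int):
        """(P(alive & current), P(alive)) at attained age ``a_target``."""
        q = effective_quit_hazard(cfg, scenario, sex, birth_year)
        never, current = 1.0, 0.0
        former = np.zeros(MAX_AGE + 2)  # index = years since quitting
        for t in range(a_target + 1):
            decay = 0.5 ** (np.arange(former.size) / hl)
            s_never = 1.0 - np.clip(base[t] / mbar[t], 0.0, 1.0)
            s_cur = 1.0 - np.clip(base[t] * (1.0 + excess) / mbar[t], 0.0, 1.0)
            s_former = 1.0 - np.clip(base[t] * (1.0 + excess * decay) / mbar[t],
                                     0.0, 1.0)
            never, current, former = never * s_never, current * s_cur, former * s_former
            if t < a_target:
                # transitions into age t+1
                quitting = current * q[t + 1]
                starting = never * h_init[t + 1]
                never -= starting
                current += starting - quitting
                former = np.roll(former, 1)
                former[0] = quitting
        return current, never + current + former.sum()

    num = den = 0.0
    for c in demog.cohort_years():
        a = year - c
        if not adult_age <= a <= MAX_AGE:
            continue
        size = demog.newborn_cohort_sizes(cfg)[c - demog.COHORT_FIRST, j]
        cur, alive = status_shares(a, int(c))
        num += size * cur
        den += size * alive
    return num / den if den > 0 else 0.0
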