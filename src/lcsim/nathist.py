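"""Lung-cancer natural history: a calibrated smoking-dependent surrogate.

Structure: an age-increasing baseline onset hazard (Weibull-like, nonzero
for never smokers) multiplied by an excess-relative-risk dose response in
*effective* pack-years (pack-years decay with a fixed half-life after
quitting); a geometric preclinical sojourn; clinical surfacing that draws an
early/late stage; and stage-specific annual cause-specific death
probabilities from the time of clinical surfacing.  Screening can only
change the stage drawn at detection (stage shift) -- it never edits hazards
directly -- so a person's lung-cancer death clock always starts at the
(possibly counterfactual) clinical surfacing time.  This makes paired
scenario comparisons free of lead-time bias by construction.

The annual-step operations here are the unit-testable transition kernels;
the engine samples entire event times with exactly equivalent inverse-CDF
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MAX_AGE, SEXES, NaturalHistoryParams, OtherCauseMortalityTable
from .smoking import SmokingHistory, pack_years

__all__ = [
    "NaturalHistoryParams", "CancerState", "baseline_hazard",
    "effective_pack_years", "onset_hazard", "progress_cancer",
    "other_cause_death", "cancer_survival_step",
    "STATE_NONE", "STATE_PRECLINICAL", "STATE_CLINICAL",
    "STAGE_UNSET", "STAGE_EARLY", "STAGE_LATE",
]

STATE_NONE, STATE_PRECLINICAL, STATE_CLINICAL = 0, 1, 2
STAGE_UNSET, STAGE_EARLY, STAGE_LATE = -1, 0, 1

_REF_AGE = 80.0  # baseline_scale is the never-smoker onset hazard at this age


@dataclass
class CancerState:
    """Vectorized disease state for a block of people (forward-only)."""

    state: np.ndarray                    # STATE_* per person
    onset_age: np.ndarray = None         # float; nan until onset
    detect_age: np.ndarray = None        # float; nan until detection
    stage: np.ndarray = None             # STAGE_* per person

    def __post_init__(self) -> None:
        n = self.state.size
        if self.onset_age is None:
            self.onset_age = np.full(n, np.nan)
        if self.detect_age is None:
            self.detect_age = np.full(n, np.nan)
        if self.stage is None:
            self.stage = np.full(n, STAGE_UNSET, dtype=np.int8)


def baseline_hazard(params: NaturalHistoryParams, scale: float, age) -> np.ndarray:
    """Never-smoker annual onset hazard; ``scale`` is the hazard at age 80.

    Weibull-like rise from ``baseline_age0`` that stops increasing at
    ``baseline_plateau_age``, matching the flattening of incidence curves
    at the oldest ages.
    """
    age = np.minimum(np.asarray(age, dtype=float), params.baseline_plateau_age)
    rel = np.clip(age - params.baseline_age0, 0.0, None) / (_REF_AGE - params.baseline_age0)
    return np.clip(scale * rel ** params.baseline_power, 0.0, 1.0)


def effective_pack_years(params: NaturalHistoryParams, history: SmokingHistory,
                         age) -> np.ndarray:
    """Pack-years driving current risk, decayed after cessation.

    While smoking this equals accumulated pack-years; after quitting the
    excess exposure decays exponentially with ``quit_halflife``.
    """
    age = np.asarray(age, dtype=float)
    py = pack_years(history, age)
    since_quit = np.clip(age - history.quit_age, 0.0, None)
    since_quit = np.where(np.isfinite(history.quit_age), since_quit, 0.0)
    return py * np.power(0.5, since_quit / params.quit_halflife)


def onset_hazard(params: NaturalHistoryParams, scale: float,
                 history: SmokingHistory, age, sex=None) -> np.ndarray:
    """Annual probability of preclinical onset at ``age``.

    ``baseline(age) * (1 + ERR * effective pack-years)``, clipped into
    [0, 1].  ``sex`` enters only through the per-sex ``scale``.
    """
    epy = effective_pack_years(params, history, age)
    if np.any(epy < 0):
        raise ValueError("negative pack-years")
    return np.clip(baseline_hazard(params, scale, age) * (1.0 + params.err_per_pack_year * epy),
                   0.0, 1.0)


def progress_cancer(state: CancerState, params: NaturalHistoryParams,
                    rng: np.random.Generator, current_age=None) -> CancerState:
    """One annual step: preclinical disease surfaces clinically.

    Surfacing is geometric with mean sojourn ``sojourn_mean``; on surfacing
    the detection stage is early with probability ``early_frac_clinical``.
    People without disease are untouched.
    """
    pre = state.state == STATE_PRECLINICAL
    if pre.any():
        surface = pre & (rng.uniform(size=state.state.size) < 1.0 / params.sojourn_mean)
        state.state[surface] = STATE_CLINICAL
        early = rng.uniform(size=state.state.size) < params.early_frac_clinical
        state.stage[surface] = np.where(early[surface], STAGE_EARLY, STAGE_LATE)
        if current_age is not None:
            state.detect_age[surface] = np.asarray(current_age, dtype=float)[surface] \
                if np.ndim(current_age) else float(current_age)
    return state


def other_cause_death(age, sex, table: OtherCauseMortalityTable,
                      rng: np.random.Generator) -> np.ndarray:
    """Bernoulli death-from-other-causes draw at the scaled country rate."""
    age = np.asarray(age)
    sex = np.asarray(sex)
    p = np.empty(age.shape, dtype=float)
    for j, sexname in enumerate(SEXES):
        rates = table.rate_array(sexname)
        sel = sex == j
        p[sel] = rates[np.clip(age[sel], 0, MAX_AGE)]
    return rng.uniform(size=age.shape) < p


def cancer_survival_step(stage: np.ndarray, params: NaturalHistoryParams,
                         rng: np.random.Generator,
                         cured: np.ndarray | None = None) -> np.ndarray:
    """One annual cause-specific survival step for detected cancer.

    Uncured cases die at the stage-specific annual probability (``q_early``
    or ``q_late``); the cured fraction (drawn once at surfacing, see
    ``cure_early``/``cure_late``) never dies of the cancer.  Screen-detected
    people differ only through the stage they carry.
    """
    stage = np.asarray(stage)
    q = np.where(stage == STAGE_EARLY, params.q_early, params.q_late)
    if cured is not None:
        q = np.where(cured, 0.0, q)
    return rng.uniform(size=stage.shape) < q
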