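"""Natural-history surrogate: hazards, progression, survival, mortality."""

import dataclasses

import numpy as np
import pytest

from lcsim.config import NaturalHistoryParams, OtherCauseMortalityTable
from lcsim.nathist import (STAGE_EARLY, STAGE_LATE, STATE_CLINICAL,
                           STATE_NONE, STATE_PRECLINICAL, CancerState,
                           baseline_hazard, cancer_survival_step,
                           effective_pack_years, onset_hazard,
                           other_cause_death, progress_cancer)
from lcsim.smoking import SmokingHistory
from lcsim.synth import REFERENCE_MAKEHAM

PARAMS = NaturalHistoryParams()


def _hist(init, quit, cpd, n=1):
    return SmokingHistory(np.full(n, 1950), np.zeros(n, dtype=np.int8),
                          np.full(n, float(init)), np.full(n, float(quit)),
                          np.full(n, float(cpd)))


class TestOnsetHazard:
    def test_never_smoker_equals_baseline(self):
        h = SmokingHistory(np.array([1950]), np.array([0], dtype=np.int8),
                           np.array([np.inf]), np.array([np.inf]), np.array([0.0]))
        got = onset_hazard(PARAMS, 2e-3, h, 70)
        np.testing.assert_allclose(got, baseline_hazard(PARAMS, 2e-3, 70))

    def test_hazard_ratio_closed_form(self):
        """30 pack-years vs never at the same age: ratio = 1 + 30 * ERR."""
        smoker = _hist(20, np.inf, 20.0)   # 30 py at age 50
        never = SmokingHistory(np.array([1950]), np.array([0], dtype=np.int8),
                               np.array([np.inf]), np.array([np.inf]),
                               np.array([0.0]))
        hr = onset_hazard(PARAMS, 1e-3, smoker, 50)[0] / \
            onset_hazard(PARAMS, 1e-3, never, 50)[0]
        np.testing.assert_allclose(hr, 1.0 + 30.0 * PARAMS.err_per_pack_year)

    def test_post_quit_decay_halves_exposure(self):
        h = _hist(20, 50, 20.0)  # 30 py at quit
        epy = effective_pack_years(PARAMS, h, 50 + PARAMS.quit_halflife)
        np.testing.assert_allclose(epy, 15.0)

    def test_negative_pack_years_rejected(self):
        h = _hist(20, np.inf, 20.0)
        h.cpd[:] = -5.0  # corrupt in place, bypassing construction checks
        with pytest.raises(ValueError, match="negative pack-years"):
            onset_hazard(PARAMS, 1e-3, h, 50)

    def test_constant_hazard_cumulative_incidence(self, rng):
        """P(onset within 10 years at constant h) = 1 - (1-h)^10."""
        h = 0.02
        n = 100_000
        onset = np.zeros(n, dtype=bool)
        for _ in range(10):
            onset |= rng.uniform(size=n) < h
        expected = 1.0 - (1.0 - h) ** 10
        assert abs(onset.mean() - expected) < 0.005

    def test_baseline_plateau(self):
        assert baseline_hazard(PARAMS, 1e-3, 90) == baseline_hazard(PARAMS, 1e-3, 80)
        assert baseline_hazard(PARAMS, 1e-3, 30) == 0.0


class TestProgression:
    def test_geometric_sojourn_mean(self, rng):
        """Mean sojourn of preclinical disease matches the parameter."""
        n = 100_000
        state = CancerState(state=np.full(n, STATE_PRECLINICAL, dtype=np.int8))
        years = np.zeros(n)
        for _ in range(200):
            pre = state.state == STATE_PRECLINICAL
            if not pre.any():
                break
            years[pre] += 1
            progress_cancer(state, PARAMS, rng)
        assert abs(years.mean() - PARAMS.sojourn_mean) < 0.1

    def test_early_fraction_one_means_all_early(self, rng):
        p = dataclasses.replace(PARAMS, early_frac_clinical=1.0)
        state = CancerState(state=np.full(50_000, STATE_PRECLINICAL, dtype=np.int8))
        for _ in range(100):
            progress_cancer(state, p, rng)
        done = state.state == STATE_CLINICAL
        assert done.all()
        assert np.all(state.stage[done] == STAGE_EARLY)

    def test_disease_free_untouched(self, rng):
        state = CancerState(state=np.full(100, STATE_NONE, dtype=np.int8))
        progress_cancer(state, PARAMS, rng)
        assert np.all(state.state == STATE_NONE)


class TestOtherCauseDeath:
    TABLE = OtherCauseMortalityTable(REFERENCE_MAKEHAM,
                                     {"male": 1.0, "female": 1.0})

    def test_ratio_identity_and_zero(self):
        t0 = OtherCauseMortalityTable(REFERENCE_MAKEHAM, {"male": 0.0, "female": 0.0})
        assert np.all(t0.rate_array("male") == 0.0)
        np.testing.assert_array_equal(self.TABLE.rate_array("female"),
                                      self.TABLE.base_rate_array("female"))

    def test_scaled_rate_binomial_check(self, rng):
        """rate 0.01 * ratio 1.5 kills 1.5% +/- binomial error of draws."""
        t = OtherCauseMortalityTable({"male": (0.01, 0.0, 1.0),
                                      "female": (0.01, 0.0, 1.0)},
                                     {"male": 1.5, "female": 1.5})
        n = 1_000_000
        died = other_cause_death(np.full(n, 50), np.zeros(n, dtype=np.int8), t, rng)
        assert abs(died.mean() - 0.015) < 0.0004

    def test_clipping_warns(self):
        t = OtherCauseMortalityTable(REFERENCE_MAKEHAM, {"male": 100.0, "female": 1.0})
        with pytest.warns(RuntimeWarning, match="clipping"):
            t.rate_array("male")


class TestCancerSurvival:
    def test_survival_closed_form(self, rng):
        """Uncured late-stage survival after k years is (1-q)^k."""
        n, k = 200_000, 4
        stage = np.full(n, STAGE_LATE, dtype=np.int8)
        alive = np.ones(n, dtype=bool)
        for _ in range(k):
            died = cancer_survival_step(stage, PARAMS, rng, cured=np.zeros(n, bool))
            alive &= ~died
        expected = (1.0 - PARAMS.q_late) ** k
        assert abs(alive.mean() - expected) < 0.005

    def test_cured_never_die(self, rng):
        stage = np.full(1000, STAGE_EARLY, dtype=np.int8)
        died = cancer_survival_step(stage, PARAMS, rng, cured=np.ones(1000, bool))
        assert not died.any()
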