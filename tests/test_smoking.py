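"""Smoking life histories, pack-years, smoker typing, and scenarios."""

import numpy as np
import pytest

from lcsim.smoking import (CURRENT, FORMER, NEVER, OPTIMISTIC, ORIGINAL,
                           PESSIMISTIC, SensitivityScenario, SmokingHistory,
                           apply_sensitivity, effective_quit_hazard,
                           expected_smoking_prevalence, pack_years,
                           simulate_smoking, smoker_type)


def _hist(birth, init, quit, cpd, sex=0):
    n = len(birth)
    return SmokingHistory(np.asarray(birth), np.full(n, sex, dtype=np.int8),
                          np.asarray(init, dtype=float),
                          np.asarray(quit, dtype=float),
                          np.asarray(cpd, dtype=float))


class TestPackYears:
    @pytest.mark.parametrize("cpd,init,age,expected", [
        (20.0, 20, 50, 30.0),
        (10.0, 20, 50, 15.0),
        (40.0, 25, 40, 30.0),
    ])
    def test_definition(self, cpd, init, age, expected):
        h = _hist([1950], [init], [np.inf], [cpd])
        assert pack_years(h, age)[0] == expected

    def test_stops_accruing_at_cessation(self):
        h = _hist([1950], [20], [40], [20.0])
        assert pack_years(h, 40)[0] == pack_years(h, 60)[0] == 20.0

    def test_nondecreasing_piecewise_linear(self):
        h = _hist([1950], [18], [45], [15.0])
        ages = np.arange(0, 101)
        py = np.array([pack_years(h, a)[0] for a in ages])
        assert np.all(np.diff(py) >= 0)
        assert py[0] == 0.0

    def test_never_smoker_is_zero(self):
        h = _hist([1950], [np.inf], [np.inf], [0.0])
        assert pack_years(h, 80)[0] == 0.0


class TestSmokerType:
    def test_three_states(self):
        h = _hist([1970, 1970, 1970], [np.inf, 20, 20],
                  [np.inf, np.inf, 35], [0, 20, 20])
        got = smoker_type(h, 2010)  # age 40
        assert list(got) == [NEVER, CURRENT, FORMER]

    def test_not_yet_initiated_is_never(self):
        h = _hist([2005], [20], [np.inf], [10.0])
        assert smoker_type(h, 2010)[0] == NEVER


class TestScenarios:
    def test_presets(self):
        assert (ORIGINAL.cessation_mult, ORIGINAL.cpd_mult) == (1.0, 1.0)
        assert (OPTIMISTIC.cessation_mult, OPTIMISTIC.cpd_mult) == (1.2, 0.8)
        assert (PESSIMISTIC.cessation_mult, PESSIMISTIC.cpd_mult) == (0.8, 1.2)
        assert ORIGINAL.cohort_threshold == 1981 and ORIGINAL.start_year == 2011

    def test_quit_hazard_multiplied_only_when_affected(self, china):
        # 1990 cohort, pessimistic: 0.02 * 0.8 = 0.016 from 2011 onward
        q = effective_quit_hazard(china, PESSIMISTIC, "male", 1990)
        assert np.isclose(q[30], 0.016)  # calendar 2020 >= 2011
        # 1975 cohort unaffected
        q75 = effective_quit_hazard(china, PESSIMISTIC, "male", 1975)
        assert np.isclose(q75[30], 0.02)
        # optimistic: 20% higher
        qo = effective_quit_hazard(china, OPTIMISTIC, "male", 1990)
        assert np.isclose(qo[40], 0.024)

    def test_cpd_multiplier_on_affected_cohorts(self, china):
        from lcsim.smoking import current_cpd
        cfg, scen = apply_sensitivity(china, "optimistic")
        birth = np.full(20_000, 1990)
        old = np.full(20_000, 1960)
        sex = np.zeros(20_000, dtype=np.int8)
        pk = {"male": 0.1, "female": 0.02}
        h_new = simulate_smoking(cfg, birth, sex, scen, seed=5, peak_rate=pk)
        h_old = simulate_smoking(cfg, old, sex, scen, seed=5, peak_rate=pk)
        h_ref = simulate_smoking(cfg, birth, sex, ORIGINAL, seed=5, peak_rate=pk)
        sm = h_new.cpd > 0
        # affected cohort: same smokers; intensity 20% lower from 2011 on,
        # untouched before (a 20-CPD smoker drops to 16)
        np.testing.assert_array_equal(sm, h_ref.cpd > 0)
        np.testing.assert_allclose(current_cpd(h_new, 2015)[sm],
                                   0.8 * current_cpd(h_ref, 2015)[sm])
        np.testing.assert_array_equal(current_cpd(h_new, 2009), h_new.cpd)
        # pack-years accrued before 2011 are identical to the base case
        np.testing.assert_allclose(pack_years(h_new, 2010 - 1990),
                                   pack_years(h_ref, 2010 - 1990))
        # by 2030 the affected smokers have fewer pack-years
        later = pack_years(h_new, 40)[sm] <= pack_years(h_ref, 40)[sm]
        assert later.all()
        # unaffected cohort: identical histories under paired seed
        h_old_ref = simulate_smoking(cfg, old, sex, ORIGINAL, seed=5, peak_rate=pk)
        np.testing.assert_array_equal(h_old.cpd * h_old.cpd_mult,
                                      h_old_ref.cpd * h_old_ref.cpd_mult)

    def test_unknown_label_rejected(self, china):
        with pytest.raises(ValueError, match="unknown scenario"):
            apply_sensitivity(china, "imaginative")


class TestSimulateSmoking:
    def test_zero_initiation_gives_never_smokers(self, china):
        birth = np.full(5_000, 1960)
        sex = np.zeros(5_000, dtype=np.int8)
        h = simulate_smoking(china, birth, sex, ORIGINAL, seed=1,
                             peak_rate={"male": 0.0, "female": 0.0})
        assert np.all(~np.isfinite(h.init_age))
        assert np.all(pack_years(h, 60) == 0.0)

    def test_uncalibrated_config_rejected(self, china):
        with pytest.raises(ValueError, match="uncalibrated"):
            simulate_smoking(china, np.array([1960]),
                             np.array([0], dtype=np.int8), ORIGINAL, seed=1)

    def test_quit_survival_matches_closed_form(self, china):
        """At 2%/yr from age 30, ~0.98^10 of smokers-at-30 still smoke at 40."""
        n = 200_000
        birth = np.full(n, 1950)
        sex = np.zeros(n, dtype=np.int8)
        h = simulate_smoking(china, birth, sex, ORIGINAL, seed=2,
                             peak_rate={"male": 0.2, "female": 0.0})
        at30 = smoker_type(h, 1980) == CURRENT
        at40 = smoker_type(h, 1990) == CURRENT
        frac = at40[at30].mean()
        assert abs(frac - 0.98**10) < 0.01  # 0.817 +/- MC

    def test_prevalence_monotone_in_cessation_multiplier(self, china):
        """Higher quit rates cannot raise current prevalence (paired seed)."""
        n = 100_000
        birth = np.full(n, 1960)
        sex = np.zeros(n, dtype=np.int8)
        pk = {"male": 0.12, "female": 0.02}
        prev = []
        for mult in (0.5, 1.0, 2.0):
            scen = SensitivityScenario("x", mult, 1.0, cohort_threshold=1900,
                                       start_year=1900)
            h = simulate_smoking(china, birth, sex, scen, seed=3, peak_rate=pk)
            prev.append((smoker_type(h, 2010) == CURRENT).mean())
        assert prev[0] >= prev[1] >= prev[2]

    def test_simulation_matches_closed_form_expectation(self, china):
        """Monte Carlo prevalence agrees with the analytic expectation."""
        from lcsim.engine import build_population, weighted_smoking_prevalence
        pk = {"male": 0.1, "female": 0.02}
        base = build_population(china, ORIGINAL, 150_000, seed=4,
                                peak_rate=pk, with_cancer=False)
        sim = weighted_smoking_prevalence(base, 2010, "male")
        exact = expected_smoking_prevalence(china, 2010, "male", pk["male"])
        assert abs(sim - exact) < 0.01
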