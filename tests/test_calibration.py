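"""Staged calibration: target matching, parameter recovery, idempotence.

The toy country stores its true parameters, so stripping them and
re-calibrating is a genuine recovery experiment.  Sample sizes are kept at
the smallest n where Monte Carlo noise is comfortably inside the stated
recovery bounds.
"""

import dataclasses

import numpy as np
import pytest

from lcsim.calibrate import (calibrate_mortality, calibrate_screening_benefit,
                             calibrate_smoking, trial_cohort, trial_reduction)
from lcsim.config import CalibrationTargets

N = 200_000


@pytest.fixture(scope="module")
def stripped(toy):
    """The toy country with its calibrated parameters removed."""
    return dataclasses.replace(toy, calibrated=None)


@pytest.fixture(scope="module")
def resmoked(stripped):
    return calibrate_smoking(stripped, N, seed=11)


class TestSmokingCalibration:
    def test_prevalence_targets_hit(self, resmoked, toy):
        for line in resmoked.calibrated.report["smoking"]["targets"]:
            assert line["pass"], line
            assert abs(line["achieved"] - line["target"]) <= 0.01

    def test_peak_rate_recovered(self, resmoked, toy):
        """Fitted initiation peak rates land within 10% of the truth."""
        for sex in ("male", "female"):
            truth = toy.calibrated.initiation_peak_rate[sex]
            got = resmoked.calibrated.initiation_peak_rate[sex]
            assert abs(got - truth) / truth < 0.10

    def test_deterministic_given_seed(self, stripped, resmoked):
        again = calibrate_smoking(stripped, N, seed=11)
        assert again.calibrated.initiation_peak_rate == \
            resmoked.calibrated.initiation_peak_rate


@pytest.fixture(scope="module")
def remort(resmoked):
    return calibrate_mortality(resmoked, N, seed=11)


class TestMortalityCalibration:
    def test_death_targets_hit(self, remort):
        for line in remort.calibrated.report["mortality"]["targets"]:
            assert line["pass"], line

    def test_baseline_scale_recovered(self, remort, toy):
        """Fitted baseline hazard scales land within 15% of the truth."""
        for sex in ("male", "female"):
            truth = toy.calibrated.baseline_scale[sex]
            got = remort.calibrated.baseline_scale[sex]
            assert abs(got - truth) / truth < 0.15

    def test_near_zero_target_drives_scale_to_boundary(self, resmoked):
        tiny = dataclasses.replace(
            resmoked,
            targets=CalibrationTargets(
                resmoked.targets.prevalence_year, resmoked.targets.prevalence,
                resmoked.targets.mortality_year, {"male": 1, "female": 1}))
        out = calibrate_mortality(tiny, 50_000, seed=2)
        for sex in ("male", "female"):
            assert out.calibrated.baseline_scale[sex] < 1e-5

    def test_requires_smoking_stage_first(self, stripped):
        with pytest.raises(ValueError, match="calibrate_smoking"):
            calibrate_mortality(stripped, 20_000, seed=1)


class TestScreeningBenefitCalibration:
    def test_null_benefit_and_bracket(self, toy):
        """No stage shift gives no reduction; the full-shift bracket can
        exceed the trial target."""
        cohort = trial_cohort(toy, 100_000, seed=5)
        null = trial_reduction(cohort, 1.0,
                               toy.natural_history.early_frac_clinical)
        assert abs(null) < 1e-12
        assert trial_reduction(cohort, 1.0, 1.0) > 0.20

    def test_fitted_benefit_on_held_out_seed(self, toy):
        sens, f_fit, report = calibrate_screening_benefit(toy, 300_000, seed=11)
        line = report["targets"][0]
        assert report["converged"]
        assert toy.natural_history.early_frac_clinical <= f_fit <= 1.0
        assert abs(line["achieved"] - 0.20) <= 0.03

    def test_requires_natural_history(self, resmoked):
        with pytest.raises(ValueError, match="natural history"):
            calibrate_screening_benefit(resmoked, 20_000, seed=1)


class TestIdempotence:
    def test_recalibration_reproduces_parameters(self, resmoked):
        """Calibration is deterministic and never warm-started, so running
        the stage again changes nothing."""
        again = calibrate_smoking(
            dataclasses.replace(resmoked, calibrated=None), N, seed=11)
        for sex in ("male", "female"):
            assert again.calibrated.initiation_peak_rate[sex] == \
                pytest.approx(resmoked.calibrated.initiation_peak_rate[sex],
                              abs=1e-12)
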