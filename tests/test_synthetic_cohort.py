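"""Generator calibration, determinism, and descriptive summaries."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import logit

import vdscore as v
from vdscore.errors import ConvergenceError
from vdscore.synthetic_cohort import APACHE_MODEL, DCCI_MODEL


def _no_effect_config(**over):
    zeros = dict(
        beta_vitd=0.0, beta_dcci=0.0, beta_apache=0.0, beta_age=0.0,
        beta_sex=0.0, beta_race=0.0, beta_bmi=0.0, beta_type=0.0,
        vitd_dcci_coupling=0.0, vitd_apache_coupling=0.0,
    )
    zeros.update(over)
    return v.GeneratorConfig(**zeros)


class TestCalibrateIntercept:
    def test_constant_linear_predictor_gives_logit_of_target(self):
        cfg = _no_effect_config(target_mortality=0.19)
        alpha = v.calibrate_intercept(cfg, n_mc=2000)
        assert alpha == pytest.approx(logit(0.19), abs=1e-3)

    def test_symmetric_target_gives_zero(self):
        cfg = _no_effect_config(target_mortality=0.5)
        assert v.calibrate_intercept(cfg, n_mc=2000) == pytest.approx(0.0, abs=1e-3)

    def test_default_config_hits_target_on_independent_draw(self, dcci_config, dcci_alpha):
        # fresh 100k cohort with a seed unrelated to the calibration seed
        cfg = dataclasses.replace(dcci_config, n=100_000, seed=424242)
        cohort = v.generate_cohort(cfg, alpha=dcci_alpha)
        assert cohort.frame["death90"].mean() == pytest.approx(0.19, abs=0.01)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_targets_rejected(self, target):
        cfg = _no_effect_config(target_mortality=target)
        with pytest.raises(ValueError):
            v.calibrate_intercept(cfg, n_mc=2000)

    def test_small_monte_carlo_size_rejected(self, dcci_config):
        with pytest.raises(ValueError):
            v.calibrate_intercept(dcci_config, n_mc=10)


class TestGenerateCohort:
    def test_zero_size_gives_empty_cohort(self):
        cohort = v.generate_cohort(_no_effect_config(n=0))
        assert len(cohort) == 0
        assert cohort.is_empty

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            v.generate_cohort(_no_effect_config(n=-1))

    def test_same_seed_is_reproducible(self, dcci_config, dcci_alpha):
        cfg = dataclasses.replace(dcci_config, n=310, seed=7)
        a = v.generate_cohort(cfg, alpha=dcci_alpha)
        b = v.generate_cohort(cfg, alpha=dcci_alpha)
        assert a.frame.equals(b.frame)

    def test_different_seeds_differ(self, dcci_config, dcci_alpha):
        a = v.generate_cohort(dataclasses.replace(dcci_config, seed=1), alpha=dcci_alpha)
        b = v.generate_cohort(dataclasses.replace(dcci_config, seed=2), alpha=dcci_alpha)
        assert not a.frame.equals(b.frame)

    def test_marginals_match_study_population(self, dcci_config, dcci_alpha):
        cfg = dataclasses.replace(dcci_config, n=10_000, seed=3)
        f = v.generate_cohort(cfg, alpha=dcci_alpha).frame
        assert f["vitd_25ohd"].mean() == pytest.approx(19.0, abs=0.5)
        assert f["death90"].mean() == pytest.approx(0.19, abs=0.01)
        assert f["dcci"].mean() == pytest.approx(4.0, abs=0.2)
        assert f["apache_ii"].mean() == pytest.approx(17.0, abs=0.3)
        # rounding/clamping keep the integer scores in range
        assert f["dcci"].min() >= 0
        assert f["apache_ii"].between(0, 71).all()
        assert f["age"].min() >= 18
        assert (f["vitd_25ohd"] > 0).all()

    def test_increasing_dcci_effect_never_reduces_high_dcci_mortality(
        self, dcci_config, dcci_alpha
    ):
        # common random numbers: same seed, same alpha, larger beta_dcci
        lo = dataclasses.replace(dcci_config, n=5000, seed=5)
        hi = dataclasses.replace(lo, beta_dcci=math.log(2.0))
        f_lo = v.generate_cohort(lo, alpha=dcci_alpha).frame
        f_hi = v.generate_cohort(hi, alpha=dcci_alpha).frame
        mask = f_lo["dcci"] >= 6
        assert (f_hi.loc[mask, "death90"] >= f_lo.loc[mask, "death90"]).all()

    def test_apache_model_uses_apache_coefficient(self, apache_config, apache_alpha):
        cfg = dataclasses.replace(apache_config, n=20_000, seed=9)
        f = v.generate_cohort(cfg, alpha=apache_alpha).frame
        dead = f["death90"] == 1
        assert f.loc[dead, "apache_ii"].mean() > f.loc[~dead, "apache_ii"].mean()

    def test_unbracketable_target_raises(self):
        cfg = _no_effect_config(beta_bmi=10.0, target_mortality=1e-9)
        with pytest.raises((ConvergenceError, ValueError)):
            cfg2 = dataclasses.replace(cfg, target_mortality=0.19)
            # a huge positive effect on an always-positive covariate pushes
            # every linear predictor far above what alpha in [-20, 20] can undo
            v.calibrate_intercept(dataclasses.replace(cfg2, beta_bmi=50.0), n_mc=2000)


class TestSummarizeCohort:
    def test_empty_cohort_summary_is_absent(self):
        s = v.summarize_cohort(v.Cohort())
        assert s.overall is None and s.mortality_prob is None

    def test_all_survivors_has_absent_nonsurvivor_stratum(self):
        records = [
            v.PatientRecord(70, "female", "white", 25.0, "surgical", 2, 10, 15.0, 0),
            v.PatientRecord(60, "male", "white", 30.0, "medical", 4, 20, 25.0, 0),
        ]
        s = v.summarize_cohort(v.Cohort.from_records(records))
        assert s.non_survivors is None
        assert s.mortality_prob == 0.0
        assert s.survivors.n == 2

    def test_three_point_hand_check(self):
        records = [
            v.PatientRecord(70, "female", "white", 25.0, "surgical", 2, 10, x, 0)
            for x in (10.0, 20.0, 30.0)
        ]
        s = v.summarize_cohort(v.Cohort.from_records(records))
        mean, sd = s.survivors.means["vitd_25ohd"]
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(10.0)  # n-1 denominator

    def test_stratum_counts_and_proportions(self, cohort310):
        s = v.summarize_cohort(cohort310)
        assert s.survivors.n + s.non_survivors.n == s.overall.n == len(cohort310)
        for stratum in (s.overall, s.survivors, s.non_survivors):
            for props in stratum.proportions.values():
                assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_permutation_invariance(self, cohort310, rng):
        shuffled = v.Cohort(
            cohort310.frame.sample(frac=1.0, random_state=12345), label="shuffled"
        )
        a = v.summarize_cohort(cohort310)
        b = v.summarize_cohort(shuffled)
        assert a.mortality_prob == b.mortality_prob
        for sa, sb in ((a.overall, b.overall), (a.survivors, b.survivors),
                       (a.non_survivors, b.non_survivors)):
            assert sa.n == sb.n
            assert sa.proportions == sb.proportions
            for field in sa.means:
                # up to float summation order
                assert sa.means[field] == pytest.approx(sb.means[field], rel=1e-12)

    def test_survivors_have_higher_vitamin_d(self, big_cohort):
        # the inverse 25OHD-mortality coefficient implies a positive
        # survivor/non-survivor gap in mean 25OHD
        s = v.summarize_cohort(big_cohort)
        assert s.survivors.means["vitd_25ohd"][0] > s.non_survivors.means["vitd_25ohd"][0]
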