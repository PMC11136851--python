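"""Likelihood under both estimand strategies, against brute-force oracles."""

import math

import numpy as np
import pytest

from renresp.likelihood import (
    dropout_probability,
    hazard_path,
    impute_post_dropout,
    individual_objectives,
    loglik_imputed,
    loglik_joint,
    objective,
    survival_probability,
)
from renresp.model_core import response_probability
from renresp.types import (
    DEFAULT_SCHEDULE,
    CovariateSet,
    DataConsistencyError,
    HazardPair,
    ModelSpec,
    ParameterVector,
    SubjectRecord,
    VisitObservation,
)

from conftest import make_subject, random_small_subjects


def day_grid_loglik_oracle(subject, theta, spec):
    """Brute-force joint log-likelihood: per-visit Bernoulli terms plus a
    day-by-day Riemann sum of the carried-forward-status hazard (exact for
    integer breakpoints)."""
    ll = 0.0
    for obs in subject.observations:
        p = response_probability(theta, subject.cov, spec, obs.t)
        ll += math.log(p) if obs.response else math.log1p(-p)
    hz = {1: theta.hz_r, 0: theta.hz_nr}

    def status_at(day):
        s = 0
        for obs in subject.observations:
            if obs.t <= day:
                s = obs.response
        return s

    integral = sum(hz[status_at(d)] for d in range(int(subject.t1)))
    ll -= integral
    if subject.dropped:
        gap = subject.t2 - subject.t1
        ll += math.log1p(-math.exp(-gap * hz[status_at(subject.t1)]))
    else:
        ll -= (subject.study_end - subject.t1) * hz[status_at(subject.t1)]
    return ll


class TestImputation:
    def test_completer_unchanged(self):
        s = make_subject(times=DEFAULT_SCHEDULE, responses=[1] * 26)
        assert impute_post_dropout(s) == s

    def test_dropout_padded_to_schedule(self):
        s = make_subject(times=(28, 56), responses=(0, 1), dropped=True, t2=70.0)
        out = impute_post_dropout(s)
        assert len(out.observations) == 26
        assert out.observations[:2] == s.observations
        assert all(o.response == 0 for o in out.observations[2:])
        assert not out.dropped and out.t2 is None

    def test_zero_visit_subject_fully_imputed(self):
        s = make_subject(times=(), responses=(), dropped=True, t2=10.0)
        out = impute_post_dropout(s)
        assert len(out.observations) == 26
        assert {o.response for o in out.observations} == {0}

    def test_attended_visit_missing_from_schedule_rejected(self):
        s = make_subject(times=(14, 28), responses=(0, 0))
        with pytest.raises(DataConsistencyError, match="schedule"):
            impute_post_dropout(s, schedule=DEFAULT_SCHEDULE)


class TestBernoulliPart:
    def test_hand_computed_products(self, joint_spec):
        theta = ParameterVector(theta1=0.0, theta2=0.0)  # p = 0.5 everywhere
        s = make_subject(times=(28,), responses=(1,))
        assert loglik_imputed(s, theta, joint_spec) == pytest.approx(math.log(0.5))

    def test_two_visit_hand_product(self, b1_theta, joint_spec):
        s = make_subject(times=(28, 56), responses=(0, 1))
        p28 = response_probability(b1_theta, s.cov, joint_spec, 28.0)
        p56 = response_probability(b1_theta, s.cov, joint_spec, 56.0)
        expected = math.log1p(-p28) + math.log(p56)
        assert loglik_imputed(s, b1_theta, joint_spec) == pytest.approx(expected, abs=1e-12)

    def test_full_schedule_matches_per_visit_summation(self, b1_theta, joint_spec):
        rng = np.random.default_rng(5)
        responses = rng.integers(0, 2, size=26)
        s = make_subject(times=DEFAULT_SCHEDULE, responses=responses)
        expected = 0.0
        for t, y in zip(DEFAULT_SCHEDULE, responses):
            p = response_probability(b1_theta, s.cov, joint_spec, float(t))
            expected += math.log(p) if y else math.log1p(-p)
        assert loglik_imputed(s, b1_theta, joint_spec) == pytest.approx(expected, abs=1e-10)


class TestHazardPathAndSurvival:
    def test_no_responder_visits_constant_nr(self):
        s = make_subject(times=(28, 56), responses=(0, 0))
        path = hazard_path(s, 70.0)
        hz = HazardPair(hz_r=1.0, hz_nr=2.0)
        assert all(st == 0 for _, _, st in path.intervals)
        assert path.integral(hz) == pytest.approx(140.0)

    def test_carry_forward_switch(self):
        s = make_subject(times=(28, 56), responses=(0, 1), dropped=True, t2=70.0)
        hz = HazardPair(hz_r=0.5, hz_nr=2.0)
        path = hazard_path(s, 70.0)
        # NR on [0,56), R on [56,70)
        assert path.value(10.0, hz) == 2.0
        assert path.value(55.9, hz) == 2.0
        assert path.value(56.0, hz) == 0.5
        assert path.integral(hz) == pytest.approx(56 * 2.0 + 14 * 0.5)

    def test_equal_hazards_status_irrelevant(self):
        s = make_subject(times=(28, 56), responses=(1, 0))
        hz = HazardPair(hz_r=0.3, hz_nr=0.3)
        assert hazard_path(s, 100.0).integral(hz) == pytest.approx(30.0)

    def test_zero_hazard_survival_is_one(self):
        s = make_subject()
        assert survival_probability(s, HazardPair(0.0, 0.0), 728.0) == 1.0
        assert survival_probability(s, HazardPair(1.0, 1.0), 0.0) == 1.0

    def test_constant_nonresponder_through_study(self):
        s = make_subject(times=DEFAULT_SCHEDULE, responses=[0] * 26)
        hz_nr = math.exp(-6.82)
        p = survival_probability(s, HazardPair(hz_r=0.0, hz_nr=hz_nr), 728.0)
        assert p == pytest.approx(math.exp(-728 * hz_nr), rel=1e-12)
        assert p == pytest.approx(0.452, abs=5e-4)

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(11)
        for s in random_small_subjects(rng, 10):
            hz = HazardPair(hz_r=float(rng.uniform(0, 0.01)), hz_nr=float(rng.uniform(0, 0.01)))
            vals = [survival_probability(s, hz, u) for u in np.linspace(0, 728, 30)]
            assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


class TestDropoutProbability:
    def test_responder_gap_value(self):
        s = make_subject(times=(28, 56), responses=(0, 1), dropped=True, t2=70.0)
        hz = HazardPair(hz_r=math.exp(-8.46), hz_nr=1.0)
        expected = 1 - math.exp(-14 * math.exp(-8.46))
        assert dropout_probability(s, hz) == pytest.approx(expected, rel=1e-12)
        assert dropout_probability(s, hz) == pytest.approx(0.00295, abs=5e-5)

    def test_zero_and_infinite_hazard_limits(self):
        s = make_subject(times=(28,), responses=(0,), dropped=True, t2=40.0)
        assert dropout_probability(s, HazardPair(0.0, 0.0)) == 0.0
        assert dropout_probability(s, HazardPair(1e9, 1e9)) == pytest.approx(1.0)

    def test_non_dropout_rejected(self):
        s = make_subject()
        with pytest.raises(ValueError):
            dropout_probability(s, HazardPair(0.1, 0.1))


class TestJointLikelihood:
    def test_zero_hazard_completer_equals_imputed(self, b1_theta, joint_spec):
        theta = b1_theta.replace(log_hz_r=-700.0, log_hz_ratio=0.0)
        s = make_subject(times=DEFAULT_SCHEDULE, responses=[0, 1] * 13)
        assert loglik_joint(s, theta, joint_spec) == loglik_imputed(s, theta, joint_spec)

    def test_term_by_term_composition(self, b1_theta, joint_spec):
        s = make_subject(times=(28, 56), responses=(0, 1), dropped=True, t2=70.0)
        hz = b1_theta.hazards
        p28 = response_probability(b1_theta, s.cov, joint_spec, 28.0)
        p56 = response_probability(b1_theta, s.cov, joint_spec, 56.0)
        expected = (
            math.log1p(-p28)
            + math.log(p56)
            + math.log(survival_probability(s, hz, 56.0))
            + math.log(dropout_probability(s, hz))
        )
        assert loglik_joint(s, b1_theta, joint_spec) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_day_grid_oracle(self, b1_theta, joint_spec):
        rng = np.random.default_rng(99)
        for s in random_small_subjects(rng, 100):
            expected = day_grid_loglik_oracle(s, b1_theta, joint_spec)
            assert loglik_joint(s, b1_theta, joint_spec) == pytest.approx(
                expected, abs=1e-9
            )

    def test_generating_parameters_beat_perturbed_on_average(self, joint_spec, b1_theta):
        from renresp.synthetic import GeneratorConfig, simulate_trial

        perturbed = b1_theta.replace(theta2=3.5, log_hz_ratio=1.0)
        diffs = []
        for rep in range(5):
            ds = simulate_trial(GeneratorConfig(n_placebo=80, n_treated=80, seed=300 + rep))
            diffs.append(
                objective(ds, b1_theta, joint_spec) - objective(ds, perturbed, joint_spec)
            )
        assert np.mean(diffs) < 0


class TestObjective:
    def test_empty_and_single(self, b1_theta, joint_spec):
        assert objective([], b1_theta, joint_spec) == 0
        s = make_subject()
        assert objective([s], b1_theta, joint_spec) == pytest.approx(
            -2 * loglik_joint(s, b1_theta, joint_spec)
        )

    def test_additive_over_disjoint_subsets(self, b1_theta, joint_spec, small_trial):
        a, b = small_trial[:40], small_trial[40:]
        assert objective(a, b1_theta, joint_spec) + objective(
            b, b1_theta, joint_spec
        ) == pytest.approx(objective(small_trial, b1_theta, joint_spec), rel=1e-12)

    def test_error_carries_subject_id(self, b1_theta):
        spec = ModelSpec(cavg_metric="cavg12", dropout_strategy="joint")
        s = make_subject(sid="BAD1", trt=1)  # treated, no cavg12
        with pytest.raises(Exception, match="BAD1"):
            individual_objectives([s], b1_theta, spec)
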