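"""Forward simulation: weighted hazard, bands, exact binomial intervals."""

import math

import numpy as np
import pytest

from renresp.estimation import fit
from renresp.simulation import (
    clopper_pearson,
    marginal_hazard,
    observed_rates,
    sample_parameters,
    simulate_bands,
    simulated_responder_probability,
    survival_marginal,
)
from renresp.model_core import response_probability
from renresp.types import ParameterVector

from conftest import make_subject


@pytest.fixture(scope="module")
def fitted(full_trial, joint_spec):
    return fit(full_trial, joint_spec, n_starts=1)


class TestMarginalHazard:
    def test_degenerate_weights(self, joint_spec, median_cov):
        # p ~ 0 -> hz_nr; p ~ 1 -> hz_r
        low = ParameterVector(theta1=-40.0, log_hz_r=-8.0, log_hz_ratio=1.0)
        high = ParameterVector(theta1=40.0, log_hz_r=-8.0, log_hz_ratio=1.0)
        assert marginal_hazard(low, median_cov, joint_spec, 100.0) == pytest.approx(
            low.hz_nr, rel=1e-10
        )
        assert marginal_hazard(high, median_cov, joint_spec, 100.0) == pytest.approx(
            high.hz_r, rel=1e-10
        )

    def test_equal_hazards_constant(self, b1_theta, joint_spec, median_cov):
        theta = b1_theta.replace(log_hz_ratio=0.0)
        t = np.array([0.0, 100.0, 700.0])
        assert np.allclose(marginal_hazard(theta, median_cov, joint_spec, t), theta.hz_r)


class TestSurvivalMarginal:
    def test_zero_hazard_is_one(self, b1_theta, joint_spec, median_cov):
        theta = b1_theta.replace(log_hz_r=-700.0)
        assert survival_marginal(theta, median_cov, joint_spec, 500.0) == pytest.approx(1.0)

    def test_constant_hazard_closed_form(self, joint_spec, median_cov):
        theta = ParameterVector(theta1=0.3, theta2=0.0, log_hz_r=-7.0, log_hz_ratio=0.0)
        h = theta.hz_r
        for t in (0.0, 28.0, 728.0):
            assert survival_marginal(theta, median_cov, joint_spec, t) == pytest.approx(
                math.exp(-h * t), abs=1e-8
            )

    def test_quadrature_refinement(self, b1_theta, joint_spec, median_cov):
        t = 728.0
        coarse = survival_marginal(b1_theta, median_cov, joint_spec, t, step=1.0)
        fine = survival_marginal(b1_theta, median_cov, joint_spec, t, step=0.5)
        assert abs(coarse - fine) < 1e-6


class TestSimulatedResponderProbability:
    def test_zero_hazard_equals_on_treatment(self, b1_theta, joint_spec, median_cov):
        theta = b1_theta.replace(log_hz_r=-700.0)
        t = np.array([28.0, 364.0, 728.0])
        assert np.allclose(
            simulated_responder_probability(theta, median_cov, joint_spec, t),
            response_probability(theta, median_cov, joint_spec, t),
        )

    def test_never_exceeds_on_treatment_probability(self, b1_theta, joint_spec, median_cov):
        t = np.linspace(0, 728, 27)
        sim = simulated_responder_probability(b1_theta, median_cov, joint_spec, t)
        p = response_probability(b1_theta, median_cov, joint_spec, t)
        assert np.all(sim <= p + 1e-15)

    def test_composition_at_study_end(self, b1_theta, joint_spec, median_cov):
        p = 1.0 / (1.0 + math.exp(-(0.161 - 4.61 * math.exp(-0.0117 * 728))))
        s = survival_marginal(b1_theta, median_cov, joint_spec, 728.0)
        assert simulated_responder_probability(
            b1_theta, median_cov, joint_spec, 728.0
        ) == pytest.approx(p * s, rel=1e-10)


class TestSampleParameters:
    def test_zero_covariance_collapses(self, fitted):
        import copy

        frozen = copy.copy(fitted)
        frozen.covariance = np.zeros_like(fitted.covariance)
        draws = sample_parameters(frozen, 10, seed=1)
        assert all(d == fitted.theta_hat for d in draws)

    def test_seed_determinism_and_mean(self, fitted):
        a = sample_parameters(fitted, 200, seed=42)
        b = sample_parameters(fitted, 200, seed=42)
        assert a == b
        big = sample_parameters(fitted, 10_000, seed=7)
        mean_t2 = np.mean([d.theta2 for d in big])
        se = fitted.se["theta2"]
        assert mean_t2 == pytest.approx(fitted.theta_hat.theta2, abs=4 * se / 100.0)


class TestSimulateBands:
    def test_single_subject_zero_covariance_collapses_to_curve(self, fitted, joint_spec):
        import copy

        frozen = copy.copy(fitted)
        frozen.covariance = np.zeros_like(fitted.covariance)
        subject = make_subject(trt=0, prot_bl=2.5, times=(28,), responses=(0,))
        grid = [28.0, 364.0, 728.0]
        bands = simulate_bands(frozen, [subject], time_grid=grid, n_samples=20, seed=3)
        assert len(bands) == 1
        b = bands[0]
        expected = simulated_responder_probability(
            fitted.theta_hat, subject.cov, joint_spec, np.array(grid)
        )
        assert np.allclose(b.median, expected, atol=1e-10)
        assert np.allclose(b.pi_low, expected, atol=1e-10)
        assert np.allclose(b.pi_high, expected, atol=1e-10)

    def test_band_ordering_and_range(self, fitted, full_trial):
        bands = simulate_bands(fitted, full_trial[:100], n_samples=30, seed=9)
        for b in bands:
            assert np.all(b.pi_low <= b.median + 1e-12)
            assert np.all(b.median <= b.pi_high + 1e-12)
            assert np.all((b.median >= 0) & (b.median <= 1))

    def test_default_strata_structure(self, fitted, full_trial):
        bands = simulate_bands(fitted, full_trial, n_samples=5, seed=2)
        labels = {b.stratum for b in bands}
        assert labels == {
            "placebo prot<2.5",
            "placebo prot>=2.5",
            "belimumab prot<2.5",
            "belimumab prot>=2.5",
        }

    def test_median_invariant_to_subject_order(self, fitted, full_trial):
        subjects = full_trial[:60]
        b1 = simulate_bands(fitted, subjects, n_samples=10, seed=4)
        b2 = simulate_bands(fitted, list(reversed(subjects)), n_samples=10, seed=4)
        for x, y in zip(b1, b2):
            assert x.stratum == y.stratum
            assert np.allclose(x.median, y.median)


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_half_of_ten(self):
        low, high = clopper_pearson(5, 10)
        assert low == pytest.approx(0.187, abs=1e-3)
        assert high == pytest.approx(0.813, abs=1e-3)

    def test_matches_statsmodels_beta_method(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(0, 7), (3, 9), (5, 10), (11, 11), (40, 100)]:
            lo, hi = clopper_pearson(k, n)
            slo, shi = statsmodels.proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(float(slo), abs=1e-10)
            assert hi == pytest.approx(float(shi), abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(-1, 10)
        with pytest.raises(ValueError):
            clopper_pearson(3, 0)


class TestObservedRates:
    def test_hand_enumerated_toy_dataset(self):
        subjects = [
            make_subject(sid="A", times=(28, 56), responses=(0, 1)),
            make_subject(sid="B", times=(28, 56), responses=(1, 1)),
            make_subject(sid="C", times=(28,), responses=(0,), dropped=True, t2=40.0),
            make_subject(sid="D", times=(), responses=(), dropped=True, t2=5.0),
        ]
        schedule = (28, 56)
        imp = observed_rates(subjects, schedule, strategy="impute_nonresponder")
        # day 28: A=0, B=1, C=0, D=0 -> 1/4; day 56: A=1, B=1, C->0, D->0 -> 2/4
        assert [(r.k, r.n) for r in imp] == [(1, 4), (2, 4)]
        ontrt = observed_rates(subjects, schedule, strategy="on_treatment")
        # day 28: A, B, C observed -> 1/3; day 56: A, B -> 2/2
        assert [(r.k, r.n) for r in ontrt] == [(1, 3), (2, 2)]
        for r in imp + ontrt:
            assert r.ci_low <= r.rate <= r.ci_high

    def test_no_dropouts_strategies_identical(self):
        subjects = [
            make_subject(sid=f"S{i}", times=(28, 56), responses=(i % 2, 1))
            for i in range(6)
        ]
        a = observed_rates(subjects, (28, 56), "impute_nonresponder")
        b = observed_rates(subjects, (28, 56), "on_treatment")
        assert [(r.k, r.n) for r in a] == [(r.k, r.n) for r in b]

    def test_all_dropped_point_omitted_on_treatment(self):
        subjects = [
            make_subject(sid=f"S{i}", times=(), responses=(), dropped=True, t2=3.0)
            for i in range(5)
        ]
        imp = observed_rates(subjects, (28,), "impute_nonresponder")
        assert [(r.k, r.n, r.rate) for r in imp] == [(0, 5, 0.0)]
        assert observed_rates(subjects, (28,), "on_treatment") == []

    def test_empirical_coverage_of_exact_interval(self):
        rng = np.random.default_rng(17)
        n, p = 40, 0.3
        ks = rng.binomial(n, p, size=2000)
        covered = 0
        for k in ks:
            lo, hi = clopper_pearson(int(k), n)
            covered += lo <= p <= hi
        assert covered / len(ks) >= 0.95
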