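"""IRT mixture model tests: density, fitting, classification, segmentation."""

import numpy as np
import pytest
from scipy.integrate import quad

from pavpupil import bouts
from pavpupil.bouts import PAUSE, WITHIN_BOUT, IRTMixtureParams

from conftest import pooled_irts


class TestComputeIrts:
    @pytest.mark.parametrize(
        "licks,expected",
        [([0.1, 0.2, 1.5], [0.1, 1.3]), ([0.0, 1.0], [1.0])],
    )
    def test_definition(self, licks, expected):
        np.testing.assert_allclose(bouts.compute_irts(licks), expected)

    def test_single_lick_errors(self):
        with pytest.raises(ValueError):
            bouts.compute_irts([5.0])


class TestMixtureDensity:
    def test_single_component_limit(self):
        """As q -> 1 the density at 0 approaches w."""
        p = IRTMixtureParams(q=1 - 1e-12, w=8.0, b=0.3)
        assert bouts.mixture_logdensity(p, 0.0) == pytest.approx(np.log(8.0), abs=1e-9)

    def test_equal_rates_collapse_to_exponential(self):
        """With w = b = lambda the mixture is Exp(lambda) for any q.

        (w = b violates the fitted-parameter ordering, so evaluate the
        normalized form directly.)"""
        lam, q = 2.0, 0.37
        tau = np.linspace(0, 5, 50)
        direct = np.log(q * lam * np.exp(-lam * tau) + (1 - q) * lam * np.exp(-lam * tau))
        np.testing.assert_allclose(direct, np.log(lam) - lam * tau, atol=1e-12)

    def test_normalization_quadrature(self):
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        integral, _ = quad(lambda t: np.exp(bouts.mixture_logdensity(p, t)), 0, 200)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_normalization_random_parameters(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            b = rng.uniform(0.05, 2.0)
            w = b * rng.uniform(1.5, 50.0)
            q = rng.uniform(0.05, 0.95)
            p = IRTMixtureParams(q=q, w=w, b=b)
            integral, _ = quad(
                lambda t: np.exp(bouts.mixture_logdensity(p, t)), 0, 400 / b, limit=200
            )
            assert integral == pytest.approx(1.0, abs=1e-6)

    def test_negative_tau_rejected(self):
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        with pytest.raises(ValueError):
            bouts.mixture_logdensity(p, -0.1)


class TestFitMixture:
    def test_recovers_generating_parameters(self, gain_free_config):
        tau = pooled_irts(gain_free_config, 5000, seed0=500)
        fit = bouts.fit_mixture(tau, seed=0)
        assert fit.converged
        assert fit.q == pytest.approx(0.7, rel=0.10)
        assert fit.w == pytest.approx(8.0, rel=0.10)
        assert fit.b == pytest.approx(0.3, rel=0.10)

    def test_error_shrinks_with_sample_size(self, gain_free_config):
        errs = []
        for n in (500, 5000, 50000):
            tau = pooled_irts(gain_free_config, n, seed0=700)
            fit = bouts.fit_mixture(tau, seed=0)
            errs.append(
                abs(fit.q - 0.7) / 0.7 + abs(fit.w - 8) / 8 + abs(fit.b - 0.3) / 0.3
            )
        assert errs[2] < errs[0]
        assert errs[1] < errs[0]

    def test_single_exponential_data_nests(self):
        """On Exp(5) data the fitted mixture log-likelihood is within 1e-3
        of (and effectively never below) the single-exponential maximum."""
        rng = np.random.default_rng(4)
        tau = rng.exponential(1 / 5.0, size=2000)
        fit = bouts.fit_mixture(tau, seed=0)
        lam = 1.0 / tau.mean()
        ll_single = len(tau) * np.log(lam) - lam * tau.sum()
        assert fit.loglik >= ll_single - 1e-3
        assert fit.loglik - ll_single < 2.0  # no spurious structure invented

    def test_deterministic_given_seed(self, gain_free_config):
        tau = pooled_irts(gain_free_config, 2000, seed0=800)
        f1 = bouts.fit_mixture(tau, seed=3)
        f2 = bouts.fit_mixture(tau, seed=3)
        assert (f1.q, f1.w, f1.b) == (f2.q, f2.w, f2.b)

    def test_too_few_irts_errors(self):
        with pytest.raises(ValueError, match="at least"):
            bouts.fit_mixture(np.ones(10))

    def test_bayes_mode_agrees_roughly_with_mle(self, gain_free_config):
        tau = pooled_irts(gain_free_config, 1500, seed0=900)
        fit = bouts.fit_mixture(tau, method="bayes", seed=0, n_steps=600, n_burn=200)
        assert fit.method == "bayes"
        assert fit.q == pytest.approx(0.7, rel=0.2)
        assert fit.w == pytest.approx(8.0, rel=0.2)
        assert fit.b == pytest.approx(0.3, rel=0.2)


class TestClassification:
    def test_threshold_closed_form(self):
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        expected = np.log(0.7 * 8.0 / (0.3 * 0.3)) / 7.7
        assert bouts.classification_threshold(p) == pytest.approx(expected, rel=1e-12)
        assert bouts.classification_threshold(p) == pytest.approx(0.536, abs=5e-3)

    def test_threshold_symmetric_example(self):
        p = IRTMixtureParams(q=0.5, w=2.0, b=1.0)
        assert bouts.classification_threshold(p) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_equal_rates_error(self):
        with pytest.raises(ValueError):
            bouts.classification_threshold(IRTMixtureParams(q=0.5, w=2.0, b=2.0))

    def test_threshold_matches_grid_crossover(self):
        """Dense grid search for the component-likelihood crossover agrees
        with the closed form."""
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        grid = np.linspace(0, 5, 2_000_001)
        fast = np.log(p.q) + np.log(p.w) - p.w * grid
        slow = np.log1p(-p.q) + np.log(p.b) - p.b * grid
        crossover = grid[np.argmax(fast <= slow)]
        assert crossover == pytest.approx(bouts.classification_threshold(p), abs=5e-6)

    @pytest.mark.parametrize("tau,expected", [(0.1, WITHIN_BOUT), (5.0, PAUSE)])
    def test_examples(self, tau, expected):
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        assert bouts.classify_licks([tau], p)[0] == expected

    def test_classification_equals_threshold_rule(self):
        """Likelihood comparison is identical to thresholding at tau* for
        10,000 random IRTs (ties -> pause)."""
        rng = np.random.default_rng(5)
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        tau = rng.uniform(0, 10, size=10000)
        tstar = bouts.classification_threshold(p)
        oracle = np.where(tau < tstar, WITHIN_BOUT, PAUSE)
        np.testing.assert_array_equal(bouts.classify_licks(tau, p), oracle)

    def test_all_pause_when_threshold_nonpositive(self):
        # q w <= (1-q) b: fast component never dominates
        p = IRTMixtureParams(q=0.01, w=1.0, b=0.99)
        assert bouts.classification_threshold(p) <= 0
        labels = bouts.classify_licks(np.linspace(0.01, 5, 100), p)
        assert (labels == PAUSE).all()


class TestSegmentation:
    def test_two_bout_example(self):
        licks = np.array([0.0, 0.1, 0.2, 5.0, 5.1])
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        labels = bouts.classify_licks(bouts.compute_irts(licks), p)
        seg = bouts.segment_bouts(licks, labels)
        np.testing.assert_allclose(seg.bout_onsets, [0.0, 5.0])
        np.testing.assert_allclose(seg.bout_offsets, [0.2, 5.1])
        np.testing.assert_array_equal(seg.licks_per_bout, [3, 2])

    def test_all_pause_labels_no_bouts(self):
        licks = np.array([0.0, 10.0, 20.0, 30.0])
        labels = np.array([PAUSE] * 3)
        seg = bouts.segment_bouts(licks, labels)
        assert len(seg.bout_onsets) == 0
        assert seg.n_discarded_runs == 4
        assert seg.n_discarded_licks == 4

    def test_single_long_bout(self):
        licks = np.arange(0, 1.0, 0.1)
        labels = np.array([WITHIN_BOUT] * (len(licks) - 1))
        seg = bouts.segment_bouts(licks, labels)
        assert len(seg.bout_onsets) == 1
        assert seg.bout_onsets[0] == 0.0
        assert seg.licks_per_bout[0] == len(licks)

    def test_lick_count_conserved(self, config):
        """Total licks = retained-bout licks + discarded-run licks."""
        from pavpupil import synthetic as syn

        sch = syn.gen_schedule("contingent", 40, config, seed=6)
        licks = syn.gen_licks(sch, config, seed=6)
        p = IRTMixtureParams(q=0.7, w=8.0, b=0.3)
        labels = bouts.classify_licks(bouts.compute_irts(licks), p)
        seg = bouts.segment_bouts(licks, labels)
        assert seg.licks_per_bout.sum() + seg.n_discarded_licks == len(licks)
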