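import numpy as np
import pytest

from ensfilter.exact_filter import (baseline_input_only, baseline_mixed_rates,
                                    evidence_posterior_closed_form,
                                    integrate_bayes, integrate_context,
                                    integrate_evidence,
                                    integrate_evidence_epsp)
from ensfilter.generative import CTMCSpec, ContextSchedule, ObservationModel
from ensfilter.spiking_core import SpikeRaster


def raster(times, neurons):
    return SpikeRaster(neuron_id=np.asarray(neurons),
                       time_ms=np.asarray(times, dtype=float))


@pytest.fixture
def two_state_model():
    return ObservationModel(lam=np.array([[5.0, 1.0], [1.0, 5.0]]),
                            baseline=1.0)


class TestEvidenceIntegration:
    def test_no_spikes_equal_decay_keeps_prior(self, two_state_model):
        prior = np.array([0.3, 0.7])
        tr = integrate_evidence(prior, two_state_model, raster([], []), 100.0)
        assert np.allclose(tr.probs[-1], prior, atol=1e-12)

    def test_single_spike_posterior(self, two_state_model):
        # equal lam_bar: one spike from afferent 0 gives odds 5:1
        tr = integrate_evidence(np.array([0.5, 0.5]), two_state_model,
                                raster([10.0], [0]), 20.0)
        assert tr.at(15.0) == pytest.approx([5 / 6, 1 / 6])

    def test_repeated_spikes_multiply_likelihood_ratios(self, two_state_model):
        prior = np.array([0.4, 0.6])
        tr = integrate_evidence(prior, two_state_model,
                                raster([5.0, 10.0], [0, 0]), 20.0)
        odds = tr.probs[-1][0] / tr.probs[-1][1]
        assert odds == pytest.approx((prior[0] / prior[1]) * 25.0)

    def test_zero_rate_entry_rejected(self):
        model = ObservationModel.__new__(ObservationModel)
        model.lam = np.array([[1.0, 0.0], [1.0, 1.0]])
        model.baseline = 1e-6
        with pytest.raises(ValueError):
            integrate_evidence(np.array([0.5, 0.5]), model, raster([], []),
                               10.0)

    def test_integrator_matches_closed_form(self):
        """Per-bin integration reproduces the closed-form solution."""
        rng = np.random.default_rng(0)
        lam = rng.uniform(0.5, 20.0, size=(3, 4))
        model = ObservationModel(lam=lam, baseline=0.5)
        prior = rng.dirichlet(np.ones(3))
        times = np.sort(rng.choice(np.arange(1, 400) * 0.5, 12,
                                   replace=False))
        neurons = rng.integers(0, 4, size=12)
        r = raster(times, neurons)
        tr = integrate_evidence(prior, model, r, 200.0)
        for t in (50.0, 125.0, 200.0):
            cf = evidence_posterior_closed_form(prior, model, r, t)
            assert np.allclose(tr.at(t), cf, rtol=1e-6)


class TestEPSPEquivalence:
    def test_epsp_route_reproduces_point_event_solution(self):
        """Integrating EPSP-weighted traces equals the point-event filter
        once every EPSP has been fully integrated, for any weight shift."""
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.5, 15.0, size=(3, 3))
        model = ObservationModel(lam=lam, baseline=0.5)
        prior = rng.dirichlet(np.ones(3))
        r = raster([10.0, 30.0, 42.5, 60.0], [0, 2, 1, 0])
        exact = evidence_posterior_closed_form(prior, model, r, 100.0)
        for shift in (None, 0.0, 3.7):
            tr = integrate_evidence_epsp(prior, model, r, 100.0, tau=20.0,
                                         shift=shift)
            assert np.allclose(tr.at(100.0), exact, rtol=1e-9)

    def test_epsp_route_lags_during_open_epsps(self):
        model = ObservationModel(lam=np.array([[5.0, 1.0], [1.0, 5.0]]),
                                 baseline=1.0)
        prior = np.array([0.5, 0.5])
        r = raster([10.0], [0])
        tr = integrate_evidence_epsp(prior, model, r, 40.0, tau=20.0)
        # mid-EPSP the update is only partially integrated
        mid = tr.at(20.0)[0]
        assert 0.5 < mid < 5 / 6
        assert tr.at(35.0) == pytest.approx([5 / 6, 1 / 6], rel=1e-9)


class TestBayesFilter:
    def test_zero_rates_reduce_to_evidence_integration(self, two_state_model):
        prior = np.array([0.3, 0.7])
        r = raster([5.0, 12.0], [1, 0])
        ev = integrate_evidence(prior, two_state_model, r, 50.0)
        by = integrate_bayes(prior, two_state_model,
                             CTMCSpec(rates=np.zeros((2, 2))), r, 50.0)
        assert np.allclose(ev.probs, by.probs, atol=1e-12)

    def test_pure_decay_matches_analytic_exponential(self):
        # q_{1->2} = r, no evidence: p_1(t) = p_1(0) exp(-r t)
        q = 12.0
        ctmc = CTMCSpec(rates=np.array([[0.0, q], [0.0, 0.0]]))
        prior = np.array([0.8, 0.2])
        tr = integrate_bayes(prior, None, ctmc, None, 50.0)
        t = tr.times * 1e-3
        assert np.allclose(tr.probs[:, 0], prior[0] * np.exp(-q * t),
                           atol=2e-3)

    def test_rows_are_normalized(self, two_state_model):
        ctmc = CTMCSpec(rates=np.array([[0.0, 3.0], [1.0, 0.0]]))
        tr = integrate_bayes(np.array([0.5, 0.5]), two_state_model, ctmc,
                             raster([7.5], [0]), 30.0)
        assert np.allclose(tr.probs.sum(axis=1), 1.0, atol=1e-12)


class TestContextFilter:
    @pytest.fixture
    def ctx_ctmc(self):
        qa = np.array([[0.0, 4.0], [0.0, 0.0]])
        qb = np.array([[0.0, 0.0], [4.0, 0.0]])
        return CTMCSpec(rates=(qa + qb) / 2, context_rates=np.stack([qa, qb]))

    def test_single_context_equals_plain_filter(self, ctx_ctmc,
                                                two_state_model):
        sched = ContextSchedule(times=np.array([0.0]),
                                contexts=np.array([0]), T=50.0, n_contexts=2)
        prior = np.array([0.6, 0.4])
        r = raster([10.0], [0])
        a = integrate_context(prior, two_state_model, ctx_ctmc, sched, r,
                              50.0)
        b = integrate_bayes(prior, two_state_model,
                            CTMCSpec(rates=ctx_ctmc.context_rates[0]), r,
                            50.0)
        assert np.allclose(a.probs, b.probs, atol=1e-12)

    def test_graded_5050_belief_is_mean_matrix(self, ctx_ctmc):
        prior = np.array([0.9, 0.1])
        nb = 100
        belief = np.full((nb, 2), 0.5)
        a = integrate_context(prior, None, ctx_ctmc, belief, None, 50.0)
        b = integrate_bayes(prior, None, baseline_mixed_rates(ctx_ctmc),
                            None, 50.0)
        assert np.allclose(a.probs, b.probs, atol=1e-12)

    def test_piecewise_context_matches_fine_grid_oracle(self, ctx_ctmc,
                                                        two_state_model):
        """Coarse-grid filter vs brute-force fine-step integration."""
        sched = ContextSchedule(times=np.array([0.0, 25.0]),
                                contexts=np.array([0, 1]), T=60.0,
                                n_contexts=2)
        prior = np.array([0.5, 0.5])
        r = raster([10.0, 40.0], [0, 1])
        coarse = integrate_context(prior, two_state_model, ctx_ctmc, sched,
                                   r, 60.0, dt=0.5)
        fine = integrate_context(prior, two_state_model, ctx_ctmc, sched,
                                 r, 60.0, dt=0.05)
        dev = np.abs(coarse.probs - fine.probs[::10]).max()
        assert dev < 1e-3

    def test_missing_context_rejected(self, ctx_ctmc, two_state_model):
        with pytest.raises(ValueError):
            integrate_context(np.array([0.5, 0.5]), two_state_model,
                              ctx_ctmc, np.full((10, 2), 0.5), raster([], []),
                              50.0)  # belief trace shorter than [0, T]


class TestBaselines:
    def test_input_only_holds_uniform_without_observations(self,
                                                           two_state_model):
        tr = baseline_input_only(two_state_model, raster([], []), 20.0)
        assert np.allclose(tr.probs, 0.5)

    def test_input_only_single_spike_held_thereafter(self, two_state_model):
        tr = baseline_input_only(two_state_model, raster([5.0], [0]), 40.0)
        assert tr.at(30.0) == pytest.approx([5 / 6, 1 / 6])
        assert tr.at(39.5) == pytest.approx([5 / 6, 1 / 6])

    def test_simultaneous_spikes_multiply_likelihoods(self, two_state_model):
        tr = baseline_input_only(two_state_model, raster([5.0, 5.0], [0, 1]),
                                 10.0)
        # both afferents spike in the same bin: 5*1 vs 1*5 -> uniform
        assert tr.at(6.0) == pytest.approx([0.5, 0.5])

    def test_mixed_rates_mean(self):
        qa = np.array([[0.0, 3.5], [0.0, 0.0]])
        qb = np.array([[0.0, 0.0], [3.5, 0.0]])
        mixed = baseline_mixed_rates(CTMCSpec(rates=qa,
                                              context_rates=np.stack([qa,
                                                                      qb])))
        assert mixed.rates[0, 1] == pytest.approx(1.75)
        assert mixed.rates[1, 0] == pytest.approx(1.75)

    def test_mixed_rates_needs_contexts(self):
        with pytest.raises(ValueError):
            baseline_mixed_rates(CTMCSpec(rates=np.zeros((2, 2))))
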