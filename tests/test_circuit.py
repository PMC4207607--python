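import numpy as np
import pytest

from ensfilter.circuit import (CircuitSimulator, build_circuit,
                               build_readout_layer, disinhibition_gate,
                               lateral_inhibition, run_circuit)
from ensfilter.generative import ObservationModel


@pytest.fixture
def two_state_obs():
    return ObservationModel(lam=np.array([[5.0, 1.0], [1.0, 5.0]]),
                            baseline=1.0)


class TestBuilder:
    def test_task_b_dynamics_weights_are_pure_copy(self, two_state_obs):
        spec = build_circuit(N=2, K=100, S=40.0, obs_model=two_state_obs)
        v = spec.v[0]
        assert np.allclose(np.diag(v), 1.0 / (100 * 0.020))
        assert np.allclose(v - np.diag(np.diag(v)), 0.0)

    def test_task_c_off_diagonal_proportional_to_rates(self):
        q = np.array([[0.0, 7.0], [0.0, 0.0]])
        spec = build_circuit(N=2, K=100, S=40.0, rates=q)
        v = spec.v[0]
        assert v[1, 0] == pytest.approx(7.0 / 100)  # into ensemble 2
        assert v[0, 1] == 0.0  # no transitions into ensemble 1
        # self weight preserves total outflow: row sums K*v = 1/tau
        assert np.allclose((v * 100).sum(axis=0), 1.0 / 0.020)

    def test_evidence_weights_shifted_non_negative(self, two_state_obs):
        spec = build_circuit(N=2, K=100, S=40.0, obs_model=two_state_obs)
        assert np.all(spec.w_ev >= 0)
        # per-afferent shift: smallest log-rate maps to zero
        assert np.isclose(spec.w_ev.min(axis=0), 0.0).all()
        ratio = np.exp(spec.w_ev[0, 0] * 0.020)
        assert ratio == pytest.approx(5.0)

    def test_excessive_outflow_rejected(self):
        q = np.array([[0.0, 60.0], [0.0, 0.0]])  # > 1/tau = 50 Hz
        with pytest.raises(ValueError):
            build_circuit(N=2, K=100, S=40.0, rates=q)

    def test_nonpositive_lambda_rejected(self):
        bad = ObservationModel.__new__(ObservationModel)
        bad.lam = np.array([[1.0, 0.0], [1.0, 1.0]])
        bad.baseline = 1e-9
        with pytest.raises(ValueError):
            build_circuit(N=2, K=10, S=4.0, obs_model=bad)


class TestInhibition:
    def test_zero_at_or_below_target(self):
        assert lateral_inhibition(400.0, 400.0, 1.0, 20.0) == 0.0
        assert lateral_inhibition(300.0, 400.0, 1.0, 20.0) == 0.0

    def test_scales_excess_by_nu_over_tau(self):
        assert lateral_inhibition(440.0, 400.0, 1.0, 20.0) == pytest.approx(
            2000.0)

    def test_optional_cap(self):
        assert lateral_inhibition(800.0, 400.0, 1.0, 20.0,
                                  cap=500.0) == 500.0


class TestDisinhibition:
    def test_silent_gater_suppresses(self):
        assert disinhibition_gate(0.0, theta=0.5, I_base=1e3) == -1e3

    def test_single_recent_spike_releases(self):
        assert disinhibition_gate(1.0, theta=0.5) == 0.0

    def test_saturating_above_threshold(self):
        assert disinhibition_gate(2.0, theta=0.5) == 0.0


class TestReadout:
    def test_identity_conditional_copies_distribution(self):
        spec = build_readout_layer(np.eye(3), K_out=200, sample_scale=0.5)
        A_in = np.array([30.0, 50.0, 20.0])
        drive = spec.weights @ A_in
        # steady-state mass = drive * tau = 0.5 * A_in -> same distribution
        out = drive / drive.sum()
        assert np.allclose(out, A_in / A_in.sum())

    def test_color_marginalization_weights(self):
        from ensfilter.scenarios import _color_marginal_conditionals
        cond = _color_marginal_conditionals()
        spec = build_readout_layer(cond, K_out=100, sample_scale=0.2)
        A_in = np.zeros(16)
        A_in[2 * 3 + 0] = 100.0  # direction 3, red
        A_in[2 * 3 + 1] = 60.0  # direction 3, blue
        drive = spec.weights @ A_in
        assert np.argmax(drive) == 3
        assert drive[np.arange(8) != 3].sum() == 0.0

    def test_invalid_conditionals_rejected(self):
        with pytest.raises(ValueError):
            build_readout_layer(np.array([[0.5, 0.4]]), 10, 1.0)

    def test_readout_mean_matches_marginalized_posterior(self):
        """Monte Carlo readout estimate is unbiased for sum_i P(x|z_i) p_i."""
        rng = np.random.default_rng(7)
        cond = rng.dirichlet(np.ones(3), size=3)  # random 3x3 table
        p_in = np.array([0.5, 0.3, 0.2])
        S_in = 200.0
        spec = build_readout_layer(cond, K_out=500, sample_scale=0.4)
        expect = cond.T @ p_in
        est = []
        for _ in range(200):
            A_in = rng.poisson(S_in * p_in).astype(float)
            drive = spec.weights @ A_in
            counts = rng.poisson(drive * 500 * 0.020 / 500)
            # one-window snapshot of the readout layer's spike counts
            tot = counts.sum()
            if tot:
                est.append(counts / tot)
        m = np.mean(est, axis=0)
        se = np.std(est, axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(m - expect) < 3 * se + 1e-3)


class TestSimulator:
    def test_uniform_task_b_circuit_is_stationary_in_expectation(self):
        """Without evidence the copy circuit holds mass S and the expected
        distribution stays uniform (single runs diffuse: the represented
        ratio is a critical branching process)."""
        spec = build_circuit(N=2, K=1000, S=200.0)
        rng = np.random.default_rng(0)
        finals, masses = [], []
        for _ in range(20):
            res = run_circuit(spec, None, 500, np.array([0.5, 0.5]),
                              rng.spawn(1)[0])
            finals.append(res.trace.probs[-1, 0])
            masses.append(res.total_mass.mean())
        finals = np.array(finals)
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(np.nanmean(finals) - 0.5) < 3 * se
        assert abs(np.mean(masses) - 200.0) < 0.15 * 200.0

    def test_gater_silence_suppresses_all_spiking(self, two_state_obs):
        """A state whose dynamics-layer partner ensembles never spike can
        produce no evidence-layer spikes (rectified gating)."""
        spec = build_circuit(N=2, K=50, S=10.0, obs_model=two_state_obs)
        sim = CircuitSimulator(spec, np.random.default_rng(1))
        sim.initialize(np.array([1.0, 0.0]))  # no particles in state 1
        for b in range(200):
            sim.step(np.array([5, 5]))  # heavy evidence for both states
        assert sim.masses[1] == 0.0

    def test_membrane_assembly_matches_hand_computation(self, two_state_obs):
        """One simulation bin reproduces the hand-computed spike
        probabilities of the membrane equations."""
        spec = build_circuit(N=2, K=10, S=4.0, obs_model=two_state_obs)
        sim = CircuitSimulator(spec, np.random.default_rng(2))
        sim.initialize(np.array([0.5, 0.5]))
        A = sim.masses.copy()
        total = A.sum()
        y = np.array([1.0, 0.0])  # one fresh spike from afferent 0
        sim.step(y.astype(int))
        tau_s, dt_s = 0.020, 0.5e-3
        I = spec.nu * max(total - spec.S, 0.0) / tau_s
        uE = spec.w_ev @ y + spec.bias - I
        np.testing.assert_allclose(sim.last_pE,
                                   np.clip(uE * dt_s, 0, 1))
        uD = spec.v[0] @ A
        np.testing.assert_allclose(sim.last_pD.ravel()[:2],
                                   np.clip(uD * dt_s, 0, 1), rtol=1e-12)

    def test_gating_matches_product_rule_under_sparse_activity(self):
        """Ensemble rate under per-neuron gating equals the product
        A_D * u within 3 SE when activity is sparse (S << K)."""
        K, A_D, u, dt_s = 4000, 100, 60.0, 0.5e-3
        rng = np.random.default_rng(3)
        n_bins = 1000
        counts = []
        for _ in range(n_bins):
            slots = rng.integers(0, K, size=A_D)  # gater spikes in window
            released = np.zeros(K, dtype=bool)
            released[slots] = True
            counts.append(rng.random(K)[released].__lt__(u * dt_s).sum())
        mean_rate = np.mean(counts)
        expect = A_D * u * dt_s
        se = np.std(counts, ddof=1) / np.sqrt(n_bins)
        assert abs(mean_rate - expect) < 3 * se + 0.05 * expect

    def test_disabling_gate_breaks_multiplication(self, monkeypatch):
        """With the disinhibition gate forced open the posterior no longer
        tracks the Bayesian update."""
        import ensfilter as ef
        import ensfilter.scenarios as sn
        from ensfilter.circuit import build_circuit as orig_build
        sc = ef.make_scenario('fig5_evidence')
        devs = {}
        for theta in (0.5, 0.0):
            def patched(*a, _theta=theta, **kw):
                kw["gate_theta"] = _theta
                return orig_build(*a, **kw)
            monkeypatch.setattr(sn, "build_circuit", patched)
            rng = np.random.default_rng(4)
            d = [abs((r := sn.run_fig5_trial(sc, rng.spawn(1)[0]))
                     ["p_circuit"] - r["p_oracle"]) for _ in range(8)]
            devs[theta] = np.mean(d)
        assert devs[0.0] > devs[0.5]

    def test_determinism_under_fixed_seed(self, two_state_obs):
        spec = build_circuit(N=2, K=200, S=40.0, obs_model=two_state_obs)
        aff = np.zeros((200, 2), dtype=int)
        aff[40, 0] = 1
        runs = [run_circuit(spec, aff, 200, np.array([0.5, 0.5]),
                            np.random.default_rng(11)) for _ in range(2)]
        assert np.array_equal(runs[0].masses, runs[1].masses)
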