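import numpy as np
import pytest

from ensfilter.generative import (CTMCSpec, ContextSchedule, ObservationModel,
                                  StatePath, gaussian_tuning,
                                  sample_context_spikes, sample_ctmc_path,
                                  sample_observation_spikes,
                                  stationary_distribution)


class TestCTMC:
    def test_zero_rates_give_constant_path(self):
        spec = CTMCSpec(rates=np.zeros((3, 3)))
        path = sample_ctmc_path(spec, 1, 5000.0, np.random.default_rng(0))
        assert list(path.states) == [1]

    def test_mean_sojourn_matches_exponential(self):
        # q_{1->2} = 1 Hz: mean sojourn in state 1 is 1 s
        spec = CTMCSpec(rates=np.array([[0.0, 1.0], [0.0, 0.0]]))
        rng = np.random.default_rng(1)
        sojourns = []
        for _ in range(1000):
            p = sample_ctmc_path(spec, 0, 20_000.0, rng)
            if p.times.size > 1:
                sojourns.append(p.times[1])
        s = np.array(sojourns)
        se = s.std(ddof=1) / np.sqrt(s.size)
        assert abs(s.mean() - 1000.0) < 3 * se

    def test_occupancy_matches_stationary_distribution(self):
        rng = np.random.default_rng(2)
        Q = np.array([[0.0, 2.0, 1.0],
                      [0.5, 0.0, 1.5],
                      [1.0, 1.0, 0.0]])
        spec = CTMCSpec(rates=Q)
        pi = stationary_distribution(Q)
        occ = np.zeros(3)
        for _ in range(20):
            path = sample_ctmc_path(spec, 0, 50_000.0, rng)
            states = path.per_bin(1.0)
            occ += np.bincount(states, minlength=3)
        occ = occ / occ.sum()
        assert np.allclose(occ, pi, atol=0.02)

    def test_empirical_transition_rates_match_q(self):
        rng = np.random.default_rng(3)
        Q = np.array([[0.0, 3.0], [1.0, 0.0]])
        spec = CTMCSpec(rates=Q)
        time_in = np.zeros(2)
        jumps = np.zeros((2, 2))
        for _ in range(30):
            p = sample_ctmc_path(spec, 0, 20_000.0, rng)
            bounds = np.append(p.times, p.T)
            for s, t0, t1 in zip(p.states, bounds[:-1], bounds[1:]):
                time_in[s] += (t1 - t0) * 1e-3
            for a, b in zip(p.states[:-1], p.states[1:]):
                jumps[a, b] += 1
        q01 = jumps[0, 1] / time_in[0]
        se = np.sqrt(jumps[0, 1]) / time_in[0]
        assert abs(q01 - 3.0) < 3 * se

    def test_min_dwell_enforced(self):
        spec = CTMCSpec(rates=np.array([[0.0, 50.0], [50.0, 0.0]]),
                        min_dwell=60.0)
        path = sample_ctmc_path(spec, 0, 5000.0, np.random.default_rng(4))
        dwell = np.diff(np.append(path.times, path.T))[:-1]
        assert np.all(dwell >= 60.0)


class TestObservations:
    def test_rates_switch_with_the_path(self):
        model = ObservationModel(lam=np.array([[1000.0], [0.1]]),
                                 baseline=0.1)
        path = StatePath(times=np.array([0.0, 500.0]),
                         states=np.array([0, 1]), T=1000.0)
        r = sample_observation_spikes(path, model, np.random.default_rng(0))
        assert np.sum(r.time_ms >= 500.0) <= 2  # baseline only after switch
        assert np.sum(r.time_ms < 500.0) > 300

    def test_count_matches_poisson_mean(self):
        model = ObservationModel(lam=np.array([[5.0]]), baseline=0.1)
        path = StatePath(times=np.array([0.0]), states=np.array([0]),
                         T=200_000.0)
        r = sample_observation_spikes(path, model, np.random.default_rng(1))
        assert abs(len(r) - 1000) < 3 * np.sqrt(1000)

    def test_counts_are_poisson_dispersed(self):
        rng = np.random.default_rng(2)
        model = ObservationModel(lam=np.array([[50.0]]), baseline=0.1)
        path = StatePath(times=np.array([0.0]), states=np.array([0]),
                         T=100.0)
        counts = [len(sample_observation_spikes(path, model, rng))
                  for _ in range(10_000)]
        c = np.asarray(counts, dtype=float)
        assert 0.9 < c.var() / c.mean() < 1.1


class TestGaussianTuning:
    def test_peak_floor_and_symmetry(self):
        m = gaussian_tuning(J=35, means=[10.0], sigma=3.0, lam_max=20.0,
                            baseline=0.1)
        lam = m.lam[0]
        assert lam[9] == pytest.approx(20.0)  # position 10 -> peak
        assert lam[34] == pytest.approx(0.1, abs=1e-3)  # far tail -> floor
        assert lam[7] == pytest.approx(lam[11])  # symmetric around the mean

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_tuning(J=5, means=[1.0], sigma=0.0, lam_max=5.0)


class TestContextSpikes:
    @pytest.fixture
    def schedule(self):
        return ContextSchedule(times=np.array([0.0, 1000.0]),
                               contexts=np.array([0, 1]), T=2000.0,
                               neurons_per_context=10, active_rate=50.0,
                               n_contexts=2)

    def test_only_active_context_fires(self, schedule):
        r = sample_context_spikes(schedule, np.random.default_rng(0))
        assert np.all(r.ensemble_id[r.time_ms < 1000.0] == 0)
        assert np.all(r.ensemble_id[r.time_ms >= 1000.0] == 1)

    def test_total_count(self, schedule):
        # 10 neurons at 50 Hz for 2 s total active time -> 1000 expected
        r = sample_context_spikes(schedule, np.random.default_rng(1))
        assert abs(len(r) - 1000) < 3 * np.sqrt(1000)


def test_observation_model_requires_positive_floor():
    with pytest.raises(ValueError):
        ObservationModel(lam=np.array([[1.0, 0.05]]), baseline=0.1)
    with pytest.raises(ValueError):
        ObservationModel(lam=np.array([[1.0]]), baseline=0.0)
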