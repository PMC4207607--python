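"""Synthetic-world generators.

Hidden states evolve as a continuous-time Markov chain (CTMC), optionally
with per-context rate matrices; observations are Poisson point events from
afferent neurons whose rates depend on the current state (e.g. Gaussian
tuning curves over a feature axis); context is signalled by dedicated
ensembles of context neurons firing at a fixed rate when their context is
active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiking_core import DT_MS, SpikeRaster

__all__ = [
    "CTMCSpec",
    "ContextSchedule",
    "ObservationModel",
    "StatePath",
    "gaussian_tuning",
    "sample_context_spikes",
    "sample_ctmc_path",
    "sample_observation_spikes",
    "stationary_distribution",
]


@dataclass
class CTMCSpec:
    """Transition rates of a CTMC, optionally one matrix per context.

    ``rates[k, i]`` is the rate (Hz) of ``k -> i`` transitions; diagonals are
    ignored (kept zero).  ``context_rates`` holds one such matrix per context
    over the same state space.  ``min_dwell`` (ms) forces every visited state
    to be held at least that long.
    """

    rates: np.ndarray
    context_rates: np.ndarray | None = None  # (M, N, N)
    min_dwell: float | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2 or self.rates.shape[0] != self.rates.shape[1]:
            raise ValueError("rates must be a square matrix")
        if np.any(self.rates < 0):
            raise ValueError("transition rates must be non-negative")
        np.fill_diagonal(self.rates, 0.0)
        if self.context_rates is not None:
            self.context_rates = np.asarray(self.context_rates, dtype=float)
            if (self.context_rates.ndim != 3
                    or self.context_rates.shape[1:] != self.rates.shape):
                raise ValueError("context matrices must share the state space")
            if np.any(self.context_rates < 0):
                raise ValueError("transition rates must be non-negative")
            for m in self.context_rates:
                np.fill_diagonal(m, 0.0)

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def n_contexts(self) -> int:
        return 0 if self.context_rates is None else self.context_rates.shape[0]


@dataclass
class StatePath:
    """Piecewise-constant state trajectory on [0, T].

    ``times[j]`` is the entry time (ms) of ``states[j]``; ``times[0] == 0``.
    """

    times: np.ndarray
    states: np.ndarray
    T: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.times.size != self.states.size or self.times.size == 0:
            raise ValueError("times and states must be non-empty and aligned")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("entry times must start at 0 and increase")

    def state_at(self, t) -> np.ndarray | int:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right") - 1
        out = self.states[idx]
        return out if np.ndim(out) else int(out)

    def per_bin(self, dt: float = DT_MS) -> np.ndarray:
        """State index at each bin start over [0, T)."""
        n = int(round(self.T / dt))
        return np.asarray(self.state_at(np.arange(n) * dt))


@dataclass
class ContextSchedule:
    """Piecewise-constant context trajectory with its context-neuron layout."""

    times: np.ndarray
    contexts: np.ndarray
    T: float
    neurons_per_context: int = 10
    active_rate: float = 50.0  # Hz
    n_contexts: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.contexts = np.asarray(self.contexts, dtype=int)
        if self.times.size != self.contexts.size or self.times.size == 0:
            raise ValueError("times and contexts must be non-empty and aligned")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("entry times must start at 0 and increase")
        if self.n_contexts is None:
            self.n_contexts = int(self.contexts.max()) + 1

    def context_at(self, t) -> np.ndarray | int:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right") - 1
        out = self.contexts[idx]
        return out if np.ndim(out) else int(out)

    def per_bin(self, dt: float = DT_MS) -> np.ndarray:
        n = int(round(self.T / dt))
        return np.asarray(self.context_at(np.arange(n) * dt))


@dataclass
class ObservationModel:
    """State-dependent Poisson rates of ``J`` afferent neurons.

    ``lam[i, j]`` is the rate (Hz) of afferent ``j`` in state ``i``; all
    entries must be at least ``baseline`` > 0 so that log-likelihood weights
    are finite.
    """

    lam: np.ndarray
    baseline: float = 0.1

    def __post_init__(self) -> None:
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        if not self.baseline > 0:
            raise ValueError("baseline rate must be strictly positive")
        if np.any(self.lam < self.baseline - 1e-12):
            raise ValueError("all rates must be >= baseline")

    @property
    def n_states(self) -> int:
        return self.lam.shape[0]

    @property
    def n_afferents(self) -> int:
        return self.lam.shape[1]

    @property
    def lam_bar(self) -> np.ndarray:
        """Total afferent rate per state, ``sum_j lam[i, j]``."""
        return self.lam.sum(axis=1)


def sample_ctmc_path(spec: CTMCSpec, x0: int, T: float,
                     rng: np.random.Generator,
                     schedule: ContextSchedule | None = None) -> StatePath:
    """Simulate the CTMC by competing exponential clocks.

    After each transition the chain starts afresh.  With ``min_dwell`` set,
    candidate transitions before dwell expiry are rejected, which by
    memorylessness makes each sojourn ``min_dwell + Exp(total rate)``.  With
    a ``schedule``, the rate matrix of the scheduled context applies at each
    instant (rates are re-drawn at context switches).
    """
    N = spec.n_states
    if not 0 <= x0 < N:
        raise ValueError("invalid initial state")
    times = [0.0]
    states = [x0]
    t, x = 0.0, x0
    guard = float(spec.min_dwell or 0.0)
    while True:
        earliest = t + guard
        # competing exponentials from the current entry, context-resolved
        while True:
            Q = spec.rates if schedule is None else (
                spec.context_rates[schedule.context_at(min(max(earliest, t),
                                                           T - 1e-9))])
            out = Q[x]
            total = out.sum()
            if total <= 0:
                if schedule is not None:
                    sw = schedule.times[schedule.times > earliest]
                    if sw.size and sw[0] < T:
                        earliest = float(sw[0])
                        continue
                nxt_t, nxt_x = np.inf, x
            else:
                waits = np.full(N, np.inf)
                pos = out > 0
                waits[pos] = rng.exponential(1.0, size=int(pos.sum())) \
                    / out[pos] * 1e3  # Hz -> ms
                j = int(np.argmin(waits))
                nxt_t, nxt_x = earliest + waits[j], j
            if schedule is not None and np.isfinite(nxt_t):
                # if the context switches before the candidate event,
                # restart the clocks at the switch (memoryless)
                sw = schedule.times[(schedule.times > earliest)
                                    & (schedule.times < nxt_t)]
                if sw.size:
                    earliest = float(sw[0])
                    continue
            break
        if nxt_t >= T:
            break
        t, x = nxt_t, nxt_x
        times.append(t)
        states.append(x)
    return StatePath(times=np.array(times), states=np.array(states), T=T)


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary distribution of the generator built from ``rates``."""
    Q = np.asarray(rates, dtype=float).T.copy()  # columns: source states
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=0)
    # solve pi Q = 0 with sum(pi) = 1
    A = np.vstack([Q, np.ones(Q.shape[0])])
    b = np.zeros(Q.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def sample_observation_spikes(path: StatePath, model: ObservationModel,
                              rng: np.random.Generator,
                              dt: float = DT_MS) -> SpikeRaster:
    """Bernoulli-per-bin afferent spikes with rates ``lam[x(t), j]``."""
    states = path.per_bin(dt)
    p = model.lam[states] * dt * 1e-3  # (T, J)
    if np.any(p > 1.0):
        raise ValueError("r*dt exceeds 1; decrease dt")
    hits = rng.random(p.shape) < p
    tbin, j = np.nonzero(hits)
    return SpikeRaster(neuron_id=j, time_ms=tbin * dt, ensemble_id=j,
                       layer="afferent")


def gaussian_tuning(J: int, means: np.ndarray, sigma, lam_max: float,
                    baseline: float = 0.1,
                    positions: np.ndarray | None = None) -> ObservationModel:
    """Observation model from Gaussian tuning curves over the afferent axis.

    Afferent positions default to ``1..J``; state ``i`` drives afferent ``j``
    at ``baseline + (lam_max - baseline) * exp(-(pos_j - mean_i)^2 /
    (2 sigma_i^2))`` — the baseline acts as an additive floor so rates never
    drop below it.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), means.shape)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    pos = (np.arange(1, J + 1, dtype=float)
           if positions is None else np.asarray(positions, dtype=float))
    gauss = np.exp(-(pos[None, :] - means[:, None]) ** 2
                   / (2.0 * sigma[:, None] ** 2))
    lam = baseline + (lam_max - baseline) * gauss
    return ObservationModel(lam=lam, baseline=baseline)


def sample_context_spikes(schedule: ContextSchedule, rng: np.random.Generator,
                          dt: float = DT_MS) -> SpikeRaster:
    """Poisson spikes of context neurons: active context fires, others silent."""
    ctx = schedule.per_bin(dt)  # (T,)
    M, Kc = schedule.n_contexts, schedule.neurons_per_context
    p = schedule.active_rate * dt * 1e-3
    if p > 1.0:
        raise ValueError("active_rate * dt exceeds 1")
    hits = rng.random((ctx.size, M, Kc)) < p
    hits &= (np.arange(M)[None, :, None] == ctx[:, None, None])
    tbin, c, m = np.nonzero(hits)
    return SpikeRaster(neuron_id=c * Kc + m, time_ms=tbin * dt,
                       ensemble_id=c, layer="context")
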