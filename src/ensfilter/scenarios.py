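"""Fully parameterized experiment library.

Each scenario bundles the generative world (CTMC + observation model +
context), the circuit parameters and the stimulus protocol of one
benchmark experiment, and knows how to run one trial/sequence of itself:

* ``fig5_evidence`` — two-state evidence integration from two afferent
  spikes at 20 and 25 ms (K=2000, S=400).
* ``fig7_dynamics`` — two-state pure dynamics tracking, transition rate
  drawn in [0, 30] Hz, no evidence.
* ``generic_C`` — five-state chain (1->2,1->3,2->4,3->5,4->1,5->1 at
  1 Hz, 60 ms minimum dwell) observed through 35 Gaussian-tuned afferents;
  12 s sequences.
* ``generic_D`` — the same chain under two contexts (B interchanges the
  2->4 / 3->5 transitions), context switching whenever state 1 is entered,
  10 context neurons per context at 50 Hz, harder observation model.
* ``maze`` — self-localization on a 10x10 grid in a two-chamber maze with
  ambiguous southern landmarks, four movement contexts (3.5 Hz along the
  movement direction, 0.1 Hz between other adjacent cells), K=S=250.
* ``ambiguous_target`` — 16 direction-color states, 19 stimulus ensembles
  of 20 afferents (0.1 Hz baseline / 5 Hz active), epochs fixation 100 ms,
  spatial cue 250 ms, memory 250 ms, color cue 250 ms; K=1000, S=400;
  8-action readout of 100 neurons per action marginalizing color.
* ``ambiguous_target_sequential`` — two chained trials (fixation extended
  to 250 ms) with a phase filter over {CHT, SC, MEM, CC} providing graded
  context that resets the belief during fixation (all-to-all 1 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import exact_filter as xf
from .circuit import (CircuitSimulator, _normalize_rows, _ReadoutSimulator,
                      build_circuit, build_readout_layer, gate_window_bins,
                      run_circuit)
from .exact_filter import PosteriorTrace
from .generative import (CTMCSpec, ContextSchedule, ObservationModel,
                         StatePath, gaussian_tuning, sample_ctmc_path,
                         sample_observation_spikes)
from .spiking_core import DT_MS, SpikeRaster

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioSpec",
    "draw_batch",
    "make_scenario",
    "run_ambiguous_trial",
    "run_fig5_trial",
    "run_fig7_trial",
    "run_generic_sequence",
    "run_maze",
    "run_sequential_trial",
]

SCENARIO_NAMES = ("fig5_evidence", "fig7_dynamics", "generic_C", "generic_D",
                  "maze", "ambiguous_target", "ambiguous_target_sequential")


@dataclass
class ScenarioSpec:
    """One experiment: generative model + circuit parameters + protocol."""

    name: str
    N: int
    K: int
    S: float
    nu: float | None = None  # None -> critically damped tau/(2 S dt)
    tau: float = 20.0
    dt: float = DT_MS
    T: float = 0.0  # ms, one trial/sequence
    ctmc: CTMCSpec | None = None
    observation: ObservationModel | None = None
    context_mode: str = "none"
    ctx_K: int = 0
    ctx_rate: float = 50.0
    ctx_S: float = 0.0
    p0: np.ndarray | None = None  # None -> uniform
    protocol: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)

    @property
    def prior(self) -> np.ndarray:
        return (np.full(self.N, 1.0 / self.N)
                if self.p0 is None else np.asarray(self.p0))

    @property
    def n_bins(self) -> int:
        return int(round(self.T / self.dt))

    def to_config(self) -> dict:
        """Round-trippable configuration (name + overrides)."""
        return {"scenario": self.name, "overrides": dict(self.overrides)}

    @staticmethod
    def from_config(cfg: dict) -> "ScenarioSpec":
        return make_scenario(cfg["scenario"], **cfg.get("overrides", {}))


# ---------------------------------------------------------------------------
# scenario constructors

_GENERIC_EDGES_A = [(0, 1), (0, 2), (1, 3), (2, 4), (3, 0), (4, 0)]
_GENERIC_EDGES_B = [(0, 1), (0, 2), (1, 4), (2, 3), (3, 0), (4, 0)]


def _chain_rates(edges, N=5, rate=1.0) -> np.ndarray:
    Q = np.zeros((N, N))
    for k, i in edges:
        Q[k, i] = rate
    return Q


def _generic_c_observation() -> ObservationModel:
    # 35 afferents; states 2 and 3 nearly coincide on the feature axis
    means = np.array([6.0, 14.0, 15.0, 22.0, 29.0])
    return gaussian_tuning(J=35, means=means, sigma=3.0, lam_max=20.0,
                           baseline=0.1)


def _generic_d_observation() -> ObservationModel:
    J, lam_max, base = 35, 20.0, 0.1
    pos = np.arange(1, J + 1, dtype=float)
    lam = np.zeros((5, J))
    # states 1 and 3 share a mean but differ in width; state 2 is apart
    for i, (mu, sg) in enumerate([(10.0, 3.0), (18.0, 3.0), (10.0, 6.0)]):
        lam[i] = base + (lam_max - base) * np.exp(-(pos - mu) ** 2
                                                  / (2 * sg ** 2))
    # state 5: uniform; state 4: two modest Gaussian bumps on an offset,
    # with the offset chosen so both states share the same total intensity
    # -- they are hard to tell apart without context
    lam[4] = 5.0
    bumps = 2.5 * (np.exp(-(pos - 24.0) ** 2 / (2 * 2.5 ** 2))
                   + np.exp(-(pos - 32.0) ** 2 / (2 * 2.5 ** 2)))
    lam[3] = np.maximum((lam[4].sum() - bumps.sum()) / J, base) + bumps
    return ObservationModel(lam=lam, baseline=base)


# -- maze geometry ----------------------------------------------------------

_MAZE_SIDE = 10
_WALL_X = 0.5
_OPEN_Y = 0.75  # wall exists below this height; no observations above it
# chamber-local centers of the four ambiguous southern landmarks
_AMBIG_CENTERS = [(0.12, 0.15), (0.35, 0.12), (0.30, 0.32), (0.13, 0.33)]
# global centers of the four unambiguous mid-region landmarks
_UNIQ_CENTERS = [(0.15, 0.55), (0.35, 0.62), (0.65, 0.55), (0.85, 0.62)]
_MAZE_SIGMA = 0.1
_MAZE_LAM_MAX = 50.0
_MAZE_DIRS = {"right": (1, 0), "down": (0, -1), "left": (-1, 0),
              "up": (0, 1)}  # context order
_MAZE_CONTEXTS = ("right", "down", "left", "up")


def _maze_positions() -> np.ndarray:
    g = (np.arange(_MAZE_SIDE) + 0.5) / _MAZE_SIDE
    xx, yy = np.meshgrid(g, g, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])  # state = gy*10+gx


def _maze_adjacent(a: int, b: int) -> bool:
    ax, ay = a % _MAZE_SIDE, a // _MAZE_SIDE
    bx, by = b % _MAZE_SIDE, b // _MAZE_SIDE
    if max(abs(ax - bx), abs(ay - by)) != 1:
        return False
    crosses = (ax <= 4) != (bx <= 4)
    if crosses and not (ay >= 8 and by >= 8):
        return False  # separated by the chamber wall
    return True


def _maze_rates() -> np.ndarray:
    N = _MAZE_SIDE ** 2
    Qs = np.zeros((4, N, N))
    for c, name in enumerate(_MAZE_CONTEXTS):
        dx, dy = _MAZE_DIRS[name]
        for a in range(N):
            ax, ay = a % _MAZE_SIDE, a // _MAZE_SIDE
            for b in range(N):
                if a == b or not _maze_adjacent(a, b):
                    continue
                bx, by = b % _MAZE_SIDE, b // _MAZE_SIDE
                if (bx - ax, by - ay) == (dx, dy):
                    Qs[c, a, b] = 3.5
                else:
                    Qs[c, a, b] = 0.1
    return Qs


def _maze_afferent_rates(pos: np.ndarray) -> np.ndarray:
    """Rates (J=8) of the maze afferents for positions (n, 2)."""
    pos = np.atleast_2d(pos)
    lam = np.full((pos.shape[0], 8), 0.1)
    in_right = pos[:, 0] >= _WALL_X
    for j, (cx, cy) in enumerate(_AMBIG_CENTERS):
        centers = np.where(in_right[:, None],
                           np.array([cx + 0.5, cy]), np.array([cx, cy]))
        d2 = ((pos - centers) ** 2).sum(axis=1)
        lam[:, j] += (_MAZE_LAM_MAX - 0.1) * np.exp(-d2 / (2 * _MAZE_SIGMA ** 2))
    for j, (cx, cy) in enumerate(_UNIQ_CENTERS):
        d2 = ((pos - np.array([cx, cy])) ** 2).sum(axis=1)
        lam[:, 4 + j] += (_MAZE_LAM_MAX - 0.1) * np.exp(-d2
                                                        / (2 * _MAZE_SIGMA ** 2))
    lam[pos[:, 1] >= _OPEN_Y] = 0.1  # evidence-free northern corridor
    return lam


def _maze_observation() -> ObservationModel:
    return ObservationModel(lam=_maze_afferent_rates(_maze_positions()),
                            baseline=0.1)


def _maze_trajectory() -> tuple[np.ndarray, np.ndarray]:
    """Waypoint times (ms) and positions of the scripted maze run."""
    t = np.array([0.0, 1700.0, 3000.0, 3800.0])
    p = np.array([[0.25, 0.15], [0.25, 0.82], [0.75, 0.82], [0.75, 0.35]])
    return t, p


def _maze_schedule(T: float) -> ContextSchedule:
    # movement context follows the scripted trajectory legs
    return ContextSchedule(times=np.array([0.0, 1700.0, 3000.0]),
                           contexts=np.array([3, 0, 1]),  # up, right, down
                           T=T, neurons_per_context=10, active_rate=50.0,
                           n_contexts=4)


# -- ambiguous target -------------------------------------------------------

_N_DIR, _N_COL = 8, 2  # state = direction * 2 + color (0 red, 1 blue)
_ENS_FIX = 0
_ENS_SC_RED = 1  # ensembles 1..8: red spatial cue at direction d
_ENS_SC_BLUE = 9  # ensembles 9..16: blue spatial cue at direction d
_ENS_CC = 17  # 17: red color cue, 18: blue color cue
_N_STIM_ENS, _ENS_SIZE = 19, 20


def _ambiguous_possible() -> np.ndarray:
    """(16, 19) bool: is stimulus ensemble o possible in state (d, col)?"""
    poss = np.zeros((16, _N_STIM_ENS), dtype=bool)
    for d in range(_N_DIR):
        for col in range(_N_COL):
            i = d * 2 + col
            poss[i, _ENS_FIX] = True
            opp = (d + 4) % 8
            if col == 0:  # red rewarded: red cue at d, blue cue opposite
                poss[i, _ENS_SC_RED + d] = True
                poss[i, _ENS_SC_BLUE + opp] = True
            else:
                poss[i, _ENS_SC_BLUE + d] = True
                poss[i, _ENS_SC_RED + opp] = True
            poss[i, _ENS_CC + col] = True
    return poss


def _ambiguous_observation() -> ObservationModel:
    lam_ens = np.where(_ambiguous_possible(), 5.0, 0.1)  # (16, 19)
    lam = np.repeat(lam_ens, _ENS_SIZE, axis=1)  # (16, 380)
    return ObservationModel(lam=lam, baseline=0.1)


def _phase_observation() -> ObservationModel:
    """Observation model of the trial-phase filter (CHT, SC, MEM, CC)."""
    lam_ens = np.full((4, _N_STIM_ENS), 0.1)
    lam_ens[0, _ENS_FIX] = 5.0  # CHT
    lam_ens[2, _ENS_FIX] = 5.0  # MEM
    lam_ens[1, _ENS_SC_RED:_ENS_SC_BLUE + 8] = 5.0 / 16.0  # SC
    lam_ens[3, _ENS_CC:_ENS_CC + 2] = 2.5  # CC
    return ObservationModel(lam=np.repeat(lam_ens, _ENS_SIZE, axis=1),
                            baseline=0.1)


def _phase_rates(rate: float = 5.0) -> np.ndarray:
    Q = np.zeros((4, 4))
    for k in range(4):
        Q[k, (k + 1) % 4] = rate  # CHT -> SC -> MEM -> CC -> CHT
    return Q


def make_scenario(name: str, **overrides) -> ScenarioSpec:
    """Build one of the named experiment configurations.

    Keyword overrides replace the corresponding :class:`ScenarioSpec`
    fields (e.g. ``nu=0.5``, ``T=6000``); they are recorded so configs
    round-trip.
    """
    if name == "fig5_evidence":
        spec = ScenarioSpec(name=name, N=2, K=2000, S=400, T=50.0,
                            observation=None,  # drawn per trial
                            protocol={"spike_times_ms": (20.0, 25.0),
                                      "eval_t_ms": 45.0,
                                      "lam_range": (6.0, 21.0),
                                      "prior_range": (0.1, 0.9)})
    elif name == "fig7_dynamics":
        spec = ScenarioSpec(name=name, N=2, K=2000, S=400, T=50.0,
                            protocol={"q_range": (0.0, 30.0),
                                      "prior_range": (0.1, 0.9),
                                      "eval_t_ms": 50.0})
    elif name == "generic_C":
        spec = ScenarioSpec(
            name=name, N=5, K=2000, S=400, T=12_000.0,
            ctmc=CTMCSpec(rates=_chain_rates(_GENERIC_EDGES_A),
                          min_dwell=60.0),
            observation=_generic_c_observation(),
            protocol={"n_sequences": 20})
    elif name == "generic_D":
        ctx = np.stack([_chain_rates(_GENERIC_EDGES_A),
                        _chain_rates(_GENERIC_EDGES_B)])
        spec = ScenarioSpec(
            name=name, N=5, K=2000, S=400, T=12_000.0,
            ctmc=CTMCSpec(rates=ctx.mean(axis=0), context_rates=ctx,
                          min_dwell=60.0),
            observation=_generic_d_observation(),
            context_mode="hard", ctx_K=10, ctx_rate=50.0,
            protocol={"n_sequences": 20, "switch_state": 0})
    elif name == "maze":
        Qs = _maze_rates()
        spec = ScenarioSpec(
            name=name, N=100, K=250, S=250, T=3800.0,
            ctmc=CTMCSpec(rates=Qs.mean(axis=0), context_rates=Qs),
            observation=_maze_observation(),
            context_mode="hard", ctx_K=10, ctx_rate=50.0,
            protocol={"sigma": _MAZE_SIGMA, "lam_max": _MAZE_LAM_MAX})
    elif name == "ambiguous_target":
        spec = ScenarioSpec(
            name=name, N=16, K=1000, S=400, T=850.0,
            observation=_ambiguous_observation(),
            protocol={"epochs_ms": {"CHT": 100.0, "SC": 250.0, "MEM": 250.0,
                                    "CC": 250.0},
                      "readout_K": 100, "readout_S": 80.0,
                      "success_window_ms": 100.0})
    elif name == "ambiguous_target_sequential":
        M = 4
        ctx_rates = np.zeros((M, 16, 16))
        ctx_rates[0] = 1.0  # fixation context: all-to-all 1 Hz
        np.fill_diagonal(ctx_rates[0], 0.0)
        spec = ScenarioSpec(
            name=name, N=16, K=1000, S=400, T=2000.0,
            observation=_ambiguous_observation(),
            ctmc=CTMCSpec(rates=ctx_rates.mean(axis=0),
                          context_rates=ctx_rates),
            context_mode="graded", ctx_K=1000, ctx_S=400.0,
            protocol={"epochs_ms": {"CHT": 250.0, "SC": 250.0, "MEM": 250.0,
                                    "CC": 250.0},
                      "n_chained_trials": 2,
                      "readout_K": 100, "readout_S": 80.0,
                      "phase_rates_hz": 5.0})
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from "
                         f"{SCENARIO_NAMES}")
    if overrides:
        spec = replace(spec, **overrides)
    spec.overrides = dict(overrides)
    return spec


# ---------------------------------------------------------------------------
# runners

def run_fig5_trial(scenario: ScenarioSpec, rng: np.random.Generator) -> dict:
    """One two-state evidence-integration trial; returns circuit vs oracle
    posterior for state 0 at the evaluation time."""
    proto = scenario.protocol
    lo, hi = proto["lam_range"]
    lam = rng.uniform(lo, hi, size=(2, 2))
    model = ObservationModel(lam=lam, baseline=float(lam.min()))
    p1 = rng.uniform(*proto["prior_range"])
    prior = np.array([p1, 1.0 - p1])
    nb = scenario.n_bins
    aff = np.zeros((nb, 2), dtype=int)
    for j, t in enumerate(proto["spike_times_ms"]):
        aff[int(round(t / scenario.dt)), j] = 1
    spec = build_circuit(N=2, K=scenario.K, S=scenario.S, obs_model=model,
                         nu=scenario.nu, tau=scenario.tau, dt=scenario.dt)
    res = run_circuit(spec, aff, nb, prior, rng)
    raster = SpikeRaster(neuron_id=np.array([0, 1]),
                         time_ms=np.array(proto["spike_times_ms"]))
    t_eval = proto["eval_t_ms"]
    oracle = xf.evidence_posterior_closed_form(prior, model, raster, t_eval)
    return {"lam": lam, "prior": prior,
            "circuit_trace": res.trace, "total_mass": res.total_mass,
            "p_circuit": float(res.trace.at(t_eval)[0]),
            "p_oracle": float(oracle[0])}


def run_fig7_trial(scenario: ScenarioSpec, rng: np.random.Generator) -> dict:
    """One two-state pure-dynamics trial against the analytic decay."""
    proto = scenario.protocol
    q = rng.uniform(*proto["q_range"])
    p1 = rng.uniform(*proto["prior_range"])
    prior = np.array([p1, 1.0 - p1])
    rates = np.array([[0.0, q], [0.0, 0.0]])
    nb = scenario.n_bins
    spec = build_circuit(N=2, K=scenario.K, S=scenario.S, rates=rates,
                         nu=scenario.nu, tau=scenario.tau, dt=scenario.dt)
    res = run_circuit(spec, None, nb, prior, rng)
    t = np.arange(nb + 1) * scenario.dt
    p1_true = p1 * np.exp(-q * t * 1e-3)
    analytic = np.column_stack([p1_true, 1.0 - p1_true])
    return {"q": q, "prior": prior, "circuit_trace": res.trace,
            "analytic": PosteriorTrace(times=t, probs=analytic,
                                       dt=scenario.dt),
            "total_mass": res.total_mass}


def _sample_switching_path(Qs: np.ndarray, x0: int, c0: int, T: float,
                           min_dwell: float, switch_state: int,
                           rng: np.random.Generator
                           ) -> tuple[StatePath, ContextSchedule]:
    """CTMC path whose context toggles whenever ``switch_state`` is entered."""
    M = Qs.shape[0]
    t, x, c = 0.0, x0, c0
    times, states = [0.0], [x0]
    ctimes, ctxs = [0.0], [c0]
    while True:
        out = Qs[c][x]
        total = out.sum()
        if total <= 0:
            break
        sojourn = min_dwell + rng.exponential(1.0 / total) * 1e3
        t = t + sojourn
        if t >= T:
            break
        x = int(rng.choice(out.size, p=out / total))
        times.append(t)
        states.append(x)
        if x == switch_state:
            c = (c + 1) % M
            ctimes.append(t)
            ctxs.append(c)
    path = StatePath(times=np.array(times), states=np.array(states), T=T)
    sched = ContextSchedule(times=np.array(ctimes), contexts=np.array(ctxs),
                            T=T, neurons_per_context=10, active_rate=50.0,
                            n_contexts=M)
    return path, sched


def _hard_context_gate(schedule: ContextSchedule, n_bins: int, gate_W: int,
                       dt: float, rng: np.random.Generator) -> np.ndarray:
    """(n_bins, M) bool: per-bin release of each context's D ensembles.

    Simulates the context neurons (Poisson at the active rate) and opens a
    context's gate when its windowed ensemble spike count reaches the
    disinhibition threshold (>= 1 spike for theta = 0.5).  A warm-up
    stretch before t=0 puts the gates in steady state at the start.
    """
    ctx = schedule.per_bin(dt)
    M, Kc = schedule.n_contexts, schedule.neurons_per_context
    p = schedule.active_rate * dt * 1e-3
    pre = gate_W
    active = np.zeros((n_bins + pre, M), dtype=bool)
    active[pre:] = np.arange(M)[None, :] == ctx[:, None]
    active[:pre] = active[pre]
    counts = rng.binomial(Kc, p, size=active.shape) * active
    csum = np.vstack([np.zeros((1, M), dtype=int),
                      np.cumsum(counts, axis=0)])
    # windowed count over the last gate_W bins, current bin inclusive
    idx = np.arange(pre, pre + n_bins)
    wins = csum[idx + 1] - csum[idx + 1 - gate_W]
    return wins >= 1


def run_generic_sequence(scenario: ScenarioSpec, rng: np.random.Generator,
                         epsp: str = "rect", inh_delay_ms: float = 0.5,
                         disinh_delay_ms: float = 0.0,
                         nu: float | None = None,
                         jitter_sigma: float | None = None,
                         oracles: tuple[str, ...] = ("opt", "inp")) -> dict:
    """One 12 s sequence of the generic task-C or task-D benchmark.

    Returns the state path, circuit posterior trace, requested oracle
    traces (``opt`` exact filter, ``inp`` input-only baseline, ``mix``
    context-blind mixed-rate filter) and the layer total-mass history.
    """
    nu = scenario.nu if nu is None else nu
    nb = scenario.n_bins
    model = scenario.observation
    contextual = scenario.context_mode == "hard"
    x0 = int(rng.integers(scenario.N))
    if contextual:
        path, sched = _sample_switching_path(
            scenario.ctmc.context_rates, x0, 0, scenario.T,
            scenario.ctmc.min_dwell or 0.0,
            scenario.protocol.get("switch_state", 0), rng)
    else:
        path = sample_ctmc_path(scenario.ctmc, x0, scenario.T, rng)
        sched = None
    raster = sample_observation_spikes(path, model, rng, scenario.dt)
    aff = xf.spike_counts_per_bin(raster, model.n_afferents, nb, scenario.dt)
    kw = {}
    if contextual:
        kw = dict(context_mode="hard", ctx_rates=scenario.ctmc.context_rates,
                  ctx_K=scenario.ctx_K, ctx_rate=scenario.ctx_rate)
    spec = build_circuit(N=scenario.N, K=scenario.K, S=scenario.S,
                         obs_model=model,
                         rates=None if contextual else scenario.ctmc.rates,
                         nu=nu, tau=scenario.tau, dt=scenario.dt,
                         epsp=epsp, inh_delay_ms=inh_delay_ms,
                         disinh_delay_ms=disinh_delay_ms, **kw)
    if jitter_sigma is not None:
        spec.v_jitter = _lognormal_jitter(spec.v, scenario.K, jitter_sigma,
                                          rng)
    ctx_open = None
    if contextual:
        ctx_open = _hard_context_gate(sched, nb, gate_window_bins(spec),
                                      scenario.dt, rng)
    res = run_circuit(spec, aff, nb, scenario.prior, rng,
                      ctx_open=ctx_open, ctx0=0)
    out = {"path": path, "schedule": sched, "raster": raster,
           "circuit_trace": res.trace, "total_mass": res.total_mass}
    prior = scenario.prior
    if "opt" in oracles:
        if contextual:
            out["opt_trace"] = xf.integrate_context(
                prior, model, scenario.ctmc, sched, raster, scenario.T,
                scenario.dt)
        else:
            out["opt_trace"] = xf.integrate_bayes(
                prior, model, scenario.ctmc, raster, scenario.T, scenario.dt)
    if "inp" in oracles:
        out["inp_trace"] = xf.baseline_input_only(model, raster, scenario.T,
                                                  scenario.dt)
    if "mix" in oracles:
        mixed = xf.baseline_mixed_rates(scenario.ctmc)
        out["mix_trace"] = xf.integrate_bayes(prior, model, mixed, raster,
                                              scenario.T, scenario.dt)
    return out


def _lognormal_jitter(v: np.ndarray, K: int, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-neuron multiplicative log-normal jitter with unit mean."""
    M, N, _ = v.shape
    gains = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                          size=(M, N, K, N))
    return v[:, :, None, :] * gains


def _ambiguous_epoch_rates(scenario: ScenarioSpec, d_true: int, col_true: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(n_bins, 19) ensemble rates and epoch boundaries for one trial."""
    proto = scenario.protocol
    epochs = proto["epochs_ms"]
    n_rep = proto.get("n_chained_trials", 1)
    order = ["CHT", "SC", "MEM", "CC"]
    bounds = [0.0]
    labels = []
    for _ in range(n_rep):
        for e in order:
            bounds.append(bounds[-1] + epochs[e])
            labels.append(e)
    nb = int(round(bounds[-1] / scenario.dt))
    rates = np.full((nb, _N_STIM_ENS), 0.1)
    opp = (d_true + 4) % 8
    red_pos = d_true if col_true == 0 else opp
    blue_pos = opp if col_true == 0 else d_true
    for (t0, t1), lab in zip(zip(bounds[:-1], bounds[1:]), labels):
        b0, b1 = int(round(t0 / scenario.dt)), int(round(t1 / scenario.dt))
        if lab in ("CHT", "MEM"):
            rates[b0:b1, _ENS_FIX] = 5.0
        elif lab == "SC":
            rates[b0:b1, _ENS_SC_RED + red_pos] = 5.0
            rates[b0:b1, _ENS_SC_BLUE + blue_pos] = 5.0
        else:  # CC
            rates[b0:b1, _ENS_CC + col_true] = 5.0
    return rates, np.array(bounds)


def _sample_stim_counts(ens_rates: np.ndarray, dt: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-bin spike counts of the 380 afferents from ensemble rates."""
    p = ens_rates * dt * 1e-3
    counts = rng.binomial(1, p[:, :, None].repeat(_ENS_SIZE, axis=2))
    return counts.reshape(ens_rates.shape[0], -1)


def _color_marginal_conditionals() -> np.ndarray:
    """(16, 8) table P(action = l | state (d, col)) = 1{l = d}."""
    cond = np.zeros((16, 8))
    for d in range(8):
        for col in range(2):
            cond[d * 2 + col, d] = 1.0
    return cond


def run_ambiguous_trial(scenario: ScenarioSpec, rng: np.random.Generator,
                        record_spikes: bool = False) -> dict:
    """One trial of the ambiguous target task with action readout."""
    d_true = int(rng.integers(_N_DIR))
    col_true = int(rng.integers(_N_COL))
    ens_rates, bounds = _ambiguous_epoch_rates(scenario, d_true, col_true)
    aff = _sample_stim_counts(ens_rates, scenario.dt, rng)
    nb = aff.shape[0]
    spec = build_circuit(N=16, K=scenario.K, S=scenario.S,
                         obs_model=scenario.observation, nu=scenario.nu,
                         tau=scenario.tau, dt=scenario.dt)
    proto = scenario.protocol
    readout = build_readout_layer(_color_marginal_conditionals(),
                                  K_out=proto["readout_K"],
                                  sample_scale=proto["readout_S"] / scenario.S,
                                  tau=scenario.tau)
    res = run_circuit(spec, aff, nb, scenario.prior, rng,
                      readouts=(readout,), record_spikes=record_spikes)
    return {"d_true": d_true, "col_true": col_true, "bounds": bounds,
            "aff_counts": aff, "circuit_trace": res.trace,
            "readout_trace": res.readout_traces[0],
            "total_mass": res.total_mass, "rasters": res.rasters}


def run_sequential_trial(scenario: ScenarioSpec, rng: np.random.Generator
                         ) -> dict:
    """Two chained ambiguous-target trials with the phase-filter cascade.

    The phase filter (task C over {CHT, SC, MEM, CC}) sees the same
    afferents and its evidence-layer ensembles act as graded context for
    the main direction-color filter, whose fixation-context dynamics reset
    the belief between trials.
    """
    truths = [(int(rng.integers(_N_DIR)), int(rng.integers(_N_COL)))
              for _ in range(scenario.protocol["n_chained_trials"])]
    # build the joint stimulus stream trial by trial
    one = replace(scenario, protocol={**scenario.protocol,
                                      "n_chained_trials": 1})
    segs, bounds_all, t_off = [], [0.0], 0.0
    for d_true, col_true in truths:
        r, bounds = _ambiguous_epoch_rates(one, d_true, col_true)
        segs.append(r)
        bounds_all.extend((bounds[1:] + t_off).tolist())
        t_off += bounds[-1]
    ens_rates = np.vstack(segs)
    aff = _sample_stim_counts(ens_rates, scenario.dt, rng)
    nb = aff.shape[0]
    # phase filter: plain Bayesian filtering over the four trial phases
    qp = scenario.protocol["phase_rates_hz"]
    phase_spec = build_circuit(N=4, K=1000, S=400.0,
                               obs_model=_phase_observation(),
                               rates=_phase_rates(qp),
                               nu=scenario.nu, tau=scenario.tau,
                               dt=scenario.dt)
    main_spec = build_circuit(N=16, K=scenario.K, S=scenario.S,
                              obs_model=scenario.observation,
                              ctx_rates=scenario.ctmc.context_rates,
                              context_mode="graded", ctx_K=scenario.ctx_K,
                              ctx_S=scenario.ctx_S, nu=scenario.nu,
                              tau=scenario.tau, dt=scenario.dt)
    proto = scenario.protocol
    readout = build_readout_layer(_color_marginal_conditionals(),
                                  K_out=proto["readout_K"],
                                  sample_scale=proto["readout_S"] / scenario.S,
                                  tau=scenario.tau)
    phase_sim = CircuitSimulator(phase_spec, rng)
    main_sim = CircuitSimulator(main_spec, rng)
    phase_sim.initialize(np.array([1.0, 0, 0, 0]))  # trials start in CHT
    main_sim.initialize(scenario.prior,
                        ctx_belief0=np.array([1.0, 0, 0, 0]))
    rsim = _ReadoutSimulator(readout, scenario.tau, scenario.dt, "rect", rng)
    phase_mass = np.zeros((nb + 1, 4))
    main_mass = np.zeros((nb + 1, 16))
    read_mass = np.zeros((nb + 1, 8))
    phase_mass[0], main_mass[0] = phase_sim.masses, main_sim.masses
    for b in range(nb):
        phase_sim.step(aff[b])
        ctx_recent = phase_sim.recent_E()
        main_sim.step(aff[b], ctx_recent=ctx_recent)
        rsim.step(main_sim.masses)
        phase_mass[b + 1] = phase_sim.masses
        main_mass[b + 1] = main_sim.masses
        read_mass[b + 1] = rsim.mass.A
    times = np.arange(nb + 1) * scenario.dt
    return {"truths": truths, "bounds": np.array(bounds_all),
            "phase_trace": PosteriorTrace(times, _normalize_rows(phase_mass),
                                          scenario.dt),
            "main_trace": PosteriorTrace(times, _normalize_rows(main_mass),
                                         scenario.dt),
            "readout_trace": PosteriorTrace(times,
                                            _normalize_rows(read_mass),
                                            scenario.dt),
            "phase_total": phase_mass.sum(axis=1),
            "main_total": main_mass.sum(axis=1)}


def run_maze(scenario: ScenarioSpec, rng: np.random.Generator) -> dict:
    """The scripted two-chamber self-localization run."""
    nb = scenario.n_bins
    t_bins = np.arange(nb) * scenario.dt
    wt, wp = _maze_trajectory()
    pos = np.column_stack([np.interp(t_bins, wt, wp[:, 0]),
                           np.interp(t_bins, wt, wp[:, 1])])
    lam_t = _maze_afferent_rates(pos)  # (nb, 8) true rates from agent pos
    aff = (rng.random(lam_t.shape) < lam_t * scenario.dt * 1e-3).astype(int)
    sched = _maze_schedule(scenario.T)
    spec = build_circuit(N=100, K=scenario.K, S=scenario.S,
                         obs_model=scenario.observation,
                         ctx_rates=scenario.ctmc.context_rates,
                         context_mode="hard", ctx_K=scenario.ctx_K,
                         ctx_rate=scenario.ctx_rate, nu=scenario.nu,
                         tau=scenario.tau, dt=scenario.dt)
    ctx_open = _hard_context_gate(sched, nb, gate_window_bins(spec),
                                  scenario.dt, rng)
    ctx0 = int(sched.context_at(0.0))
    res = run_circuit(spec, aff, nb, scenario.prior, rng, ctx_open=ctx_open,
                      ctx0=ctx0)
    return {"positions": pos, "schedule": sched,
            "grid_positions": _maze_positions(),
            "circuit_trace": res.trace, "total_mass": res.total_mass,
            "aff_counts": aff}


def draw_batch(scenario: ScenarioSpec, n_trials: int,
               rng: np.random.Generator) -> list[dict]:
    """Independent randomized trials with matched oracle runs.

    Each entry records the child seed used, so a batch re-run with the
    same master generator state reproduces identical inputs.
    """
    out = []
    streams = rng.spawn(n_trials)
    for k, child in enumerate(streams):
        if scenario.name == "fig5_evidence":
            res = run_fig5_trial(scenario, child)
        elif scenario.name == "fig7_dynamics":
            res = run_fig7_trial(scenario, child)
        elif scenario.name in ("generic_C", "generic_D"):
            oracles = (("opt", "inp") if scenario.name == "generic_C"
                       else ("opt", "mix"))
            res = run_generic_sequence(scenario, child, oracles=oracles)
        elif scenario.name == "ambiguous_target":
            res = run_ambiguous_trial(scenario, child)
        elif scenario.name == "ambiguous_target_sequential":
            res = run_sequential_trial(scenario, child)
        elif scenario.name == "maze":
            res = run_maze(scenario, child)
        else:  # pragma: no cover
            raise ValueError(scenario.name)
        res["trial_index"] = k
        out.append(res)
    return out
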