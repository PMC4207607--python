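"""The spiking particle-filter circuit.

Two coupled layers of ENS ensembles track the posterior over a hidden
state.  The *evidence layer* E injects observation likelihoods: its neurons
are driven by afferent EPSPs with weights ``w_ij = (log lam_ij + c_j)/tau``,
a bias containing the ``1/tau`` recovery term and the evidence-decay term
``-lam_bar_i`` (shifted to be non-negative), and a layer-wide lateral
inhibition ``I = nu * max(A_total - S, 0)/tau`` that pulls the total mass
back to the target sample size S.  The *dynamics layer* D predicts state
transitions: its neurons sum the E masses through weights proportional to
the CTMC rates (``v_ki ~ q_{k->i}/K`` off-diagonal, with the self weight
``(1/tau - sum_k q_{i->k})/K`` so that the representation is stationary in
the absence of transitions).

Multiplication of probability mass by evidence is implemented by
disinhibition gating: E neuron ``e_i^m`` can fire only if its paired D
neuron ``d_i^m`` spiked within the last EPSP length, so the expected
ensemble rate is the product of the D mass and the evidence drive.  With
context (task D), the D layer holds one copy of the state ensembles per
context, disinhibited by the context ensembles; in graded mode (task E)
each D neuron is gated by a single context neuron of an ENS context
representation, which makes the effective transition rates the
belief-weighted mixture of the per-context rates.

Membrane potentials are expressed in drive units of Hz: the rectified
linear link is applied with unit scale and the rate scale is absorbed into
the weights, which keeps every term of the membrane equations in the same
units as the filtering equations they approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .exact_filter import PosteriorTrace
from .spiking_core import DT_MS, EPSPKernel, SpikeRaster

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import ScenarioSpec

__all__ = [
    "CircuitSpec",
    "CircuitSimulator",
    "LayerSpec",
    "ReadoutSpec",
    "SimResult",
    "build_particle_filter_circuit",
    "build_readout_layer",
    "disinhibition_gate",
    "lateral_inhibition",
    "run_circuit",
]

_NEVER = -(10 ** 9)  # sentinel "no spike yet" bin index


def gate_window_bins(spec: "CircuitSpec") -> int:
    """Bins for which one gater spike keeps a disinhibition gate open."""
    if spec.gate_theta == 0:  # gating disabled
        return 1
    ms = spec.kernel.support_above(spec.gate_theta)
    return max(int(math.floor(ms / spec.dt + 1e-9)), 1)


@dataclass(frozen=True)
class LayerSpec:
    """Descriptive layer geometry: role, ensembles, size, rate scale."""

    role: str  # dynamics | evidence | readout | context
    n_ensembles: int
    K: int
    f: float  # per-neuron max rate (Hz) in the ENS interpretation


@dataclass
class CircuitSpec:
    """Fully wired particle-filter circuit.

    ``v[c, i, k]`` is the drive (Hz per unit mass) from E ensemble ``k`` to
    D ensemble ``i`` of context ``c`` (a single context slot when the task
    has none).  ``w_ev[i, j]`` is the drive per unit afferent trace.
    """

    N: int
    K: int
    S: float
    tau: float = 20.0
    dt: float = DT_MS
    w_ev: np.ndarray | None = None  # (N, J)
    lam_bar: np.ndarray | None = None  # (N,)
    bias: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v: np.ndarray = field(default_factory=lambda: np.zeros((1, 0, 0)))
    nu: float = 1.0
    inh_delay_ms: float = 0.5
    inh_cap: float | None = None
    gate_theta: float = 0.5
    disinh_delay_ms: float = 0.0
    epsp: str = "rect"
    v_jitter: np.ndarray | None = None  # (M, N, K, N) per-neuron weights
    context_mode: str = "none"  # none | hard | graded
    ctx_K: int = 0  # context-ensemble size (hard/graded)
    ctx_rate: float = 50.0  # Hz, hard-context neurons when active
    ctx_S: float = 0.0  # context-filter sample size (graded)

    @property
    def n_contexts(self) -> int:
        return self.v.shape[0]

    @property
    def n_afferents(self) -> int:
        return 0 if self.w_ev is None else self.w_ev.shape[1]

    @property
    def kernel(self) -> EPSPKernel:
        if self.epsp == "rect":
            return EPSPKernel("rect", self.tau, 1.0)
        return EPSPKernel.matched_exponential(self.tau)

    @property
    def layers(self) -> list[LayerSpec]:
        f = self.S / (self.K * self.tau * 1e-3)
        return [
            LayerSpec("dynamics", self.n_contexts * self.N, self.K, f),
            LayerSpec("evidence", self.N, self.K, f),
        ]


@dataclass
class ReadoutSpec:
    """Feed-forward readout layer inferring P(x) = sum_z P(x|z) p(z).

    ``weights[l, i]`` is the drive from E ensemble ``i`` to readout
    ensemble ``l``; built from a conditional table by :func:
    `build_readout_layer`.
    """

    weights: np.ndarray  # (N_out, N_in)
    K_out: int
    sample_scale: float  # S_out = sample_scale * S_in

    @property
    def n_out(self) -> int:
        return self.weights.shape[0]


def lateral_inhibition(total_mass: float, S: float, nu: float, tau: float,
                       cap: float | None = None) -> float:
    """Shared inhibitory drive ``nu * max(A_total - S, 0) / tau`` (Hz).

    Purely inhibitory: activity below the target is not compensated here
    (the ``1/tau`` bias term recovers it).  ``tau`` in ms.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    I = nu * max(total_mass - S, 0.0) / (tau * 1e-3)
    if cap is not None:
        I = min(I, cap)
    return I


def disinhibition_gate(y_gaters: float, theta: float = 0.5,
                       I_base: float = 1e3) -> float:
    """Membrane contribution of a disinhibition gate.

    Released (0) when the summed filtered gater activity reaches ``theta``;
    otherwise ``-I_base``, strong enough to suppress all activity.  With
    unit rectangular EPSPs and ``theta <= 1`` a single gater spike within
    the last tau releases the neuron.  ``theta = 0`` disables gating in the
    simulator (ablation control).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return 0.0 if y_gaters >= theta else -I_base


def build_particle_filter_circuit(scenario: "ScenarioSpec",
                                  **overrides) -> CircuitSpec:
    """Wire the particle-filter circuit for a scenario.

    Evidence weights are shifted per afferent by ``c_j = -min_i log
    lam_ij`` so they are non-negative (the shift cancels in
    normalization); dynamics weights implement the scenario's (per-context)
    transition rates.  In task B (pure evidence integration, all rates
    zero) the dynamics weights reduce to a diagonal copy.
    """
    obs = scenario.observation
    rates = scenario.ctmc.rates if scenario.ctmc is not None else None
    ctx_rates = (scenario.ctmc.context_rates
                 if scenario.ctmc is not None else None)
    params = dict(
        N=scenario.N, K=scenario.K, S=scenario.S, tau=scenario.tau,
        dt=scenario.dt, nu=scenario.nu, context_mode=scenario.context_mode,
        ctx_K=scenario.ctx_K, ctx_rate=scenario.ctx_rate,
        ctx_S=scenario.ctx_S,
    )
    params.update(overrides)
    return build_circuit(obs_model=obs, rates=rates, ctx_rates=ctx_rates,
                         **params)


def build_circuit(N: int, K: int, S: float, obs_model=None, rates=None,
                  ctx_rates=None, tau: float = 20.0, dt: float = DT_MS,
                  nu: float | None = None, context_mode: str = "none",
                  ctx_K: int = 0, ctx_rate: float = 50.0, ctx_S: float = 0.0,
                  **kw) -> CircuitSpec:
    """Explicit-parameter circuit constructor (see
    :func:`build_particle_filter_circuit`).

    ``nu=None`` selects the critically damped inhibition scaling
    ``tau / (2 S dt)``: the discrete inhibition feedback loop has per-bin
    gain ``S nu dt / tau``, and a gain of 1/2 keeps the total mass pinned
    at S without the relaxation oscillations (and occasional layer
    extinctions) that an overdriven loop produces.
    """
    if nu is None:
        nu = tau / (2.0 * S * dt)
    tau_s = tau * 1e-3
    recovery = kw.pop("bias_recovery", 1.1)
    if obs_model is not None:
        if np.any(obs_model.lam <= 0):
            raise ValueError("observation rates must be strictly positive")
        loglam = np.log(obs_model.lam)
        c = -loglam.min(axis=0)
        w_ev = (loglam + c[None, :]) / tau_s
        lam_bar = obs_model.lam_bar
    else:
        w_ev, lam_bar = None, np.zeros(N)
    # the recovery margin above 1/tau keeps the one-sided inhibition loop
    # pinned at the target mass instead of drifting below it; the common
    # surplus cancels in normalization
    bias = recovery / tau_s + (lam_bar.max() - lam_bar)
    if context_mode == "none":
        Qs = np.zeros((1, N, N)) if rates is None else rates[None, :, :]
    else:
        if ctx_rates is None:
            raise ValueError("context mode requires per-context rates")
        Qs = np.asarray(ctx_rates, dtype=float)
    M = Qs.shape[0]
    v = np.zeros((M, N, N))
    for cdx in range(M):
        Q = Qs[cdx]
        out = Q.sum(axis=1)
        if out.max() * tau_s >= 1.0:
            raise ValueError("total outflow rate must stay below 1/tau")
        v[cdx] = Q.T / K  # v[c, i, k] = q_{k->i} / K
        v[cdx, np.arange(N), np.arange(N)] = (1.0 / tau_s - out) / K
    if context_mode == "graded":
        if ctx_K < K:
            raise ValueError("graded gating needs ctx ensemble size >= K")
        if not ctx_S > 0:
            raise ValueError("graded gating needs the context sample size")
        v = v * (ctx_K / ctx_S)
    return CircuitSpec(N=N, K=K, S=S, tau=tau, dt=dt, w_ev=w_ev,
                       lam_bar=lam_bar, bias=bias, v=v, nu=nu,
                       context_mode=context_mode, ctx_K=ctx_K,
                       ctx_rate=ctx_rate, ctx_S=ctx_S, **kw)


def build_readout_layer(conditionals: np.ndarray, K_out: int,
                        sample_scale: float,
                        tau: float = 20.0) -> ReadoutSpec:
    """Readout weights from a conditional table ``P(x = l | z = i)``.

    ``conditionals[i, l]`` rows must be distributions over ``l``.  The
    drive weights are ``sample_scale * P(l|i) / (K_out * tau)`` so the
    readout's steady mass is ``sample_scale * sum_i P(l|i) A_i`` and its
    estimation sample size is ``sample_scale * S_in``.
    """
    cond = np.asarray(conditionals, dtype=float)
    if np.any(cond < 0) or not np.allclose(cond.sum(axis=1), 1.0):
        raise ValueError("conditional rows must be distributions")
    w = sample_scale * cond.T / (K_out * tau * 1e-3)
    return ReadoutSpec(weights=w, K_out=K_out, sample_scale=sample_scale)


class _MassAccumulator:
    """Windowed (rect) or exponentially decaying (exp) per-unit mass."""

    def __init__(self, n: int, W: int, mode: str, dt: float, tau: float):
        self.n, self.W, self.mode = n, W, mode
        self.A = np.zeros(n)
        if mode == "rect":
            self.ring = np.zeros((W, n))
            self.ptr = 0
        else:
            self.decay = math.exp(-dt / tau)

    def seed_counts(self, counts_by_age: np.ndarray) -> None:
        """Seed from per-unit counts indexed by age in bins (0 = one bin ago)."""
        if self.mode == "rect":
            for age in range(min(self.W, counts_by_age.shape[0])):
                self.ring[(self.ptr - 1 - age) % self.W] += counts_by_age[age]
            self.A = self.ring.sum(axis=0)
        else:
            ages = np.arange(counts_by_age.shape[0])
            self.A = (counts_by_age * self.decay ** (ages + 1)[:, None]
                      ).sum(axis=0)

    def push(self, counts: np.ndarray) -> np.ndarray:
        if self.mode == "rect":
            self.A = self.A + counts - self.ring[self.ptr]
            self.ring[self.ptr] = counts
            self.ptr = (self.ptr + 1) % self.W
        else:
            self.A = self.A * self.decay + counts
        return self.A


class CircuitSimulator:
    """Stepwise simulator of one particle-filter circuit.

    Drives both layers one time bin at a time so that several circuits can
    be advanced in lockstep (the graded-context cascade couples a context
    filter's evidence layer to the main filter's dynamics layer).
    """

    def __init__(self, spec: CircuitSpec, rng: np.random.Generator,
                 record_spikes: bool = False):
        self.spec = spec
        self.rng = rng
        self.record = record_spikes
        self.W = int(round(spec.tau / spec.dt))
        self.gate_W = gate_window_bins(spec)
        self.dis_delay = int(round(spec.disinh_delay_ms / spec.dt))
        self.inh_delay = max(int(round(spec.inh_delay_ms / spec.dt)), 1)
        M = spec.n_contexts
        self.lastD = np.full((M, spec.N, spec.K), _NEVER, dtype=np.int64)
        self.lastE = np.full((spec.N, spec.K), _NEVER, dtype=np.int64)
        self.massE = _MassAccumulator(spec.N, self.W, spec.epsp, spec.dt,
                                      spec.tau)
        self.afftrace = _MassAccumulator(max(spec.n_afferents, 1), self.W,
                                         spec.epsp, spec.dt, spec.tau)
        self.totals: list[float] = []
        self.spikesD: list[tuple[int, np.ndarray]] = []
        self.spikesE: list[tuple[int, np.ndarray]] = []
        self._b = 0

    # -- initialization ---------------------------------------------------
    def initialize(self, p0: np.ndarray,
                   ctx_belief0: np.ndarray | None = None,
                   ctx0: int | None = None) -> None:
        """Seed activity on [-tau, 0) so masses at t=0 represent ``p0``."""
        spec = self.spec
        p0 = np.asarray(p0, dtype=float)
        prob = spec.S * p0 / spec.K
        if np.any(prob > 1):
            raise ValueError("S*p0_i/K exceeds 1: K too small")
        # evidence layer
        hitsE = self.rng.random((spec.N, spec.K)) < prob[:, None]
        age = self.rng.integers(0, self.W, size=hitsE.shape)  # bins in past
        self.lastE = np.where(hitsE, -1 - age, _NEVER)
        countsE = np.zeros((self.W, spec.N))
        ii, mm = np.nonzero(hitsE)
        np.add.at(countsE, (age[ii, mm], ii), 1)
        self.massE.seed_counts(countsE)
        # dynamics layer: weight per-context copies by the context belief
        M = spec.n_contexts
        if spec.context_mode == "none":
            w_ctx = np.ones(1)
        elif spec.context_mode == "hard":
            w_ctx = np.zeros(M)
            w_ctx[ctx0 if ctx0 is not None else 0] = 1.0
        else:
            w_ctx = (np.full(M, 1.0 / M) if ctx_belief0 is None
                     else np.asarray(ctx_belief0, dtype=float))
        pD = w_ctx[:, None] * prob[None, :]
        hitsD = self.rng.random((M, spec.N, spec.K)) < pD[..., None]
        ageD = self.rng.integers(0, self.gate_W, size=hitsD.shape)
        self.lastD = np.where(hitsD, -1 - ageD, _NEVER)
        self.totals = [float(self.massE.A.sum())]

    # -- one time bin -----------------------------------------------------
    def step(self, aff_counts: np.ndarray | None = None,
             ctx_open: np.ndarray | None = None,
             ctx_recent: np.ndarray | None = None) -> None:
        """Advance one bin.

        ``aff_counts``: per-afferent spike counts of this bin.
        ``ctx_open``: (M,) bool, hard-context release of D ensembles.
        ``ctx_recent``: (M, >=K) bool, graded per-slot release of D slots.
        """
        spec, b = self.spec, self._b
        dt_s = spec.dt * 1e-3
        # afferent traces include this bin's spikes (lag-0 EPSP value)
        if spec.n_afferents:
            y = self.afftrace.push(aff_counts.astype(float))
            ev = spec.w_ev @ y
        else:
            ev = 0.0
        j = max(len(self.totals) - self.inh_delay, 0)
        I = lateral_inhibition(self.totals[j], spec.S, spec.nu, spec.tau,
                               spec.inh_cap)
        uE = ev + spec.bias - I
        # dynamics layer: drive from current E masses.  Bernoulli-per-bin
        # saturates at probability 1 when a transient drives r*dt above 1.
        if spec.v_jitter is not None:
            uD = spec.v_jitter @ self.massE.A  # (M, N, K) per-slot drive
            pD = np.clip(uD * dt_s, 0.0, 1.0)
        else:
            uD = spec.v @ self.massE.A  # (M, N)
            pD = np.clip(uD * dt_s, 0.0, 1.0)[..., None]
        draw = self.rng.random(self.lastD.shape) < pD
        if spec.context_mode == "hard":
            draw &= ctx_open[:, None, None]
        elif spec.context_mode == "graded":
            draw &= ctx_recent[:, None, :spec.K]
        self.lastD[draw] = b
        # evidence layer: gated one-to-one by the D slots of all contexts
        if spec.gate_theta == 0:  # ablation: disinhibition gate always open
            released = np.ones((spec.N, spec.K), dtype=bool)
        else:
            lag = (b - self.dis_delay) - self.lastD
            released = ((lag >= 0) & (lag < self.gate_W)).any(axis=0)  # (N, K)
        pE = np.clip(uE * dt_s, 0.0, 1.0)
        self.last_pE, self.last_pD = pE, pD
        drawE = (self.rng.random(released.shape) < pE[:, None]) & released
        self.lastE[drawE] = b
        countsE = drawE.sum(axis=1).astype(float)
        self.massE.push(countsE)
        self.totals.append(float(self.massE.A.sum()))
        if self.record:
            if draw.any():
                self.spikesD.append((b, np.argwhere(draw)))
            if drawE.any():
                self.spikesE.append((b, np.argwhere(drawE)))
        self._b += 1

    # -- outputs ----------------------------------------------------------
    @property
    def masses(self) -> np.ndarray:
        return self.massE.A

    def recent_E(self, b: int | None = None) -> np.ndarray:
        """(N, K) bool: E slots that spiked within the gate window."""
        b = self._b - 1 if b is None else b
        lag = b - self.lastE
        return (lag >= 0) & (lag < self.gate_W)

    def raster(self, which: str = "E") -> SpikeRaster:
        events = self.spikesE if which == "E" else self.spikesD
        if not events:
            return SpikeRaster(neuron_id=np.zeros(0, int),
                               time_ms=np.zeros(0),
                               ensemble_id=np.zeros(0, int),
                               layer="evidence" if which == "E" else "dynamics")
        ids, ens, times = [], [], []
        K = self.spec.K
        for b, idx in events:
            t = b * self.spec.dt
            if which == "E":
                e = idx[:, 0]
                ids.append(e * K + idx[:, 1])
            else:
                e = idx[:, 0] * self.spec.N + idx[:, 1]
                ids.append(e * K + idx[:, 2])
            ens.append(e)
            times.append(np.full(e.size, t))
        return SpikeRaster(neuron_id=np.concatenate(ids),
                           time_ms=np.concatenate(times),
                           ensemble_id=np.concatenate(ens),
                           layer="evidence" if which == "E" else "dynamics")


class _ReadoutSimulator:
    """Feed-forward readout ensembles driven by the E-layer masses."""

    def __init__(self, spec: ReadoutSpec, tau: float, dt: float, epsp: str,
                 rng: np.random.Generator):
        self.spec = spec
        self.dt_s = dt * 1e-3
        self.rng = rng
        W = int(round(tau / dt))
        self.mass = _MassAccumulator(spec.n_out, W, epsp, dt, tau)

    def step(self, A_in: np.ndarray) -> None:
        u = self.spec.weights @ A_in
        p = np.clip(u, 0.0, None) * self.dt_s
        if np.any(p > 1.0):
            raise ValueError("readout rate*dt exceeds 1")
        counts = self.rng.binomial(self.spec.K_out, p)
        self.mass.push(counts.astype(float))


@dataclass
class SimResult:
    """Output bundle of a circuit run."""

    trace: PosteriorTrace  # circuit ENS estimate over time
    masses: np.ndarray  # (nb+1, N) E-layer masses
    total_mass: np.ndarray  # (nb+1,)
    readout_traces: list[PosteriorTrace] = field(default_factory=list)
    rasters: dict | None = None


def _normalize_rows(masses: np.ndarray) -> np.ndarray:
    tot = masses.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = masses / tot
    probs[tot[:, 0] == 0] = np.nan
    return probs


def run_circuit(spec: CircuitSpec, aff_counts: np.ndarray | None,
                n_bins: int, p0: np.ndarray, rng: np.random.Generator,
                ctx_open: np.ndarray | None = None,
                ctx0: int | None = None,
                readouts: tuple[ReadoutSpec, ...] = (),
                record_spikes: bool = False) -> SimResult:
    """Run a (non-graded) circuit for ``n_bins`` bins.

    ``aff_counts``: (n_bins, J) afferent spikes per bin, or None.
    ``ctx_open``: (n_bins, M) bool hard-context gate openness per bin.
    """
    sim = CircuitSimulator(spec, rng, record_spikes=record_spikes)
    sim.initialize(p0, ctx0=ctx0)
    rsims = [_ReadoutSimulator(r, spec.tau, spec.dt, spec.epsp, rng)
             for r in readouts]
    N = spec.N
    mass_hist = np.empty((n_bins + 1, N))
    mass_hist[0] = sim.masses
    rmass_hist = [np.zeros((n_bins + 1, r.n_out)) for r in readouts]
    for b in range(n_bins):
        sim.step(aff_counts[b] if aff_counts is not None else None,
                 ctx_open=ctx_open[b] if ctx_open is not None else None)
        mass_hist[b + 1] = sim.masses
        for rs, hist in zip(rsims, rmass_hist):
            rs.step(sim.masses)
            hist[b + 1] = rs.mass.A
    times = np.arange(n_bins + 1) * spec.dt
    trace = PosteriorTrace(times=times, probs=_normalize_rows(mass_hist),
                           dt=spec.dt)
    rtraces = [PosteriorTrace(times=times, probs=_normalize_rows(h),
                              dt=spec.dt) for h in rmass_hist]
    rasters = None
    if record_spikes:
        rasters = {"E": sim.raster("E"), "D": sim.raster("D")}
    return SimResult(trace=trace, masses=mass_hist,
                     total_mass=np.asarray(sim.totals),
                     readout_traces=rtraces, rasters=rasters)
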