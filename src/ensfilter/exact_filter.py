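"""Exact filtering oracles, solved deterministically in discretized time.

The posterior over a discrete hidden state observed through Poisson point
events admits unnormalized masses ``L_i(t)`` with dynamics

    dL_i/dt = L_i ( sum_j w_ij s_j(t) - lam_bar_i )        (evidence)
            + sum_{k!=i} q_{k->i} L_k - L_i sum_{k!=i} q_{i->k}   (dynamics)

where ``s_j`` are afferent spike trains, ``lam_bar_i = sum_j lam_ij`` and
``q`` are CTMC transition rates; probabilities follow by normalization.
Afferent spikes are applied as exact per-bin multiplicative likelihood
factors ``lam_ij`` (the closed-form solution of the evidence part), so the
evidence-only integrator matches the closed form to machine precision; the
transition part is integrated by forward Euler.  Per-bin renormalization
avoids exponential blow-up of the masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .generative import CTMCSpec, ContextSchedule, ObservationModel
from .spiking_core import DT_MS, SpikeRaster

__all__ = [
    "PosteriorTrace",
    "baseline_input_only",
    "baseline_mixed_rates",
    "evidence_posterior_closed_form",
    "integrate_bayes",
    "integrate_context",
    "integrate_evidence",
    "integrate_evidence_epsp",
    "spike_counts_per_bin",
]


@dataclass
class PosteriorTrace:
    """Normalized distribution over states on a uniform time grid."""

    times: np.ndarray  # ms
    probs: np.ndarray  # (T, N); rows sum to 1 (NaN rows = undefined)
    dt: float = DT_MS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.times.size != self.probs.shape[0]:
            raise ValueError("times and probs misaligned")

    def at(self, t: float) -> np.ndarray:
        """Distribution at the last grid point <= t."""
        idx = int(np.searchsorted(self.times, t + 1e-9, side="right")) - 1
        return self.probs[max(idx, 0)]

    def to_frame(self):
        import pandas as pd

        n = self.probs.shape[1]
        return pd.DataFrame(self.probs,
                            columns=[f"state_{i}" for i in range(n)]
                            ).assign(time_ms=self.times)


def spike_counts_per_bin(raster: SpikeRaster, n_units: int, n_bins: int,
                         dt: float = DT_MS) -> np.ndarray:
    """(n_bins, n_units) spike counts; spikes are bin-left-aligned."""
    counts = np.zeros((n_bins, n_units), dtype=np.int64)
    keep = (raster.time_ms >= 0) & (raster.time_ms < n_bins * dt)
    b = np.floor(raster.time_ms[keep] / dt + 1e-9).astype(int)
    np.add.at(counts, (b, raster.neuron_id[keep]), 1)
    return counts


def _check_model(model: ObservationModel) -> None:
    if np.any(model.lam <= 0):
        raise ValueError("all observation rates must be strictly positive")


def _evidence_step(L: np.ndarray, model: ObservationModel,
                   counts_row: np.ndarray, dt: float) -> np.ndarray:
    L = L * np.exp(-model.lam_bar * dt * 1e-3)
    hot = np.nonzero(counts_row)[0]
    for j in hot:
        L = L * model.lam[:, j] ** counts_row[j]
    return L


def integrate_evidence(prior: np.ndarray, model: ObservationModel,
                       spikes: SpikeRaster, T: float,
                       dt: float = DT_MS) -> PosteriorTrace:
    """Posterior for a static hidden state from afferent point events."""
    _check_model(model)
    prior = np.asarray(prior, dtype=float)
    nb = int(round(T / dt))
    counts = spike_counts_per_bin(spikes, model.n_afferents, nb, dt)
    probs = np.empty((nb + 1, prior.size))
    L = prior / prior.sum()
    probs[0] = L
    for b in range(nb):
        L = _evidence_step(L, model, counts[b], dt)
        L = L / L.sum()
        probs[b + 1] = L
    return PosteriorTrace(times=np.arange(nb + 1) * dt, probs=probs, dt=dt)


def evidence_posterior_closed_form(prior: np.ndarray,
                                   model: ObservationModel,
                                   spikes: SpikeRaster,
                                   t: float) -> np.ndarray:
    """Closed form: ``L_i(t) = p_i exp(-lam_bar_i t) prod_j lam_ij^{N_j(t)}``."""
    _check_model(model)
    prior = np.asarray(prior, dtype=float)
    N_j = np.zeros(model.n_afferents)
    keep = (spikes.time_ms >= 0) & (spikes.time_ms < t)
    np.add.at(N_j, spikes.neuron_id[keep], 1)
    logL = (np.log(prior) - model.lam_bar * t * 1e-3
            + np.log(model.lam) @ N_j)
    logL -= logL.max()
    L = np.exp(logL)
    return L / L.sum()


def integrate_evidence_epsp(prior: np.ndarray, model: ObservationModel,
                            spikes: SpikeRaster, T: float, tau: float = 20.0,
                            shift: np.ndarray | float | None = None,
                            dt: float = DT_MS) -> PosteriorTrace:
    """Evidence integration driven by EPSP-filtered afferent traces.

    Rate-level integration of ``d log L_i/dt = sum_j w_ij y_j(t) -
    lam_bar_i`` with rectangular EPSPs of length ``tau`` and weights
    ``w_ij = (log lam_ij + c_j) / tau``.  Once every EPSP has been fully
    integrated the result equals the point-event solution for any shift
    ``c_j`` (the shift scales all masses alike and cancels in
    normalization).  Exact for bin-aligned spikes since the traces are
    piecewise constant on bins.
    """
    _check_model(model)
    prior = np.asarray(prior, dtype=float)
    J = model.n_afferents
    if shift is None:
        c = -np.log(model.lam).min(axis=0)
    else:
        c = np.broadcast_to(np.asarray(shift, dtype=float), (J,)).copy()
    w = (np.log(model.lam) + c[None, :]) / (tau * 1e-3)  # (N, J), 1/s
    nb = int(round(T / dt))
    counts = spike_counts_per_bin(spikes, J, nb, dt).astype(float)
    # y_j on bin b = number of spikes in (b*dt - tau, b*dt]
    W = int(round(tau / dt))
    csum = np.vstack([np.zeros(J), np.cumsum(counts, axis=0)])
    y = np.empty((nb, J))
    for b in range(nb):
        y[b] = csum[b + 1] - csum[max(b + 1 - W, 0)]
    logL = np.log(prior / prior.sum())
    probs = np.empty((nb + 1, prior.size))
    probs[0] = np.exp(logL)
    dts = dt * 1e-3
    for b in range(nb):
        logL = logL + (w @ y[b] - model.lam_bar) * dts
        z = logL - logL.max()
        probs[b + 1] = np.exp(z) / np.exp(z).sum()
    return PosteriorTrace(times=np.arange(nb + 1) * dt, probs=probs, dt=dt)


def _transition_step(L: np.ndarray, Q: np.ndarray, dt_s: float) -> np.ndarray:
    inflow = Q.T @ L
    outflow = Q.sum(axis=1) * L
    return L + dt_s * (inflow - outflow)


def integrate_bayes(prior: np.ndarray, model: ObservationModel | None,
                    ctmc: CTMCSpec, spikes: SpikeRaster | None, T: float,
                    dt: float = DT_MS) -> PosteriorTrace:
    """Bayesian filter for a CTMC hidden state with point-event evidence.

    With all transition rates zero this reduces exactly to
    :func:`integrate_evidence`; with ``model=None`` it tracks the prior
    evolution under the dynamics alone.
    """
    prior = np.asarray(prior, dtype=float)
    nb = int(round(T / dt))
    dt_s = dt * 1e-3
    if ctmc.rates.sum(axis=1).max() * dt_s > 0.1:
        warnings.warn("transition rates large for dt; Euler step may be "
                      "inaccurate", stacklevel=2)
    if model is not None:
        _check_model(model)
        counts = spike_counts_per_bin(spikes, model.n_afferents, nb, dt)
    probs = np.empty((nb + 1, prior.size))
    L = prior / prior.sum()
    probs[0] = L
    for b in range(nb):
        if model is not None:
            L = _evidence_step(L, model, counts[b], dt)
        L = _transition_step(L, ctmc.rates, dt_s)
        L = L / L.sum()
        probs[b + 1] = L
    return PosteriorTrace(times=np.arange(nb + 1) * dt, probs=probs, dt=dt)


def integrate_context(prior: np.ndarray, model: ObservationModel | None,
                      ctmc: CTMCSpec, context, spikes: SpikeRaster | None,
                      T: float, dt: float = DT_MS) -> PosteriorTrace:
    """Context-dependent Bayesian filter.

    ``context`` is either a :class:`ContextSchedule` (hard context: the
    scheduled context's rate matrix applies per bin) or an array of per-bin
    context beliefs of shape (n_bins, M) (graded context: the effective
    matrix is the belief-weighted linear mixture of the context matrices).
    """
    if ctmc.context_rates is None:
        raise ValueError("ctmc has no per-context rate matrices")
    prior = np.asarray(prior, dtype=float)
    nb = int(round(T / dt))
    dt_s = dt * 1e-3
    M = ctmc.n_contexts
    if isinstance(context, ContextSchedule):
        ctx = context.per_bin(dt)
        if ctx.size < nb:
            raise ValueError("context schedule does not cover [0, T]")
        Q_of_bin = lambda b: ctmc.context_rates[ctx[b]]  # noqa: E731
    else:
        belief = np.asarray(context, dtype=float)
        if belief.shape != (nb, M):
            raise ValueError("belief trace must have shape (n_bins, M)")
        Q_of_bin = lambda b: np.tensordot(belief[b], ctmc.context_rates,  # noqa: E731
                                          axes=1)
    if model is not None:
        _check_model(model)
        counts = spike_counts_per_bin(spikes, model.n_afferents, nb, dt)
    probs = np.empty((nb + 1, prior.size))
    L = prior / prior.sum()
    probs[0] = L
    for b in range(nb):
        if model is not None:
            L = _evidence_step(L, model, counts[b], dt)
        L = _transition_step(L, Q_of_bin(b), dt_s)
        L = L / L.sum()
        probs[b + 1] = L
    return PosteriorTrace(times=np.arange(nb + 1) * dt, probs=probs, dt=dt)


def baseline_input_only(model: ObservationModel, spikes: SpikeRaster,
                        T: float, dt: float = DT_MS) -> PosteriorTrace:
    """Most-recent-observation decoder.

    On bins with at least one afferent spike the estimate is the Bayes
    posterior of those spikes under a uniform prior; on silent bins the
    previous estimate is held.
    """
    _check_model(model)
    N = model.n_states
    nb = int(round(T / dt))
    counts = spike_counts_per_bin(spikes, model.n_afferents, nb, dt)
    probs = np.empty((nb + 1, N))
    est = np.full(N, 1.0 / N)
    probs[0] = est
    loglam = np.log(model.lam)
    for b in range(nb):
        if counts[b].any():
            logL = loglam @ counts[b]
            logL -= logL.max()
            L = np.exp(logL)
            est = L / L.sum()
        probs[b + 1] = est
    return PosteriorTrace(times=np.arange(nb + 1) * dt, probs=probs, dt=dt)


def baseline_mixed_rates(ctmc: CTMCSpec) -> CTMCSpec:
    """Context-blind CTMC: the arithmetic mean rate matrix over contexts."""
    if ctmc.context_rates is None or ctmc.n_contexts < 2:
        raise ValueError("need at least two context rate matrices")
    return CTMCSpec(rates=ctmc.context_rates.mean(axis=0),
                    min_dwell=ctmc.min_dwell)
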