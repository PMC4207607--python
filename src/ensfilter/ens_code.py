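"""Ensemble-based neural sampling (ENS) code.

A discrete random variable with ``N`` states is represented by ``N``
ensembles of ``K`` stochastic neurons.  Every spike is one sample of the
variable's value; with unit rectangular EPSPs of length ``tau`` the
probability mass ``A_i(t)`` of state ``i`` is simply the number of spikes
its ensemble emitted in ``(t - tau, t]``, and the represented distribution
is estimated by the relative portion of spikes,

    p_hat_i(t) = A_i(t) / sum_k A_k(t).

When ensemble neurons fire as Poisson processes with rates ``f * p_i`` the
estimator is unbiased for the tau-averaged probability, and its variance is
approximately ``p (1 - p) / S`` where ``S = K * f * tau`` — the *estimation
sample size*, the expected number of spikes from all ensembles per EPSP
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiking_core import EPSPKernel, SpikeRaster

__all__ = [
    "DistributionEstimate",
    "EnsembleCode",
    "estimate_distribution",
    "estimation_sample_size",
    "estimator_variance",
    "filtered_probability",
    "initialize_activity",
    "probability_mass",
]


@dataclass(frozen=True)
class EnsembleCode:
    """Parameters of an ENS representation.

    Parameters
    ----------
    N : number of states (>= 2).
    K : neurons per ensemble (*ensemble size*).
    f : maximal per-neuron rate in Hz (rate of a neuron whose state has
        probability 1).
    tau : EPSP length in ms.
    """

    N: int
    K: int
    f: float
    tau: float = 20.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least two states")
        if self.K < 1:
            raise ValueError("ensemble size K must be >= 1")
        if not self.f > 0:
            raise ValueError("rate scale f must be positive")
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    @property
    def sample_size(self) -> float:
        """Estimation sample size ``S = K * f * tau``."""
        return estimation_sample_size(self)

    @property
    def kernel(self) -> EPSPKernel:
        return EPSPKernel(shape="rect", tau=self.tau, amplitude=1.0)


@dataclass
class DistributionEstimate:
    """Per-state masses and the normalized ENS estimate."""

    masses: np.ndarray
    probs: np.ndarray
    valid: bool  # False when the total mass is zero (estimate undefined)


def estimation_sample_size(code: EnsembleCode) -> float:
    """Expected total spikes from all ensembles within one EPSP length.

    With rates ``f * p_i`` per neuron the ensemble totals sum to ``K * f``
    regardless of the distribution, hence ``S = K * f * tau``.
    """
    return code.K * code.f * code.tau * 1e-3


def probability_mass(raster: SpikeRaster, code: EnsembleCode, state: int,
                     t: float, kernel: EPSPKernel | None = None) -> float:
    """Summed EPSP-filtered activity ``A_i(t)`` of ensemble ``state``."""
    if not 0 <= state < code.N:
        raise ValueError(f"state {state} outside 0..{code.N - 1}")
    kernel = kernel or code.kernel
    times = raster.time_ms[raster.ensemble_id == state]
    return float(np.sum(kernel.value(t - times)))


def estimate_distribution(masses: np.ndarray) -> np.ndarray:
    """Normalize probability masses to the ENS estimate ``p_hat``.

    Raises when all masses are zero — the estimator needs at least one
    sample in the window.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses < 0):
        raise ValueError("masses must be non-negative")
    total = masses.sum()
    if total == 0:
        raise ValueError("no samples in window; estimate undefined")
    return masses / total


def estimator_variance(p: float, S: float) -> float:
    """Large-``S`` variance of the ENS estimator, ``p (1 - p) / S``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p * (1.0 - p) / S


def filtered_probability(p_of_t, t: float, tau: float,
                         n_quad: int = 256) -> float:
    """Moving average of a probability trajectory over ``(t - tau, t]``.

    This is the quantity the ENS estimator is unbiased for; uses midpoint
    quadrature on a callable ``p_of_t`` (ms argument).
    """
    s = np.linspace(t - tau, t, n_quad, endpoint=False) + tau / (2 * n_quad)
    return float(np.mean([p_of_t(si) for si in s]))


def initialize_activity(p0: np.ndarray, code: EnsembleCode,
                        rng: np.random.Generator,
                        layer: str = "") -> SpikeRaster:
    """Seed spikes on ``[-tau, 0)`` so the mass at t=0 represents ``p0``.

    Each neuron of ensemble ``i`` spikes at most once, with probability
    ``S * p0_i / K``, at a time uniform in ``[-tau, 0)``; the expected
    initial mass is then ``S * p0_i``.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (code.N,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
        raise ValueError("p0 must be a distribution over the N states")
    S = code.sample_size
    prob = S * p0 / code.K
    if np.any(prob > 1.0):
        raise ValueError("S * p0_i / K exceeds 1; ensemble size K too small")
    hits = rng.random((code.N, code.K)) < prob[:, None]
    ens, neu = np.nonzero(hits)
    times = rng.uniform(-code.tau, 0.0, size=ens.size)
    return SpikeRaster(neuron_id=ens * code.K + neu, time_ms=times,
                       ensemble_id=ens, layer=layer)
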