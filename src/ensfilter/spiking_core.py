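"""Spike trains, EPSP kernels and stochastic spike generation.

Neurons are stochastic spike-response units: a membrane potential ``u`` is
mapped through a rectified-linear link function to an instantaneous Poisson
rate ``r = f * max(u, 0)``, discretized as one Bernoulli draw per time bin.
Postsynaptic traces are spike trains convolved with an EPSP kernel; with the
unit-amplitude rectangular kernel of length ``tau`` used throughout, the
filtered trace of a train at time ``t`` is exactly the number of spikes in
the half-open window ``(t - tau, t]``, i.e. a running sample count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DT_MS",
    "EPSPKernel",
    "RateTrace",
    "SpikeRaster",
    "SpikeTrain",
    "filtered_trace",
    "link_rate",
    "sample_spikes",
]

#: Default simulation time step (ms).
DT_MS = 0.5


@dataclass(frozen=True)
class EPSPKernel:
    """Causal EPSP shape: ``rect`` (boxcar on [0, tau)) or ``exp`` decay.

    ``amplitude`` defaults to 1 for the rectangular kernel so filtered traces
    count spikes.  An exponential kernel matched to a rectangular one of the
    same ``tau`` keeps the time integral unchanged, i.e. ``amplitude *
    tau == 1 * tau`` giving amplitude 1 as well.
    """

    shape: str = "rect"
    tau: float = 20.0  # ms; boxcar length, or decay constant for "exp"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("rect", "exp"):
            raise ValueError(f"unknown EPSP shape {self.shape!r}")
        if not self.tau > 0:
            raise ValueError("EPSP tau must be positive")
        if not self.amplitude > 0:
            raise ValueError("EPSP amplitude must be positive")

    def value(self, t):
        """Kernel value at lag ``t`` ms (array-friendly); 0 for t < 0."""
        t = np.asarray(t, dtype=float)
        if self.shape == "rect":
            out = np.where((t >= 0) & (t < self.tau), self.amplitude, 0.0)
        else:
            out = np.where(t >= 0, self.amplitude * np.exp(-t / self.tau), 0.0)
        return out if out.ndim else float(out)

    def integral(self) -> float:
        """Time integral of the kernel (ms units)."""
        return self.amplitude * self.tau

    def support_above(self, theta: float) -> float:
        """Lag (ms) for which the kernel stays >= ``theta``.

        Used by disinhibition gates: a single spike keeps its gate open for
        this long.  Infinite thresholds yield 0.
        """
        if theta > self.amplitude:
            return 0.0
        if self.shape == "rect":
            return self.tau
        return self.tau * math.log(self.amplitude / theta)

    @staticmethod
    def matched_exponential(tau: float) -> "EPSPKernel":
        """Exponential kernel with the same integral as the unit boxcar."""
        return EPSPKernel(shape="exp", tau=tau, amplitude=1.0)


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) of one neuron.

    Initialization spikes may lie in ``[-tau, 0)``; all other times must be
    non-negative.
    """

    times: np.ndarray
    neuron_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def filtered_trace(spikes: SpikeTrain | Sequence[float] | np.ndarray,
                   kernel: EPSPKernel, t) -> np.ndarray | float:
    """EPSP-filtered spike train ``y(t) = sum_j kernel(t - t_j)``.

    For the unit rectangular kernel this equals the spike count in
    ``(t - tau, t]``.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(
        spikes, dtype=float)
    t = np.asarray(t, dtype=float)
    lags = t[..., None] - times[None, :] if t.ndim else t - times
    vals = kernel.value(lags)
    out = np.sum(vals, axis=-1)
    return out if np.ndim(out) else float(out)


def link_rate(u, f: float):
    """Rectified-linear link: instantaneous rate ``f * max(u, 0)`` (Hz)."""
    if not f > 0:
        raise ValueError("rate scale f must be positive")
    return f * np.maximum(np.asarray(u, dtype=float), 0.0)


@dataclass
class RateTrace:
    """Per-bin instantaneous rate (Hz) on a uniform grid with step ``dt`` ms."""

    dt: float
    values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if np.any(self.values < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class SpikeRaster:
    """Flat event table of a population: parallel arrays of equal length.

    ``neuron_id`` indexes neurons within the population, ``ensemble_id`` the
    ensemble each spike's neuron belongs to (-1 when ungrouped), ``layer`` an
    optional label shared by the whole raster.
    """

    neuron_id: np.ndarray
    time_ms: np.ndarray
    ensemble_id: np.ndarray | None = None
    layer: str = ""

    def __post_init__(self) -> None:
        self.neuron_id = np.asarray(self.neuron_id, dtype=int)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.ensemble_id is None:
            self.ensemble_id = np.full(self.neuron_id.size, -1, dtype=int)
        else:
            self.ensemble_id = np.asarray(self.ensemble_id, dtype=int)
        if not (self.neuron_id.size == self.time_ms.size
                == self.ensemble_id.size):
            raise ValueError("raster columns must have equal length")

    def __len__(self) -> int:
        return self.time_ms.size

    def train(self, neuron_id: int) -> SpikeTrain:
        """Sorted spike train of one neuron."""
        t = np.sort(self.time_ms[self.neuron_id == neuron_id])
        return SpikeTrain(times=t, neuron_id=neuron_id)

    def to_frame(self):
        """Events as a pandas DataFrame (neuron_id, ensemble_id, layer, time_ms)."""
        import pandas as pd

        return pd.DataFrame({
            "neuron_id": self.neuron_id,
            "ensemble_id": self.ensemble_id,
            "layer": self.layer,
            "time_ms": self.time_ms,
        })

    @staticmethod
    def concatenate(rasters: Sequence["SpikeRaster"]) -> "SpikeRaster":
        return SpikeRaster(
            neuron_id=np.concatenate([r.neuron_id for r in rasters]),
            time_ms=np.concatenate([r.time_ms for r in rasters]),
            ensemble_id=np.concatenate([r.ensemble_id for r in rasters]),
            layer=rasters[0].layer if rasters else "",
        )


def sample_spikes(rate: RateTrace, rng: np.random.Generator,
                  neuron_id: int = 0) -> SpikeTrain:
    """Bernoulli-per-bin realization of an inhomogeneous Poisson rate.

    Each bin spikes independently with probability ``r * dt`` (dt in seconds);
    spike times are bin-left-aligned.  ``r * dt > 1`` signals a too-coarse
    discretization and raises.
    """
    p = rate.values * rate.dt * 1e-3
    if np.any(p > 1.0):
        raise ValueError("r*dt exceeds 1 in at least one bin; decrease dt")
    hits = rng.random(p.size) < p
    times = np.nonzero(hits)[0] * rate.dt
    return SpikeTrain(times=times, neuron_id=neuron_id)
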