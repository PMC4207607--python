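"""Performance metrics and method comparisons.

The benchmark error measure is the fraction of incorrect state estimates:
per time bin the argmax of the posterior is the predicted state, compared
against the true path.  Method comparisons report per-sequence means and
SDs and a paired t-test between the spiking circuit and the context-blind
mixed-rate filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exact_filter import PosteriorTrace
from .generative import StatePath

__all__ = [
    "PerformanceReport",
    "compare_methods",
    "fraction_incorrect",
    "trial_success",
]


def fraction_incorrect(trace: PosteriorTrace, path: StatePath) -> float:
    """Fraction of bins where the posterior argmax misses the true state.

    Ties resolve to the lowest state index; bins with an undefined
    posterior (zero total mass) count as incorrect.
    """
    states = path.per_bin(trace.dt)
    nb = states.size
    if trace.probs.shape[0] < nb:
        raise ValueError("trace does not cover the state path")
    probs = trace.probs[:nb]
    pred = np.where(np.isnan(probs).any(axis=1), -1, np.argmax(probs, axis=1))
    return float(np.mean(pred != states))


def trial_success(readout_trace: PosteriorTrace, rewarded_action: int,
                  window_ms: float = 100.0,
                  t_end_ms: float | None = None) -> bool:
    """Did the readout select the rewarded action?

    Success iff the argmax of the readout's time-averaged distribution over
    the final ``window_ms`` (ending at ``t_end_ms``, default: end of trace)
    is the rewarded action; ties resolve to the lowest index.
    """
    t_end = readout_trace.times[-1] if t_end_ms is None else t_end_ms
    sel = (readout_trace.times > t_end - window_ms) & (readout_trace.times
                                                       <= t_end)
    window = readout_trace.probs[sel]
    mean = np.nanmean(window, axis=0)
    if np.all(np.isnan(mean)):
        return False
    return int(np.nanargmax(mean)) == rewarded_action


@dataclass
class PerformanceReport:
    """Per-method error summary over a batch of sequences."""

    methods: list[str]
    mean: dict[str, float]
    sd: dict[str, float]
    per_sequence: dict[str, np.ndarray]
    paired_test: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "mean": self.mean,
            "sd": self.sd,
            "paired_test": self.paired_test,
        }

    def table(self) -> str:
        lines = [f"{'method':<8}{'mean err':>10}{'sd':>10}"]
        for m in self.methods:
            lines.append(f"{m:<8}{self.mean[m]:>10.4f}{self.sd[m]:>10.4f}")
        if self.paired_test:
            pt = self.paired_test
            lines.append(f"paired t-test {pt['a']} < {pt['b']}: "
                         f"t={pt['t']:.3f}, p={pt['p']:.2g}")
        return "\n".join(lines)


def compare_methods(errors: dict[str, np.ndarray],
                    paired: tuple[str, str] | None = ("model", "mix"),
                    one_sided: bool = True) -> PerformanceReport:
    """Summarize per-sequence error fractions of several methods.

    ``errors`` maps method name to the per-sequence error array (all
    evaluated on the same sequences).  When both members of ``paired`` are
    present, a paired t-test of method ``a`` beating method ``b`` is run
    (one-sided by default).
    """
    methods = list(errors)
    lengths = {len(v) for v in errors.values()}
    if len(lengths) != 1:
        raise ValueError("all methods must cover the same sequences")
    per_seq = {m: np.asarray(v, dtype=float) for m, v in errors.items()}
    report = PerformanceReport(
        methods=methods,
        mean={m: float(v.mean()) for m, v in per_seq.items()},
        sd={m: float(v.std(ddof=1)) if v.size > 1 else 0.0
            for m, v in per_seq.items()},
        per_sequence=per_seq,
    )
    if paired and paired[0] in per_seq and paired[1] in per_seq:
        a, b = paired
        alternative = "less" if one_sided else "two-sided"
        t, p = stats.ttest_rel(per_seq[a], per_seq[b],
                               alternative=alternative)
        report.paired_test = {"a": a, "b": b, "t": float(t), "p": float(p),
                              "alternative": alternative}
    return report
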