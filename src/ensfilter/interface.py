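"""Run configuration, serialization and the reproducible experiment runner."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .scenarios import SCENARIO_NAMES, draw_batch, make_scenario

__all__ = ["RunConfig", "load_config", "run_experiment", "save_config"]

log = logging.getLogger("ensfilter")

_KNOWN_KEYS = {"scenario", "seed", "epsp", "inh_delay_ms", "nu", "out_dir",
               "oracle", "n_trials", "overrides"}


@dataclass
class RunConfig:
    """Validated configuration of one experiment run."""

    scenario: str
    seed: int
    epsp: str = "rect"
    inh_delay_ms: float = 0.5
    nu: float | None = None
    out_dir: str = "ensfilter_out"
    oracle: str = "opt"
    n_trials: int = 1
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose "
                             f"from {SCENARIO_NAMES}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.epsp not in ("rect", "exp"):
            raise ValueError("epsp must be 'rect' or 'exp'")
        if self.oracle not in ("opt", "inp", "mix"):
            raise ValueError("oracle must be one of opt/inp/mix")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")


def load_config(path: str | Path, strict: bool = True) -> RunConfig:
    """Load a YAML/JSON run configuration.

    Unknown keys produce a warning and, in strict mode, a rejection.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"malformed config {path}: expected a mapping")
    extra = set(data) - _KNOWN_KEYS
    if extra:
        warnings.warn(f"unknown config keys {sorted(extra)}", stacklevel=2)
        if strict:
            raise ValueError(f"unknown config keys {sorted(extra)}")
        data = {k: v for k, v in data.items() if k in _KNOWN_KEYS}
    if "seed" not in data:
        raise ValueError("config is missing the mandatory 'seed'")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: RunConfig) -> dict:
    """Run a scenario batch, write traces + manifest, return the bundle.

    Deterministic given the seed: one master seed spawns independent child
    streams per trial, so earlier trials are unaffected by the trial
    count.
    """
    scenario = make_scenario(config.scenario, **config.overrides)
    if config.nu is not None:
        scenario.nu = config.nu
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log.info("running %s: %d trial(s), seed %d", config.scenario,
             config.n_trials, config.seed)
    batch = draw_batch(scenario, config.n_trials, rng)
    for k, res in enumerate(batch):
        for key in ("circuit_trace", "readout_trace", "phase_trace",
                    "main_trace", "opt_trace", "inp_trace", "mix_trace"):
            if key in res and res[key] is not None:
                res[key].to_frame().to_csv(
                    out / f"trial{k:03d}_{key.replace('_trace', '')}.csv",
                    index=False)
        log.info("trial %d done", k)
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_trials": config.n_trials,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"scenario": scenario, "batch": batch, "manifest": manifest}
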