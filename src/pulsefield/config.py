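"""Experiment configuration: structured key-value files tying runs together.

A config file (YAML) mirrors the domain objects section by section
(kernel, firing, stimulus, noise, grid, run).  Every run writes the fully
resolved config and seed next to its outputs so that any result can be
regenerated from its artifact directory alone.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kernels import WeightKernel
from .free_pulse import FiringRule
from .stimulus_locked import StimulusSpec
from .stochastic_sim import NoiseModel, SimGrid

__all__ = ["ExperimentConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a config file is missing or malforms a required field."""


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"[{name}] unknown fields: {sorted(unknown)}")
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(section)
    if missing:
        raise ConfigError(f"[{name}] missing required fields: {sorted(missing)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[{name}] {exc}") from exc


@dataclass
class ExperimentConfig:
    """Fully resolved parameters of one experiment run."""

    kernel: WeightKernel
    firing: FiringRule
    noise: NoiseModel | None = None
    stimulus: StimulusSpec | None = None
    grid: SimGrid | None = None
    n_trials: int = 1
    seed: int = 0
    record_every: float = 0.5
    out_dir: str = "runs"
    options: dict = field(default_factory=dict)  # subcommand-specific extras

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        if "kernel" not in data:
            raise ConfigError("missing required section: kernel")
        if "firing" not in data:
            raise ConfigError("missing required section: firing")
        kernel = _build(WeightKernel, data["kernel"], "kernel")
        firing = _build(FiringRule, data["firing"], "firing")
        noise = _build(NoiseModel, data["noise"], "noise") if data.get("noise") else None
        stimulus = (
            _build(StimulusSpec, data["stimulus"], "stimulus") if data.get("stimulus") else None
        )
        grid = _build(SimGrid, data["grid"], "grid") if data.get("grid") else None
        run = data.get("run", {})
        cfg = cls(
            kernel=kernel,
            firing=firing,
            noise=noise,
            stimulus=stimulus,
            grid=grid,
            n_trials=int(run.get("n_trials", 1)),
            seed=int(run.get("seed", 0)),
            record_every=float(run.get("record_every", 0.5)),
            out_dir=str(run.get("out_dir", "runs")),
            options=dict(data.get("options", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("[run] n_trials must be >= 1")
        if self.noise is not None and self.grid is not None and self.noise.eps > 0:
            if self.noise.corr_len == 0.0 and abs(self.noise.C0 * self.grid.dx - 1.0) > 1e-9:
                warnings.warn(
                    f"noise C0={self.noise.C0} is inconsistent with the lattice "
                    f"white-noise limit C0 = 1/dx = {1.0 / self.grid.dx:g}; "
                    "the simulator will reject this combination",
                    stacklevel=2,
                )

    def to_dict(self) -> dict:
        data: dict = {
            "kernel": dataclasses.asdict(self.kernel),
            "firing": dataclasses.asdict(self.firing),
            "run": {
                "n_trials": self.n_trials,
                "seed": self.seed,
                "record_every": self.record_every,
                "out_dir": self.out_dir,
            },
        }
        for name in ("noise", "stimulus", "grid"):
            obj = getattr(self, name)
            if obj is not None:
                data[name] = dataclasses.asdict(obj)
        if self.options:
            data["options"] = dict(self.options)
        return data

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def write_resolved(self, directory) -> Path:
        """Record the full resolved config alongside run outputs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "config.resolved.yaml"
        path.write_text(self.to_yaml())
        return path
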