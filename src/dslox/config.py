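"""Run configuration: one YAML-serializable block per pipeline stage.

A single global seed governs all stochastic stages (fanned out through
:func:`dslox.pipeline.stage_seed`); a config round-trips through YAML
unchanged, which the benchmark relies on for reproducible reruns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import yaml

from .dsl import TrainingConfig
from .synthetic import NoiseModel, SyntheticDatasetConfig, VentilationState

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the end-to-end benchmark."""

    seed: int = 0
    simulation: SyntheticDatasetConfig = field(default_factory=SyntheticDatasetConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    networks: Tuple[str, ...] = ("fnn", "cnn")
    lsf_w_grid: Tuple[float, ...] = (0.0, 0.06, 0.12, 0.18, 0.24)
    lsf_subsample: int = 400
    sigma0_list: Tuple[float, ...] = (0.03, 0.05, 0.07, 0.09)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # keep YAML plain: dataclasses already expanded; tuples -> lists
        return _plain(d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        states = {
            int(k): tuple(VentilationState(**s) for s in v)
            for k, v in sim.pop("states_per_setup", {}).items()
        }
        sim_kwargs = dict(sim)
        for key in ("n_rats_per_setup", "train_totals", "test_totals"):
            if key in sim_kwargs:
                sim_kwargs[key] = {int(k): int(v) for k, v in sim_kwargs[key].items()}
        if "bias_coefficients" in sim_kwargs:
            sim_kwargs["bias_coefficients"] = {
                int(k): tuple(v) for k, v in sim_kwargs["bias_coefficients"].items()
            }
        if "noise" in sim_kwargs:
            sim_kwargs["noise"] = NoiseModel(**sim_kwargs["noise"])
        if states:
            sim_kwargs["states_per_setup"] = states
        training = TrainingConfig(**d.pop("training", {}))
        return cls(
            seed=d.pop("seed", 0),
            simulation=SyntheticDatasetConfig(**sim_kwargs),
            training=training,
            networks=tuple(d.pop("networks", ("fnn", "cnn"))),
            lsf_w_grid=tuple(d.pop("lsf_w_grid", (0.0, 0.06, 0.12, 0.18, 0.24))),
            lsf_subsample=int(d.pop("lsf_subsample", 400)),
            sigma0_list=tuple(d.pop("sigma0_list", (0.03, 0.05, 0.07, 0.09))),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
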