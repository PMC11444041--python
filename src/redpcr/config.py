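"""Pipeline configuration: one flat YAML document driving every stage.

The configuration round-trips losslessly through YAML and rejects unknown
keys, so a typo in a parameter name fails loudly instead of silently running
with a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .assay_sim import SelectionParams, SimulationConfig
from .quantify import DEFAULT_SPIKE_DILUTION
from .selection_stats import ClassifierThresholds


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; the single seed feeds every random stream."""

    seed: int = 0
    n_sperm: int = 57
    n_blood: int = 5
    age_min: float = 24.0
    age_max: float = 75.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc_min_depth: int = 1000
    qc_min_integrant: int = 250
    spike_dilution: float = DEFAULT_SPIKE_DILUTION
    alpha: float = 0.05
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, simulation=replace(self.simulation, seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["selection_params"] = {
            m: asdict(p) for m, p in self.simulation.selection_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        _check_keys(data, cls, "config")
        sim_data = dict(data.pop("simulation", {}))
        _check_keys(sim_data, SimulationConfig, "simulation")
        sel = sim_data.pop("selection_params", None)
        if sel is not None:
            params = {}
            for m, p in sel.items():
                _check_keys(dict(p), SelectionParams, f"selection_params.{m}")
                params[m] = SelectionParams(**p)
            sim_data["selection_params"] = params
        thr_data = dict(data.pop("thresholds", {}))
        _check_keys(thr_data, ClassifierThresholds, "thresholds")
        return cls(
            simulation=SimulationConfig(**sim_data),
            thresholds=ClassifierThresholds(**thr_data),
            **data,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)


def _check_keys(data: dict, klass, where: str) -> None:
    known = {f.name for f in fields(klass)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {unknown}")
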