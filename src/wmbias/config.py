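"""Run configuration: YAML/JSON serialization of designs, observers, options.

A run is reproducible from its config plus master seed alone; loading a
config expands every omitted field to its recorded default so the manifest
always contains a complete specification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import InvalidDesignError, InvalidParameterError
from .simulate import (
    ExperimentDesign,
    ObserverSpec,
    exp1_design,
    exp2_design,
    exp3_design,
)

__all__ = ["RunConfig", "design_from_id", "load_config", "observers_from_config"]

_DESIGNS = {"exp1": exp1_design, "exp2": exp2_design, "exp3": exp3_design}


def design_from_id(design_id: str, stimulus_domain: str | None = None) -> ExperimentDesign:
    if design_id not in _DESIGNS:
        raise InvalidDesignError(
            f"unknown design_id {design_id!r}; expected one of {sorted(_DESIGNS)}"
        )
    factory = _DESIGNS[design_id]
    return factory(stimulus_domain) if stimulus_domain else factory()


@dataclass
class RunConfig:
    """Complete, serializable description of one simulate/analyze/fit run."""

    seed: int = 0
    design_id: str = "exp1"
    stimulus_domain: str | None = None
    n_participants: int = 16
    observer: dict = field(default_factory=dict)  # ObserverSpec field overrides
    population: dict = field(default_factory=dict)  # exp3 log-normal kappa params
    analysis: dict = field(
        default_factory=lambda: {"bin_width": 5.0, "outlier_sd": 3.0,
                                 "high_confidence_only": True}
    )
    fit: dict = field(
        default_factory=lambda: {"kappa_m_source": "baseline",
                                 "judged_similar_only": True}
    )
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        design_from_id(cfg.design_id, cfg.stimulus_domain)  # validate early
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a run config from YAML (or JSON, which is a YAML subset)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"config {path} did not parse to a mapping")
    return RunConfig.from_dict(raw)


def observers_from_config(cfg: RunConfig, rng=None) -> list[ObserverSpec]:
    """Build the cohort of generative observers a config describes.

    With a ``population`` block, memory precision varies log-normally across
    participants (the individual-differences design); otherwise all
    participants share one :class:`ObserverSpec` built from the ``observer``
    overrides.
    """
    base = ObserverSpec(**cfg.observer)
    if cfg.population:
        from .simulate import generate_population_exp3

        import numpy as np

        pop_rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
        return generate_population_exp3(
            n=cfg.population.get("n", cfg.n_participants),
            median_kappa=cfg.population.get("median_kappa", 12.0),
            sigma_log=cfg.population.get("sigma_log", 0.4),
            seed=pop_rng,
            base=base,
        )
    return [base] * cfg.n_participants


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path
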