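"""YAML configuration loading with fail-fast validation.

A config file has at most two top-level sections::

    simulation:      # SimulationConfig fields
      n_domains: 100
      seed: 7
    pipeline:        # PipelineConfig fields (spot_params / particle_params nested)
      radius_factor: 1.0
      spot_params:
        k_mad: 5.0

Missing sections and keys take the documented defaults; unknown keys are
rejected with the offending name.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .pipeline import PipelineConfig
from .simulate import ConfigurationError, SimulationConfig

_SECTIONS = {"simulation", "pipeline"}


def load_config(path_or_dict) -> tuple[SimulationConfig, PipelineConfig]:
    """Load (simulation, pipeline) configs from YAML or a dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    try:
        sim = SimulationConfig.from_dict(raw.get("simulation") or {})
        pipe = PipelineConfig.from_dict(raw.get("pipeline") or {})
    except TypeError as exc:  # wrong value type for a known key
        raise ConfigurationError(str(exc)) from exc
    return sim, pipe


def dump_config(sim: SimulationConfig, pipe: PipelineConfig, path=None) -> str:
    """Serialise both sections to YAML (defaults filled in and echoed)."""
    text = yaml.safe_dump(
        {"simulation": sim.to_dict(), "pipeline": pipe.to_dict()},
        sort_keys=True,
    )
    if path is not None:
        Path(path).write_text(text)
    return text
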