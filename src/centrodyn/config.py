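"""Structured run configuration: YAML in, validated dataclasses out.

Every parameter has a default; unknown keys are rejected so a typo cannot
silently fall back to a default.  A single global seed fans out
deterministically to per-module child seeds via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cellcycle import CellCycleParams, LabelingProtocol, LoadingRule
from .inheritance import PROTEIN_PRESETS, RetentionModel
from .spot_quant import QuantConfig
from .synthetic_imaging import ImagingParams

__all__ = ["RunConfig", "load_config", "child_seeds"]


def _build(dc_type, mapping: dict | None):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    mapping = dict(mapping or {})
    names = {f.name for f in dataclasses.fields(dc_type)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {dc_type.__name__} keys: {sorted(unknown)}")
    # YAML has no tuples; coerce lists for tuple-typed defaults
    for f in dataclasses.fields(dc_type):
        if f.name in mapping and isinstance(mapping[f.name], list):
            mapping[f.name] = tuple(mapping[f.name])
    return dc_type(**mapping)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for end-to-end experiment runs."""

    seed: int = 0
    outdir: str = "results"
    protein: str = "CID"  # preset: CID, CENP-C or CAL1
    n_day1: int = 200
    n_day2: int = 200
    n_population: int = 10000
    imaging: ImagingParams = field(default_factory=ImagingParams)
    quant: QuantConfig = field(default_factory=QuantConfig)
    inheritance: RetentionModel | None = None  # None -> protein preset
    cellcycle: CellCycleParams = field(default_factory=CellCycleParams)
    protocol: LabelingProtocol = field(default_factory=LabelingProtocol)
    loading: LoadingRule | None = None  # None -> protein preset

    def retention_model(self) -> RetentionModel:
        if self.inheritance is not None:
            return self.inheritance
        if self.protein not in PROTEIN_PRESETS:
            raise ValueError(f"no inheritance preset for protein {self.protein!r}")
        return PROTEIN_PRESETS[self.protein]

    def loading_rule(self) -> LoadingRule:
        if self.loading is not None:
            return self.loading
        from .cellcycle import LOADING_PRESETS

        if self.protein not in LOADING_PRESETS:
            raise ValueError(f"no loading preset for protein {self.protein!r}")
        return LOADING_PRESETS[self.protein]

    def echo(self) -> dict[str, Any]:
        """Full parameter echo for report embedding."""

        def as_dict(obj):
            if obj is None:
                return None
            if dataclasses.is_dataclass(obj):
                return {
                    k: as_dict(v) for k, v in dataclasses.asdict(obj).items()
                }
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {f.name: as_dict(getattr(self, f.name)) for f in dataclasses.fields(self)}


_SECTION_TYPES = {
    "imaging": ImagingParams,
    "quant": QuantConfig,
    "inheritance": RetentionModel,
    "cellcycle": CellCycleParams,
    "protocol": LabelingProtocol,
    "loading": LoadingRule,
}


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file path or a mapping (or defaults)."""
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        data = yaml.safe_load(Path(source).read_text()) or {}
    kwargs: dict[str, Any] = {}
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            kwargs[key] = _build(_SECTION_TYPES[key], value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-module child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
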