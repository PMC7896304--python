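"""Run configuration: one YAML document driving every pipeline stage.

Unknown keys are rejected so that typos fail loudly rather than silently
falling back to defaults.  Per-stage seeds are derived from the global
seed and the stage name (CRC32), so any stage can be rerun independently
with identical results.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .ensemble.config import EnsembleConfig


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class WorldConfig:
    n_rows: int = 40
    n_cols: int = 40
    cell_area: float = 1.0
    autocorr_range: float = 3.0
    n_realms: int = 2
    n_ecoregions: int = 12
    n_countries: int = 8
    barrier_fraction: float = 0.15
    n_species: int = 20
    niche_breadth_lo: float = 0.6
    niche_breadth_hi: float = 1.4
    prevalence_lo: float = 0.1
    prevalence_hi: float = 0.4
    gradient_strength: float = 1.0


@dataclass
class PrepConfig:
    n_pseudoabsences: int = 1000
    min_presence_cells: int = 10


@dataclass
class SelectionConfig:
    enabled: bool = True
    min_size: int = 3
    max_size: int = 8
    r_max: float = 0.7
    n_test_species: int = 20  # full-scale runs would use ~200 per taxon group


@dataclass
class BlockingConfig:
    n_blocks: int = 10
    area_weight: float = 1.0
    climate_weight: float = 1.0


@dataclass
class AggregationConfig:
    scenario: str = "rcp85"
    taxon: str = "both"  # both | bird | mammal


@dataclass
class BordersConfig:
    enabled: bool = True
    scenario: str = "rcp85"
    taxon: str = "both"


def _from_mapping(cls, mapping: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {where!r}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**mapping)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/demo"
    fast_profile: bool = True  # desk-scale ensemble hyperparameters
    world: WorldConfig = field(default_factory=WorldConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    blocking: BlockingConfig = field(default_factory=BlockingConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    borders: BordersConfig = field(default_factory=BordersConfig)

    _SECTIONS = {
        "world": WorldConfig,
        "prep": PrepConfig,
        "selection": SelectionConfig,
        "blocking": BlockingConfig,
        "aggregation": AggregationConfig,
        "borders": BordersConfig,
    }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        kwargs = {}
        for name, sect_cls in cls._SECTIONS.items():
            if name in doc:
                kwargs[name] = _from_mapping(sect_cls, doc.pop(name), name)
        for scalar in ("seed", "outdir", "fast_profile"):
            if scalar in doc:
                kwargs[scalar] = doc.pop(scalar)
        if doc:
            raise ValueError(
                f"unknown top-level config key(s): {sorted(doc)}"
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def ensemble_config(self) -> EnsembleConfig:
        cfg = EnsembleConfig.fast() if self.fast_profile else EnsembleConfig()
        if self.blocking.n_blocks != cfg.n_blocks:
            from dataclasses import replace

            cfg = replace(cfg, n_blocks=self.blocking.n_blocks)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)
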