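"""TOML configuration holding every tunable threshold in one place.

The file mirrors the module config dataclasses; any omitted key keeps its
default.  Example::

    [chains]
    t = 1e-3
    b_min = 6

    [foldback]
    p_threshold = 0.02
    max_mean_depth = 75
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib

from .catalog import UniquenessConfig
from .chains import ChainConfig
from .contig import ScoringConfig
from .foldback import FoldbackConfig

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 1
    uniqueness: UniquenessConfig = dataclasses.field(default_factory=UniquenessConfig)
    chains: ChainConfig = dataclasses.field(default_factory=ChainConfig)
    foldback: FoldbackConfig = dataclasses.field(default_factory=FoldbackConfig)
    contig: ScoringConfig = dataclasses.field(default_factory=ScoringConfig)
    genome: dict[str, int] = dataclasses.field(default_factory=dict)
    centromeres: dict[str, int] = dataclasses.field(default_factory=dict)


_SECTIONS = {
    "uniqueness": UniquenessConfig,
    "chains": ChainConfig,
    "foldback": FoldbackConfig,
    "contig": ScoringConfig,
}


def load_config(path: str | None = None) -> PipelineConfig:
    """Load a PipelineConfig from TOML; None gives all defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "seed" in data:
        cfg.seed = int(data["seed"])
    for section, cls in _SECTIONS.items():
        if section in data:
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(data[section]) - fields
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            # tuples arrive from TOML as lists
            kwargs = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in data[section].items()}
            setattr(cfg, section, cls(**kwargs))
    cfg.genome = {k: int(v) for k, v in data.get("genome", {}).items()}
    cfg.centromeres = {k: int(v) for k, v in data.get("centromeres", {}).items()}
    log.info("loaded config from %s (seed=%d)", path, cfg.seed)
    return cfg
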