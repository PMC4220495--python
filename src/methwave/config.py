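"""Pipeline configuration: every tunable numeric parameter with its default,
YAML round-trip, and logging setup."""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .chromatin import EnrichParams
from .dmr import DmrParams
from .genic import DomainParams, GenicParams
from .preprocess import PreprocessParams


@dataclass(frozen=True)
class PipelineConfig:
    """All numeric knobs of the pipeline in one place.

    Thresholds are fractions in [0, 1] internally; values quoted in percent
    elsewhere are converted exactly once, here.  Chromosome names are
    matched exactly unless ``chrom_alias_style`` is set ("chr" or "plain"),
    which remaps names at read time.
    """

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    dmr: DmrParams = field(default_factory=DmrParams)
    genic: GenicParams = field(default_factory=GenicParams)
    domain: DomainParams = field(default_factory=DomainParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    seed: int = 0
    chrom_alias_style: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sections = {
            "preprocess": PreprocessParams, "dmr": DmrParams,
            "genic": GenicParams, "domain": DomainParams,
            "enrich": EnrichParams,
        }
        for key, typ in sections.items():
            if key in raw:
                kwargs[key] = typ(**raw.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs, **raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
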