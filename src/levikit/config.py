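"""Pipeline configuration: one flat, serialisable record of every stage
parameter, funnelling all randomness through a single seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hairpin import TrCriteria
from .similarity import AlignmentParams


@dataclass
class PipelineConfig:
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    tr_criteria: TrCriteria = field(default_factory=TrCriteria)
    cluster_threshold: float = 0.7
    flank: int = 20
    min_loop: int = 3
    min_protein_length: int = 30
    overlap_tolerance: int = 30
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tr_criteria"]["weights"] = list(d["tr_criteria"]["weights"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "alignment" in data:
            data["alignment"] = AlignmentParams(**data["alignment"])
        if "tr_criteria" in data:
            tc = dict(data["tr_criteria"])
            if "weights" in tc:
                tc["weights"] = tuple(tc["weights"])
            data["tr_criteria"] = TrCriteria(**tc)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable short hash of the configuration (stamped into outputs)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
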