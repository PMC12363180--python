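"""Pipeline configuration: every threshold in one serialisable object.

Defaults are the published tool parameters of the workflow this package
re-implements (``--min-seq-id 0.5``, ``-c 0.9`` bidirectional for
clustering; ``--tmscore-threshold 0.5`` with ``-c 0.8`` for the structure
search; TM > 0.6 for the counter-defense screen; pLDDT >= 70 for the
High/Low split; pLDDT > 90 and score > 0.8 for the predictor gates;
interaction screens at 0.5 and 0.7).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotate import DEFAULT_VOID_TERMS
from .consistency import DEFAULT_AMBIGUOUS_TERMS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # clustering
    min_identity: float = 0.5
    cluster_coverage: float = 0.9
    cluster_coverage_mode: str = "bidirectional"
    # structure search
    hit_tm: float = 0.5
    hit_coverage: float = 0.8
    hit_coverage_mode: str = "bidirectional"
    # screens and gates
    counter_defense_tm: float = 0.6
    plddt_high: float = 70.0
    plddt_gate: float = 90.0
    deepfri_score: float = 0.8
    interaction_thresholds: tuple[float, float] = (0.5, 0.7)
    interaction_screen_on: str = "weighted"
    # term lists
    void_terms: tuple[str, ...] = DEFAULT_VOID_TERMS
    ambiguous_terms: tuple[str, ...] = DEFAULT_AMBIGUOUS_TERMS
    synonym_groups_path: str | None = None
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_identity", "cluster_coverage", "hit_tm", "hit_coverage",
                     "counter_defense_tm", "deepfri_score"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for v in self.interaction_thresholds:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"interaction threshold {v!r} outside [0, 1]")
        for name in ("plddt_high", "plddt_gate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v!r}")
        for name in ("cluster_coverage_mode", "hit_coverage_mode"):
            if getattr(self, name) not in ("bidirectional", "target"):
                raise ValueError(f"{name} must be 'bidirectional' or 'target'")
        if self.interaction_screen_on not in ("weighted", "raw_sum"):
            raise ValueError("interaction_screen_on must be 'weighted' or 'raw_sum'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interaction_thresholds"] = list(self.interaction_thresholds)
        d["void_terms"] = list(self.void_terms)
        d["ambiguous_terms"] = list(self.ambiguous_terms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("interaction_thresholds", "void_terms", "ambiguous_terms"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
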