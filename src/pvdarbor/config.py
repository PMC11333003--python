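"""Run configuration: one serializable bundle for a whole pipeline run.

A :class:`RunConfig` collects every stage's parameters plus the global seed
and output directory, so a run can be reproduced bit for bit from a single
YAML file.  Re-running with an identical RunConfig reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .classify import ClassifyConfig
from .morphometrics import MorphometricsConfig
from .simulate import ArborSimParams, FluorSimParams, PunctaSimParams


@dataclass
class RunConfig:
    arbor: ArborSimParams = field(default_factory=ArborSimParams)
    fluor: FluorSimParams = field(default_factory=FluorSimParams)
    puncta: PunctaSimParams = field(default_factory=PunctaSimParams)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    morphometrics: MorphometricsConfig = field(
        default_factory=MorphometricsConfig)
    seed: int = 0
    outdir: str = "out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["morphometrics"]["grade_bins"] = list(
            d["morphometrics"]["grade_bins"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        section_types = {f.name: f.type for f in fields(cls)}
        for name, payload in raw.items():
            if name == "arbor":
                kw[name] = ArborSimParams(**payload)
            elif name == "fluor":
                kw[name] = FluorSimParams(**payload)
            elif name == "puncta":
                kw[name] = PunctaSimParams(**payload)
            elif name == "classify":
                kw[name] = ClassifyConfig(**payload)
            elif name == "morphometrics":
                payload = dict(payload)
                if "grade_bins" in payload:
                    payload["grade_bins"] = tuple(payload["grade_bins"])
                kw[name] = MorphometricsConfig(**payload)
            elif name in section_types:
                kw[name] = payload
        return cls(**kw)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True,
                       default=str).encode()).hexdigest()[:16]
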