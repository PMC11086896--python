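"""Pipeline configuration: a flat, YAML/JSON round-trippable record.

Defaults reproduce the benchmark conditions: 10 histogram bins, 300
observations per sample, 25 items per cluster, eps = 1e-9, Granger lag 1,
ML iteration factor 3, train fractions 0.3 / 0.8, unit scale factors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    problem: str = "distributions"
    method: str = "qee_ward"
    k: int | None = None  # None -> the problem's true cluster count
    seed: int = 0
    size_mode: str = "fixed"
    output_dir: str = "jointclust_out"
    problem_options: dict = field(default_factory=dict)
    distance_options: dict = field(default_factory=dict)
    qee_options: dict = field(default_factory=dict)
    evaluation_options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
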