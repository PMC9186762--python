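"""Structured run configuration shared by all CLI subcommands.

All defaults are the study's operating values: Z significance 1.96,
factor-loading membership threshold 0.5, p21 OD grading thresholds
0.2/0.4/0.6 (counterstain detection 0.05 upstream), the 8-feature
rectangular-dataset mask and a fixed seed.  Configurations are JSON; a
short content hash is echoed into every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .registry import DEFAULT_MASK


@dataclass
class RunConfig:
    z_threshold: float = 1.96
    loading_threshold: float = 0.5
    p21_thresholds: tuple[float, float, float] = (0.2, 0.4, 0.6)
    counterstain_detection_od: float = 0.05
    mask: tuple[str, ...] = ()
    use_default_mask: bool = False
    tsne_perplexity: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.loading_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        self.p21_thresholds = tuple(float(t) for t in self.p21_thresholds)
        if list(self.p21_thresholds) != sorted(self.p21_thresholds):
            raise ValueError("p21 thresholds must be ascending")
        self.mask = tuple(self.mask) or (DEFAULT_MASK if self.use_default_mask else ())

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @property
    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def echo(self) -> str:
        lines = [f"# samp config {self.digest}"]
        for k, v in asdict(self).items():
            lines.append(f"#   {k} = {v}")
        return "\n".join(lines)
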