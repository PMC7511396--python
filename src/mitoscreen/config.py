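"""Run configuration: one YAML file drives an end-to-end, reproducible run.

The resolved configuration (including defaults and seeds) is serialised into
every output directory so any result can be traced back to its exact inputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .segment import SegmentationConfig


@dataclass
class InputSpec:
    """One acquisition: either a stack on disk or a simulated scene."""

    path: str | None = None
    simulate: dict | None = None  # SceneParams keyword arguments
    group: str = "control"
    condition: str = "basal"
    induction_time: float | None = None
    day: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if (self.path is None) == (self.simulate is None):
            raise ValueError("each input needs exactly one of 'path' or 'simulate'")
        if self.name is None:
            self.name = Path(self.path).stem if self.path else f"sim_{self.group}_{self.condition}"


@dataclass
class RunConfig:
    inputs: list[InputSpec] = field(default_factory=list)
    channels: dict = field(default_factory=dict)  # role -> channel name overrides
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    overlap_threshold: float = 1.0
    containment_mode: str = "single"  # or "union"
    correction: str = "sidak"
    control_group: str = "control"
    seed: int = 0
    outdir: str = "mitoscreen_out"

    def __post_init__(self) -> None:
        self.inputs = [i if isinstance(i, InputSpec) else InputSpec(**i) for i in self.inputs]
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationConfig(**self.segmentation)
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.containment_mode not in ("single", "union"):
            raise ValueError("containment_mode must be 'single' or 'union'")

    def channel(self, role: str) -> str:
        return self.channels.get(role, role)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
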