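"""Run configuration: one flat serialisable record of every stage parameter."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .layerseg import SegmentConfig


@dataclass
class RunConfig:
    """All pipeline parameters, serialisable to a flat YAML mapping.

    Segmentation-stage parameters live in ``segment``; on disk they are
    flattened into the same mapping as the run-level fields.
    """

    voxel_size_um: float = 0.75
    axial_axis: int = 0
    seed: int = 0
    pore_k_sd: float = 3.0
    pore_min_size_vox: int = 10
    segment: SegmentConfig = field(default_factory=SegmentConfig)

    def validate(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.axial_axis not in (0, 1, 2):
            raise ValueError("axial_axis must be 0, 1 or 2")
        if not self.pore_k_sd > 0:
            raise ValueError("pore_k_sd must be > 0")
        if self.pore_min_size_vox < 1:
            raise ValueError("pore_min_size_vox must be >= 1")
        self.segment.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        seg = d.pop("segment")
        d.update(seg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg_fields = {f.name for f in dataclasses.fields(SegmentConfig)}
        run_fields = {f.name for f in dataclasses.fields(cls)} - {"segment"}
        unknown = set(d) - seg_fields - run_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        seg = SegmentConfig(**{k: v for k, v in d.items() if k in seg_fields})
        return cls(**{k: v for k, v in d.items() if k in run_fields}, segment=seg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
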