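"""Serializable run configuration.

A run's effective configuration (calibration, threshold, gate, A₁, geometry,
seed) is echoed as YAML into the output directory so any result can be
reproduced from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass

import yaml

from .cytometry import SINGLE_SPORE_AREA_UM2, CIRCULARITY_EPS, GateSpec
from .segmentation import ThresholdSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a counting run."""

    pixel_size_um: float = 1.5
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    gate_min_area_um2: float = 0.3 * SINGLE_SPORE_AREA_UM2
    gate_max_area_um2: float = math.inf
    gate_min_circularity: float = 0.4
    gate_max_circularity: float = 1.0 + CIRCULARITY_EPS
    gate_exclude_border: bool = False
    single_spore_area_um2: float = SINGLE_SPORE_AREA_UM2
    connectivity: int = 8
    field_area_um2: float = 2400.0 * 1800.0
    substrate_area_um2: float = 2.2e4 * 2.2e4  # 2.2 cm × 2.2 cm cover glass
    t_test_variant: str = "pooled"
    seed: int = 0
    strict: bool = False

    def threshold_spec(self) -> ThresholdSpec:
        if self.threshold_value is not None:
            return ThresholdSpec("fixed", float(self.threshold_value))
        return ThresholdSpec(self.threshold_method)  # type: ignore[arg-type]

    def gate_spec(self) -> GateSpec:
        return GateSpec(
            min_area_um2=self.gate_min_area_um2,
            max_area_um2=self.gate_max_area_um2,
            min_circularity=self.gate_min_circularity,
            max_circularity=self.gate_max_circularity,
            exclude_border=self.gate_exclude_border,
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d = {k: ("inf" if isinstance(v, float) and math.isinf(v) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("gate_max_area_um2") == "inf":
            d["gate_max_area_um2"] = math.inf
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
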