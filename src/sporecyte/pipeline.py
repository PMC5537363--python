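"""One-call pipeline: micrograph → cluster-corrected spore count.

Chains binarize → label → gate → corrected count, which is the per-field
unit of work everything else (field averaging, efficiency, the CLI) builds
on.
"""

from __future__ import annotations

from typing import Literal

from .cytometry import (
    SINGLE_SPORE_AREA_UM2,
    CountResult,
    GateSpec,
    corrected_count,
    default_gate,
    gate_spores,
)
from .io import FluorImage
from .segmentation import ThresholdSpec, binarize, label_particles

__all__ = ["count_field"]


def count_field(
    image: FluorImage,
    threshold: ThresholdSpec = ThresholdSpec(),
    gate: GateSpec | None = None,
    single_spore_area_um2: float = SINGLE_SPORE_AREA_UM2,
    connectivity: Literal[4, 8] = 8,
    per_particle: bool = False,
) -> CountResult:
    """Count the spores in one field.

    ``gate=None`` uses the default spore gate scaled to the supplied
    single-spore area A₁ (area ≥ 0.3·A₁, circularity ≥ 0.4).
    """
    if gate is None:
        gate = default_gate(single_spore_area_um2)
    mask = binarize(image, threshold)
    particles = label_particles(mask, connectivity=connectivity)
    spores = gate_spores(particles, gate)
    return corrected_count(spores, single_spore_area_um2, per_particle=per_particle)
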