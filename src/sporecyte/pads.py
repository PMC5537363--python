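"""Adhesive-pad area from Cy5-channel images, with spore-area exclusion.

The Cy5 label binds pad protein, but spore bodies fluoresce in the same band,
so the Cy5-positive area overstates the pad. The pad area is therefore the
set difference: Cy5 foreground minus the spore mask. When no chlorophyll
image exists for the field, spores are identified within the Cy5 particles
themselves by the spore gate and subtracted (single-channel fallback).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cytometry import GateSpec, gate_spores
from .errors import GeometryMismatchError
from .io import FluorImage
from .segmentation import BinaryMask, ThresholdSpec, binarize, label_particles

__all__ = ["PadAreaResult", "pad_area", "spore_mask_from_cy5", "pad_dose_response"]


@dataclass(frozen=True)
class PadAreaResult:
    """Areas (μm²) from one Cy5 field: total Cy5, excluded spore overlap, pad.

    ``spore_area_um2`` is the Cy5-positive area excluded as spore body, so
    ``pad_area_um2 + spore_area_um2 == cy5_area_um2`` exactly.
    """

    cy5_area_um2: float
    spore_area_um2: float
    pad_area_um2: float


def pad_area(
    cy5_image: FluorImage,
    cy5_threshold: ThresholdSpec,
    spore_mask: BinaryMask,
    spore_dilation_px: int = 0,
) -> PadAreaResult:
    """Pad area = Cy5 foreground minus the spore mask.

    ``spore_dilation_px`` optionally grows the spore mask before subtraction
    to swallow a bright halo around spore bodies (off by default).

    Raises
    ------
    GeometryMismatchError
        If image and mask differ in shape or pixel size.
    """
    if cy5_image.pixels.shape != spore_mask.pixels.shape:
        raise GeometryMismatchError(
            f"Cy5 image {cy5_image.pixels.shape} and spore mask "
            f"{spore_mask.pixels.shape} differ in shape"
        )
    if not np.isclose(cy5_image.pixel_size_um, spore_mask.pixel_size_um):
        raise GeometryMismatchError(
            f"pixel sizes differ: {cy5_image.pixel_size_um} vs {spore_mask.pixel_size_um}"
        )
    cy5 = binarize(cy5_image, cy5_threshold).pixels
    spores = spore_mask.pixels
    if spore_dilation_px > 0:
        spores = ndimage.binary_dilation(spores, iterations=spore_dilation_px)
    ps2 = cy5_image.pixel_size_um**2
    cy5_area = float(cy5.sum()) * ps2
    overlap = float((cy5 & spores).sum()) * ps2
    return PadAreaResult(
        cy5_area_um2=cy5_area,
        spore_area_um2=overlap,
        pad_area_um2=cy5_area - overlap,
    )


def spore_mask_from_cy5(
    cy5_image: FluorImage,
    cy5_threshold: ThresholdSpec,
    spore_gate: GateSpec,
    connectivity: int = 8,
) -> BinaryMask:
    """Single-channel fallback: find spore bodies inside the Cy5 mask itself.

    Particle analysis is run on the Cy5 mask and the components that satisfy
    the spore size/shape gate are returned as the spore mask to exclude.
    """
    mask = binarize(cy5_image, cy5_threshold)
    from skimage import measure

    lab = measure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    particles = label_particles(mask, connectivity=connectivity)  # same labelling order
    keep = {p.label for p in gate_spores(particles, spore_gate)}
    spore_px = np.isin(lab, list(keep)) if keep else np.zeros_like(mask.pixels)
    return BinaryMask(spore_px, cy5_image.pixel_size_um)


def pad_dose_response(
    results: Sequence[tuple[float, PadAreaResult]],
) -> pd.DataFrame:
    """Mean ± SD pad area per biocide concentration, sorted ascending.

    Parameters
    ----------
    results:
        (concentration_ppb, PadAreaResult) pairs, one per analysed field.
    """
    if len(results) == 0:
        raise ValueError("need at least one (concentration, result) pair")
    df = pd.DataFrame(
        {
            "concentration_ppb": [c for c, _ in results],
            "pad_area_um2": [r.pad_area_um2 for _, r in results],
        }
    )
    out = (
        df.groupby("concentration_ppb")["pad_area_um2"]
        .agg(mean_pad_area_um2="mean", sd_pad_area_um2=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n_fields="count")
        .reset_index()
        .sort_values("concentration_ppb", kind="stable")
        .reset_index(drop=True)
    )
    return out
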