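"""FTIR band intensities and the phospholipid-to-protein ratio.

Adhesive-pad material shows an ester carbonyl band (lipids, ~1750 cm⁻¹) and
the amide I band (protein, ~1650 cm⁻¹). The ratio of the two band heights,
I₁ (1730–1800 cm⁻¹) over I₂ (1650–1700 cm⁻¹), converts to composition via a
published linear calibration:

    moles phospholipid per kg protein = (I₁/I₂ − 0.0175) / 0.2590

The intercept and slope come from that external calibration, not from this
assay, so both are overridable.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "LIPID_RATIO_INTERCEPT",
    "LIPID_RATIO_SLOPE",
    "LIPID_BAND_CM1",
    "PROTEIN_BAND_CM1",
    "FtirSpectrum",
    "read_spectrum",
    "band_intensity",
    "lipid_protein_ratio",
]

#: Linear calibration mapping the band ratio I1/I2 to moles phospholipid
#: per kg protein (external calibration constants).
LIPID_RATIO_INTERCEPT = 0.0175
LIPID_RATIO_SLOPE = 0.2590

#: Wavenumber windows for the two band heights.
LIPID_BAND_CM1 = (1730.0, 1800.0)  # ester carbonyl stretch, I1
PROTEIN_BAND_CM1 = (1650.0, 1700.0)  # amide I, I2


@dataclass(frozen=True)
class FtirSpectrum:
    """A wavenumber/absorbance series, normalised to ascending wavenumber."""

    wavenumbers_cm1: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers_cm1, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or wn.shape != ab.shape or wn.size < 2:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D, n >= 2")
        d = np.diff(wn)
        if (d > 0).all():
            pass
        elif (d < 0).all():
            wn, ab = wn[::-1].copy(), ab[::-1].copy()
        else:
            raise ValueError("wavenumbers must be strictly monotone")
        if not (np.isfinite(wn).all() and np.isfinite(ab).all()):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavenumbers_cm1", wn)
        object.__setattr__(self, "absorbance", ab)


def _read_jcamp_xydata(path: str) -> FtirSpectrum:
    """Minimal JCAMP-DX reader: the ##XYDATA=(X++(Y..Y)) table only."""
    xs: list[float] = []
    ys: list[float] = []
    xfactor = yfactor = 1.0
    deltax = None
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, val = line.partition("=")
                key = key.strip("#").strip().upper()
                val = val.strip()
                if key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key == "DELTAX":
                    deltax = float(val)
                elif key == "XYDATA":
                    in_table = True
                elif in_table:  # any following ## record ends the table
                    in_table = False
                continue
            if in_table and line:
                vals = [float(v) for v in re.split(r"[,\s]+", line) if v]
                if len(vals) < 2:
                    continue
                x0, yvals = vals[0], vals[1:]
                if deltax is None:
                    raise ValueError(f"{path}: JCAMP XYDATA without ##DELTAX")
                for i, y in enumerate(yvals):
                    xs.append((x0 + i * deltax) * xfactor)
                    ys.append(y * yfactor)
    if not xs:
        raise ValueError(f"{path}: no XYDATA table found")
    return FtirSpectrum(np.asarray(xs), np.asarray(ys))


def read_spectrum(path: str | os.PathLike) -> FtirSpectrum:
    """Read a spectrum from two-column CSV/TSV (wavenumber, absorbance) or JCAMP-DX.

    CSV/TSV may or may not carry a header row; the delimiter is sniffed.
    ``.jdx``/``.dx`` files are parsed by a minimal JCAMP reader that accepts
    the plain ``(X++(Y..Y))`` XYDATA table.
    """
    path = os.fspath(path)
    if path.lower().endswith((".jdx", ".dx", ".jcamp")):
        return _read_jcamp_xydata(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    # drop a header row if the first cell is not numeric
    if not np.issubdtype(np.asarray([df.iloc[0, 0]]).dtype, np.number):
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
    arr = df.iloc[:, :2].astype(float).to_numpy()
    return FtirSpectrum(arr[:, 0], arr[:, 1])


def band_intensity(
    spectrum: FtirSpectrum,
    lo_cm1: float,
    hi_cm1: float,
    baseline: Literal["none", "linear_endpoints"] = "none",
) -> float:
    """Band height: maximum absorbance within [lo, hi] cm⁻¹.

    ``baseline='linear_endpoints'`` first subtracts the straight line through
    the absorbance at the two window endpoints (linearly interpolated), which
    removes a sloping background under an isolated band. Negative corrected
    heights are floored at 0.
    """
    if not lo_cm1 < hi_cm1:
        raise ValueError(f"need lo < hi, got [{lo_cm1}, {hi_cm1}]")
    wn, ab = spectrum.wavenumbers_cm1, spectrum.absorbance
    if hi_cm1 < wn[0] or lo_cm1 > wn[-1]:
        raise ValueError(
            f"band [{lo_cm1}, {hi_cm1}] cm^-1 outside spectrum support "
            f"[{wn[0]}, {wn[-1]}] cm^-1"
        )
    sel = (wn >= lo_cm1) & (wn <= hi_cm1)
    if not sel.any():
        raise ValueError(f"no sample points inside [{lo_cm1}, {hi_cm1}] cm^-1")
    x, y = wn[sel], ab[sel]
    if baseline == "linear_endpoints":
        x0, x1 = max(lo_cm1, wn[0]), min(hi_cm1, wn[-1])
        y0 = float(np.interp(x0, wn, ab))
        y1 = float(np.interp(x1, wn, ab))
        y = y - (y0 + (y1 - y0) * (x - x0) / (x1 - x0))
    elif baseline != "none":
        raise ValueError(f"unknown baseline {baseline!r}")
    return max(float(y.max()), 0.0)


def lipid_protein_ratio(
    i1: float,
    i2: float,
    intercept: float = LIPID_RATIO_INTERCEPT,
    slope: float = LIPID_RATIO_SLOPE,
) -> float:
    """Moles of phospholipid per kg protein from the band heights I₁ and I₂.

    Applies the linear calibration (I₁/I₂ − intercept)/slope. A negative
    result (I₁/I₂ below the calibration intercept) is returned as-is with a
    warning — it means "below the calibrated range", not zero lipid.
    """
    if not i2 > 0:
        raise ValueError(f"I2 must be positive, got {i2}")
    if i1 < 0:
        raise ValueError(f"I1 must be >= 0, got {i1}")
    ratio = (i1 / i2 - intercept) / slope
    if ratio < 0:
        warnings.warn(
            f"band ratio I1/I2 = {i1 / i2:.4g} is below the calibration "
            f"intercept {intercept}; lipid/protein ratio {ratio:.4g} is negative",
            stacklevel=2,
        )
    return ratio
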