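"""Assay tables, growth-rate ratios and significance testing.

Settlement assays compare conditions (biocide × concentration, with natural
seawater as the control at 0 ppb) over replicate fields or dishes. This
module assembles the per-condition summary tables, computes the growth-rate
ratio used for whole-organism inhibition, and runs the two-sample t-test
with the star conventions used in the figures (* for p < 0.01, ** for
p < 0.001).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementKind",
    "AssayRecord",
    "GrowthRecord",
    "TestResult",
    "growth_rate",
    "two_group_test",
    "significance_stars",
    "bonferroni",
    "dose_response_table",
    "read_assay_csv",
    "records_from_frame",
]


class MeasurementKind(str, enum.Enum):
    CORRECTED_COUNT = "corrected_count"
    EFFICIENCY = "efficiency"
    PAD_AREA = "pad_area"
    LENGTH = "length"


@dataclass(frozen=True)
class AssayRecord:
    """One assay condition: biocide at a concentration, with its measurements.

    ``measurements`` holds the per-field (or per-dish) values of one kind —
    corrected counts, efficiencies, pad areas or lengths. Control records
    (natural seawater) must carry concentration 0.
    """

    biocide: str
    concentration_ppb: float
    replicate: int
    measurements: tuple[float, ...]
    measurement_kind: MeasurementKind = MeasurementKind.CORRECTED_COUNT

    def __post_init__(self) -> None:
        if self.concentration_ppb < 0:
            raise ValueError("concentration_ppb must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.biocide.lower() in ("control", "seawater") and self.concentration_ppb != 0:
            raise ValueError("control records must have concentration 0")
        object.__setattr__(self, "measurements", tuple(float(m) for m in self.measurements))


@dataclass(frozen=True)
class GrowthRecord:
    """Length of one algal fragment before and after incubation.

    Growth length is floored at 0: fragments may erode, but a negative
    growth has no meaning in the growth-rate ratio.
    """

    initial_length_cm: float
    final_length_cm: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.initial_length_cm > 0:
            raise ValueError("initial_length_cm must be positive")
        if self.final_length_cm < 0:
            raise ValueError("final_length_cm must be >= 0")

    @property
    def growth_length_cm(self) -> float:
        return max(0.0, self.final_length_cm - self.initial_length_cm)


def growth_rate(treated: GrowthRecord, control: GrowthRecord) -> float:
    """Growth-rate ratio: length grown under biocide over length grown in seawater."""
    if control.growth_length_cm <= 0:
        raise ValueError("control fragment showed no growth; ratio undefined")
    return treated.growth_length_cm / control.growth_length_cm


@dataclass(frozen=True)
class TestResult:
    """Two-sample t-test outcome with figure-style significance flags."""

    t: float
    p: float
    df: float
    stars: str  # "" (n.s. at 0.01), "*" (p<0.01), "**" (p<0.001)
    significant_005: bool
    significant_001: bool
    significant_0001: bool


def significance_stars(p: float) -> str:
    """Star convention used in the assay figures: * p<0.01, ** p<0.001."""
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return ""


def two_group_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: Literal["pooled", "welch"] = "pooled",
) -> TestResult:
    """Two-sided two-sample t-test (standard Student's pooled form by default).

    Degenerate zero-variance inputs use the documented conventions:
    identical means → (t=0, p=1); different means with zero variance →
    (t=±inf, p=0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups contain non-finite values")
    df = float(a.size + b.size - 2) if variant == "pooled" else _welch_df(a, b)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        t=t,
        p=p,
        df=df,
        stars=significance_stars(p),
        significant_005=p < 0.05,
        significant_001=p < 0.01,
        significant_0001=p < 0.001,
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return float(a.size + b.size - 2)
    return float((va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (optional; raw p is the default report)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def dose_response_table(records: Sequence[AssayRecord]) -> pd.DataFrame:
    """Per-biocide mean ± SD versus concentration.

    Measurements are pooled across replicates of the same (biocide,
    concentration). Within each biocide block rows are sorted by ascending
    concentration, so the 0-ppb control row comes first.
    """
    if len(records) == 0:
        raise ValueError("need at least one assay record")
    rows = []
    for r in records:
        for m in r.measurements:
            rows.append(
                {
                    "biocide": r.biocide,
                    "concentration_ppb": r.concentration_ppb,
                    "kind": r.measurement_kind.value,
                    "value": m,
                }
            )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["biocide", "concentration_ppb", "kind"], sort=False)["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index()
        .sort_values(["biocide", "concentration_ppb"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def records_from_frame(df: pd.DataFrame) -> list[AssayRecord]:
    """Build AssayRecords from a long-format table.

    Expected columns: biocide, concentration_ppb, replicate, value and
    optionally kind (defaults to corrected_count). One record per
    (biocide, concentration, replicate); the per-field values of that
    replicate become its measurements.
    """
    required = {"biocide", "concentration_ppb", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    records = []
    kind_col = "kind" if "kind" in df.columns else None
    for (biocide, conc, rep), grp in df.groupby(
        ["biocide", "concentration_ppb", "replicate"], sort=False
    ):
        kind = (
            MeasurementKind(grp[kind_col].iloc[0])
            if kind_col
            else MeasurementKind.CORRECTED_COUNT
        )
        records.append(
            AssayRecord(
                biocide=str(biocide),
                concentration_ppb=float(conc),
                replicate=int(rep),
                measurements=tuple(grp["value"].astype(float)),
                measurement_kind=kind,
            )
        )
    return records


def read_assay_csv(path) -> list[AssayRecord]:
    """Read the long-format assay CSV (biocide, concentration_ppb, replicate, field_id, value[, kind])."""
    return records_from_frame(pd.read_csv(path))
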