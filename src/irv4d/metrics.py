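"""Contour overlap metrics and summary statistics.

Implements the evaluation side of the pipeline: Jaccard similarity,
sensitivity and specificity of a contour D against a consensus reference G;
per-organ volume variation %V = SD/mean x 100; the inter-observer relative
similarity difference %S = 2 (S_U1 - S_U2)/(S_U1 + S_U2) x 100; paired
Student's t-tests; and the mean/SD column summaries used in the packaged
reference tables.

The specificity complement is counted inside a per-pair evaluation box (the
bounding box of D union G dilated by 10 voxels in-plane and 2 slices) rather
than the whole grid, where it would saturate at ~1.  The box is configurable
and recorded with every record.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .grid import ContourMask, require_same_grid
from .staple import evaluation_box


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty."""


@dataclass(frozen=True)
class EvaluationDomain:
    """Region over which the complement of G is counted for specificity."""

    box: Tuple[slice, slice, slice]
    dilate_xy: int = 10
    dilate_z: int = 2

    @classmethod
    def around(cls, d: ContourMask, g: ContourMask,
               dilate_xy: int = 10, dilate_z: int = 2) -> "EvaluationDomain":
        box = evaluation_box([d.data, g.data], d.grid.shape, dilate_xy, dilate_z)
        return cls(box, dilate_xy, dilate_z)


@dataclass
class SSSRecord:
    """Similarity / sensitivity / specificity of one contour vs the reference."""

    jaccard: float
    sensitivity: float
    specificity: float
    organ: str = ""
    phase: int = 0
    source: str = ""
    series: str = ""
    subject: int = 0
    domain_dilate_xy: int = 10
    domain_dilate_z: int = 2


def jaccard(d: ContourMask, g: ContourMask) -> float:
    """|D n G| / |D u G|; defined as 1.0 when both masks are empty."""
    require_same_grid(d.grid, g.grid, "jaccard operands")
    union = int(np.logical_or(d.data, g.data).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(d.data, g.data).sum())
    return inter / union


def sensitivity(d: ContourMask, g: ContourMask) -> float:
    """True-positive fraction |D n G| / |G|."""
    require_same_grid(d.grid, g.grid, "sensitivity operands")
    ng = g.voxel_count
    if ng == 0:
        raise UndefinedMetricError("sensitivity undefined: reference mask G is empty")
    return int(np.logical_and(d.data, g.data).sum()) / ng


def specificity(d: ContourMask, g: ContourMask,
                domain: Optional[EvaluationDomain] = None) -> float:
    """True-negative fraction |~D n ~G| / |~G| inside the evaluation domain."""
    require_same_grid(d.grid, g.grid, "specificity operands")
    if domain is None:
        domain = EvaluationDomain.around(d, g)
    dd = d.data[domain.box]
    gg = g.data[domain.box]
    n_neg = int((~gg).sum())
    if n_neg == 0:
        raise UndefinedMetricError(
            "specificity undefined: complement of G is empty in the domain"
        )
    return int(np.logical_and(~dd, ~gg).sum()) / n_neg


def sss_record(d: ContourMask, g: ContourMask,
               domain: Optional[EvaluationDomain] = None,
               subject: int = 0) -> SSSRecord:
    if domain is None:
        domain = EvaluationDomain.around(d, g)
    return SSSRecord(
        jaccard=jaccard(d, g),
        sensitivity=sensitivity(d, g),
        specificity=specificity(d, g, domain),
        organ=d.organ, phase=d.phase_index, source=d.source, series=d.series,
        subject=subject,
        domain_dilate_xy=domain.dilate_xy, domain_dilate_z=domain.dilate_z,
    )


def volume_variation_pct(volumes_mm3: Sequence[float]) -> float:
    """%V = sample SD / mean x 100 of per-phase organ volumes."""
    v = np.asarray(volumes_mm3, dtype=float)
    if v.size < 2:
        raise ValueError("volume variation needs at least two phases")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("volume variation undefined for non-positive mean volume")
    return float(v.std(ddof=1) / mean * 100.0)


def similarity_relative_diff_pct(s_u1: float, s_u2: float) -> float:
    """%S = 2 (S_U1 - S_U2) / (S_U1 + S_U2) x 100 (signed)."""
    denom = s_u1 + s_u2
    if denom == 0:
        raise ValueError("relative similarity difference undefined: S_U1 + S_U2 = 0")
    return 2.0 * (s_u1 - s_u2) / denom * 100.0


@dataclass
class TTestResult:
    t: float
    p: float
    flag: str = ""  # "", "exact-tie", "zero-variance-shift"


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Classical paired two-tailed Student's t-test on the differences.

    Edge rules: identical samples report p = 1 (flagged tie); a constant
    non-zero shift has zero difference variance and reports t = +-inf, p = 0
    (flagged), rather than a division error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return TTestResult(t=0.0, p=1.0, flag="exact-tie")
        return TTestResult(t=float(np.sign(diff.mean()) * np.inf), p=0.0,
                           flag="zero-variance-shift")
    t, p = stats.ttest_rel(a, b)
    return TTestResult(t=float(t), p=float(p))


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def column_summary(values: Sequence[float], decimals: int) -> Tuple[float, float]:
    """Arithmetic mean and sample SD, half-up rounded at ``decimals``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("column summary of an empty column")
    if v.size < 2:
        raise ValueError("column summary needs at least two values")
    return (round_half_up(float(v.mean()), decimals),
            round_half_up(float(v.std(ddof=1)), decimals))
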