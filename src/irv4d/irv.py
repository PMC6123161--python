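"""Internal organ-at-risk volume (IRV) and organ-motion summaries.

The IRV of an organ is the Boolean (OR) union of its contours over all
respiratory phases; its relative increase over the phase-mean organ volume,

    %V = (IRV / Vbar_OAR - 1) x 100,

quantifies how much larger the motion-inclusive volume is than the organ
itself.  Motion is summarized by the SI excursion of the organ's
centre-of-mass trajectory and by the diaphragm dome range extracted from the
lung masks (most inferior occupied slice over the column at the lung's
in-plane centre of mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .grid import ContourMask, require_same_grid


@dataclass
class IRVResult:
    irv_mask: ContourMask
    irv_volume_mm3: float
    mean_organ_volume_mm3: float
    increase_pct: float
    per_phase_volumes_mm3: List[float]
    empty_phases: List[int]
    organ: str = ""
    source: str = ""
    subject: int = 0


@dataclass
class MotionTrajectory:
    com_mm: np.ndarray              # (n_phases, 3)
    si_excursion_mm: float
    errors: Dict[int, str] = field(default_factory=dict)


def compute_irv(masks: Sequence[ContourMask], organ: str = "",
                source: str = "", subject: int = 0) -> IRVResult:
    """Union the per-phase masks of one organ and quantify the increase.

    An organ absent in some phase (e.g. outlier truncation) still contributes
    its (zero) volume to the mean and is flagged, not dropped.
    """
    if len(masks) < 1:
        raise ValueError("IRV needs at least one phase mask")
    grid = masks[0].grid
    union = np.zeros(grid.shape, dtype=bool)
    vols = []
    empty = []
    for i, m in enumerate(masks):
        require_same_grid(grid, m.grid, "IRV phase masks")
        union |= m.data
        vols.append(m.volume_mm3)
        if m.is_empty():
            empty.append(i)
    irv_mask = masks[0].tagged(data=union, source=f"irv-{source}" if source else "irv")
    irv_volume = float(union.sum()) * grid.voxel_volume_mm3
    mean_vol = float(np.mean(vols))
    if mean_vol <= 0:
        raise ValueError("IRV increase undefined: mean organ volume is zero")
    increase = (irv_volume / mean_vol - 1.0) * 100.0
    return IRVResult(irv_mask, irv_volume, mean_vol, increase, vols, empty,
                     organ=organ or masks[0].organ, source=source, subject=subject)


def com_trajectory(masks: Sequence[ContourMask]) -> MotionTrajectory:
    """Centre-of-mass trajectory (mm) and its SI excursion (max - min)."""
    coms = np.full((len(masks), 3), np.nan)
    errors: Dict[int, str] = {}
    for i, m in enumerate(masks):
        if m.is_empty():
            errors[i] = f"empty mask at phase {i}"
            continue
        coms[i] = m.com_mm()
    valid = ~np.isnan(coms[:, 2])
    if not valid.any():
        raise ValueError("all phase masks are empty")
    si = coms[valid, 2]
    return MotionTrajectory(coms, float(si.max() - si.min()), errors)


def _dome_si_mm(lung_mask: ContourMask) -> float:
    if lung_mask.is_empty():
        raise ValueError(f"empty lung mask (phase {lung_mask.phase_index})")
    idx = np.argwhere(lung_mask.data)
    i, j = np.round(idx[:, :2].mean(axis=0)).astype(int)
    col = np.flatnonzero(lung_mask.data[i, j, :])
    if col.size == 0:
        raise ValueError(
            f"lung column at in-plane COM ({i},{j}) is empty "
            f"(phase {lung_mask.phase_index})"
        )
    k = int(col.min())
    return float(k * lung_mask.grid.spacing_mm[2] + lung_mask.grid.origin_mm[2])


def diaphragm_excursion(lung_masks: Sequence[ContourMask], side: str = "right"
                        ) -> float:
    """Diaphragm dome SI range (mm) over the phases of one lung."""
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    positions = []
    for m in lung_masks:
        try:
            positions.append(_dome_si_mm(m))
        except ValueError as exc:
            raise ValueError(f"{side} lung: {exc}") from exc
    return float(max(positions) - min(positions))


def diaphragm_positions(lung_masks: Sequence[ContourMask]) -> np.ndarray:
    """Dome SI position per phase (mm), for trace-level comparisons."""
    return np.asarray([_dome_si_mm(m) for m in lung_masks])
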