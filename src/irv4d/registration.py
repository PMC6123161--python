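"""Free-form intensity-based deformable image registration (DIR).

The registration minimizes the classic optical-flow/demons energy

    E(u) = sum_ROI [I_B(x+u) - I_A(x)]^2 v  +  lambda * sum_i sum ||grad u_i||^2 v

over a displacement field u (mm) defined on the fixed-image grid, where
I_A is the fixed image, I_B the moving image, v the voxel volume in mm^3
and gradients are central differences in physical units.  The associated
Euler-Lagrange equation is solved by a demons-style fixed-point scheme:
a normalized intensity-force step followed by Gaussian smoothing of the
field, embedded in a coarse-to-fine multi-resolution pyramid.  A step is
accepted only if the energy does not increase, otherwise the step size is
halved, which makes the energy trace non-increasing by construction.

Anisotropic voxel spacing enters all gradients, interpolation and the
smoothness term in physical units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import (
    ContourMask,
    DisplacementField,
    PhaseVolume,
    require_same_grid,
)

log = logging.getLogger(__name__)


@dataclass
class RegistrationParams:
    """Tunables of the free-form DIR solver.

    lambda_smooth weighs the smoothness term of the energy (weight 0.1 by
    default).  The Laplacian regularization of the fixed-point update is
    realized as Gaussian smoothing of the force (smooth_update_vox) and of
    the accumulated field (smooth_field_vox), both in voxel units so coarse
    pyramid levels diffuse over correspondingly larger physical scales.  The
    pyramid downsamples in-plane by 2 per level and the slice axis only while
    at least 16 slices would remain.
    """

    lambda_smooth: float = 0.1
    n_levels: int = 3
    iters_per_level: Tuple[int, ...] = (60, 40, 20)  # coarse -> fine
    step_size: float = 2.0
    stop_tol: float = 1e-4
    smooth_update_vox: float = 1.0
    smooth_field_vox: float = 1.0
    roi: Optional[str] = "body"  # "body" bounding box, or None for full grid
    max_step_halvings: int = 4
    min_slices: int = 16

    def __post_init__(self):
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if np.isscalar(self.iters_per_level):
            self.iters_per_level = (int(self.iters_per_level),) * self.n_levels
        if len(self.iters_per_level) < self.n_levels:
            last = self.iters_per_level[-1]
            self.iters_per_level = tuple(self.iters_per_level) + (last,) * (
                self.n_levels - len(self.iters_per_level)
            )


@dataclass
class RegistrationResult:
    dvf: DisplacementField
    energy_trace: List[float]
    converged: bool
    levels_run: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# warping primitives


def _warp_array(arr: np.ndarray, vectors: np.ndarray, spacing: Sequence[float],
                order: int = 1) -> np.ndarray:
    """Sample ``arr`` at x + u(x); trilinear, nearest-edge padding."""
    idx = np.indices(arr.shape, dtype=np.float32)
    coords = [idx[a] + vectors[..., a] / spacing[a] for a in range(3)]
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def warp_image(image: PhaseVolume, dvf: DisplacementField) -> PhaseVolume:
    """Resample an image through a displacement field: out(x) = in(x + u(x))."""
    require_same_grid(image.grid, dvf.grid, "image and DVF")
    out = _warp_array(image.intensity, dvf.vectors, image.grid.spacing_mm)
    return image.with_intensity(out)


def warp_mask(mask: ContourMask, dvf: DisplacementField) -> ContourMask:
    """Warp a binary mask as a real-valued indicator, thresholded at 0.5.

    Interpolated values exactly equal to 0.5 map to foreground.
    """
    require_same_grid(mask.grid, dvf.grid, "mask and DVF")
    if mask.is_empty():
        return mask.tagged(data=mask.data.copy())
    ind = _warp_array(mask.data.astype(np.float32), dvf.vectors, mask.grid.spacing_mm)
    return mask.tagged(data=ind >= 0.5)


# ---------------------------------------------------------------------------
# energy


def body_roi_mask(fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Bounding box of body voxels (excludes most exterior air), as a bool mask."""
    hi = max(np.percentile(fixed, 99), np.percentile(moving, 99))
    thr = 0.05 * hi
    body = (fixed > thr) | (moving > thr)
    if not body.any():
        return np.ones_like(body, dtype=bool)
    roi = np.zeros_like(body)
    sl = ndimage.find_objects(body.astype(np.int8), max_label=1)[0]
    roi[sl] = True
    return roi


def _energy_arrays(fixed: np.ndarray, moving: np.ndarray, vectors: np.ndarray,
                   spacing: Sequence[float], lambda_smooth: float,
                   roi: Optional[np.ndarray], voxel_volume: float,
                   warped: Optional[np.ndarray] = None) -> float:
    if warped is None:
        warped = _warp_array(moving, vectors, spacing)
    diff2 = (warped - fixed) ** 2
    data = float(diff2[roi].sum()) if roi is not None else float(diff2.sum())
    smooth = 0.0
    if lambda_smooth > 0:
        for c in range(3):
            for g in np.gradient(vectors[..., c], *spacing):
                smooth += float((g.astype(np.float64) ** 2).sum())
    return data * voxel_volume + lambda_smooth * smooth * voxel_volume


def energy(fixed: PhaseVolume, moving: PhaseVolume, dvf: DisplacementField,
           lambda_smooth: float = 0.1,
           roi: Optional[np.ndarray] = None) -> float:
    """Evaluate the registration energy (mm^3-weighted sums, physical gradients)."""
    require_same_grid(fixed.grid, moving.grid, "fixed and moving images")
    require_same_grid(fixed.grid, dvf.grid, "images and DVF")
    return _energy_arrays(
        fixed.intensity.astype(np.float64),
        moving.intensity.astype(np.float64),
        dvf.vectors,
        fixed.grid.spacing_mm,
        lambda_smooth,
        roi,
        fixed.grid.voxel_volume_mm3,
    )


# ---------------------------------------------------------------------------
# multi-resolution solver


def _downsample(arr: np.ndarray, factors: Tuple[int, int, int]) -> np.ndarray:
    sm = ndimage.gaussian_filter(arr, sigma=[0.8 * (f - 1) for f in factors])
    return sm[:: factors[0], :: factors[1], :: factors[2]]


def _pyramid_factors(shape, n_levels: int, min_slices: int):
    """Per-level cumulative downsampling factors, finest (1,1,1) first."""
    factors = [(1, 1, 1)]
    fx = fy = fz = 1
    for _ in range(1, n_levels):
        fx *= 2
        fy *= 2
        if shape[2] // (fz * 2) >= min_slices:
            fz *= 2
        factors.append((fx, fy, fz))
    return factors


def _run_level(fixed: np.ndarray, moving: np.ndarray, u: np.ndarray,
               spacing: Sequence[float], roi: Optional[np.ndarray],
               params: RegistrationParams, n_iters: int,
               collect_trace: bool) -> Tuple[np.ndarray, List[float], bool]:
    vv = float(np.prod(spacing))
    alpha2 = 1.0 / float(np.mean(spacing)) ** 2
    sig_u = params.smooth_update_vox
    sig_f = params.smooth_field_vox

    def E(vec):
        warped = _warp_array(moving, vec, spacing)
        return _energy_arrays(fixed, moving, vec, spacing, params.lambda_smooth,
                              roi, vv, warped=warped), warped

    def smoothed(vec, sig):
        if sig <= 0:
            return vec
        out = np.empty_like(vec)
        for c in range(3):
            out[..., c] = ndimage.gaussian_filter(vec[..., c], sigma=sig)
        return out

    cur_e, warped = E(u)
    trace = [cur_e]
    converged = False
    step = params.step_size
    for _ in range(n_iters):
        # `warped` carries over from the accepted candidate's energy evaluation
        diff = fixed - warped
        g = np.gradient(warped, *spacing)
        g2 = g[0] ** 2 + g[1] ** 2 + g[2] ** 2
        denom = np.maximum(g2 + alpha2 * diff ** 2, 1e-12)
        scale = np.where(denom > 1e-12, diff / denom, 0.0)
        if roi is not None:
            scale = scale * roi
        force = smoothed(
            np.stack([scale * g[c] for c in range(3)], axis=-1).astype(np.float32),
            sig_u,
        )
        accepted = False
        trial = step
        for _half in range(params.max_step_halvings + 1):
            cand = smoothed(u + trial * force, sig_f)
            cand_e, cand_warped = E(cand)
            if np.isfinite(cand_e) and cand_e <= cur_e:
                accepted = True
                break
            trial *= 0.5
        if accepted:
            # remember the working step; retry slightly larger next iteration
            step = min(params.step_size, trial * 1.3)
        else:
            # field smoothing can stall descent near convergence: fall back to
            # the pure (fluid-like) force step before declaring the level done
            cand = u + trial * force
            cand_e, cand_warped = E(cand)
            if not (np.isfinite(cand_e) and cand_e <= cur_e):
                converged = True
                break
        u = cand
        warped = cand_warped
        rel = (cur_e - cand_e) / max(cur_e, 1e-12)
        cur_e = cand_e
        trace.append(cur_e)
        if rel < params.stop_tol:
            converged = True
            break
    return u, (trace if collect_trace else []), converged


def register(fixed: PhaseVolume, moving: PhaseVolume,
             params: Optional[RegistrationParams] = None) -> RegistrationResult:
    """Estimate the displacement field aligning ``moving`` onto ``fixed``.

    The field lives on the fixed grid and maps fixed points x to moving
    points x + u(x), so reference-phase contours are pulled forward with
    :func:`warp_mask`.
    """
    params = params or RegistrationParams()
    require_same_grid(fixed.grid, moving.grid, "fixed and moving images")
    grid = fixed.grid
    f0 = fixed.intensity.astype(np.float32)
    m0 = moving.intensity.astype(np.float32)
    if not (np.isfinite(f0).all() and np.isfinite(m0).all()):
        raise ValueError("registration inputs must be finite")
    if np.ptp(f0) == 0 and np.ptp(m0) == 0:
        log.warning("degenerate (constant) images: returning zero field")
        return RegistrationResult(DisplacementField.zero(grid), [], True, 0,
                                  degenerate=True)

    roi_full = body_roi_mask(f0, m0) if params.roi == "body" else None
    factors = _pyramid_factors(grid.shape, params.n_levels, params.min_slices)

    u = None
    trace: List[float] = []
    levels_run = 0
    converged = False
    for level in range(params.n_levels - 1, -1, -1):
        fct = factors[level]
        f = _downsample(f0, fct) if fct != (1, 1, 1) else f0
        m = _downsample(m0, fct) if fct != (1, 1, 1) else m0
        roi = None
        if roi_full is not None:
            roi = roi_full[:: fct[0], :: fct[1], :: fct[2]]
        spacing = tuple(grid.spacing_mm[a] * fct[a] for a in range(3))
        if u is None:
            u = np.zeros(f.shape + (3,), dtype=np.float32)
        else:
            zoom = [f.shape[a] / u.shape[a] for a in range(3)] + [1.0]
            u = ndimage.zoom(u, zoom, order=1, mode="nearest",
                             grid_mode=False).astype(np.float32)
            # zoom can be off by one voxel on odd shapes; pad/crop to match
            u = _fit_shape(u, f.shape + (3,))
        n_iters = params.iters_per_level[params.n_levels - 1 - level]
        u, lvl_trace, converged = _run_level(
            f, m, u, spacing, roi, params, n_iters, collect_trace=(level == 0)
        )
        if level == 0:
            trace = lvl_trace
        levels_run += 1
    dvf = DisplacementField(u, grid)
    return RegistrationResult(dvf, trace, converged, levels_run)


def _fit_shape(arr: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Pad (edge) or crop ``arr`` to ``shape``."""
    if arr.shape == tuple(shape):
        return arr
    pads = []
    slices = []
    for a, (have, want) in enumerate(zip(arr.shape, shape)):
        pads.append((0, max(0, want - have)))
        slices.append(slice(0, want))
    return np.pad(arr, pads, mode="edge")[tuple(slices)]


# ---------------------------------------------------------------------------
# contour propagation


@dataclass
class PropagationResult:
    """DIR-propagated contours for every phase of a series."""

    masks: Dict[int, Dict[str, ContourMask]]   # phase -> key -> mask
    registrations: Dict[int, RegistrationResult]
    errors: Dict[int, str] = field(default_factory=dict)


def propagate_contours(series: Sequence[PhaseVolume],
                       reference_masks: Dict[str, ContourMask],
                       params: Optional[RegistrationParams] = None,
                       ) -> PropagationResult:
    """Propagate full-exhalation (phase 0) contours to every other phase.

    For each phase p != 0 the registration uses fixed = phase p and
    moving = phase 0, then warps each reference mask by the resulting field.
    All reference masks share the per-phase field, so several contour sets
    (e.g. two observers) are propagated with one registration per phase.
    A failed registration yields an error entry; remaining phases still run.
    """
    params = params or RegistrationParams()
    ref_grid = series[0].grid
    for key, m in reference_masks.items():
        require_same_grid(m.grid, ref_grid, f"reference mask {key!r} and series")
    out_masks: Dict[int, Dict[str, ContourMask]] = {}
    regs: Dict[int, RegistrationResult] = {}
    errors: Dict[int, str] = {}
    for p, vol in enumerate(series):
        if p == 0:
            out_masks[0] = {
                k: m.tagged(data=m.data.copy(), phase_index=0, source="auto")
                for k, m in reference_masks.items()
            }
            continue
        try:
            res = register(vol, series[0], params)
            regs[p] = res
            out_masks[p] = {
                k: warp_mask(m, res.dvf).tagged(phase_index=p, source="auto")
                for k, m in reference_masks.items()
            }
        except Exception as exc:  # per-phase isolation by contract
            log.error("propagation failed at phase %d: %s", p, exc)
            errors[p] = str(exc)
    return PropagationResult(out_masks, regs, errors)
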