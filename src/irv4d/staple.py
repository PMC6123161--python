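"""Binary STAPLE consensus over multiple contour sets.

Simultaneous truth and performance level estimation: an EM algorithm that
treats the unknown true segmentation as a latent per-voxel indicator and each
rater as a binary channel with sensitivity p_j and specificity q_j.

E-step (posterior weight of foreground at voxel x, given decisions d_j):

    W(x) = a / (a + b)
    a = pi  * prod_j p_j^{d_j} (1 - p_j)^{1 - d_j}
    b = (1 - pi) * prod_j (1 - q_j)^{d_j} q_j^{1 - d_j}

M-step:

    p_j = sum W d_j / sum W
    q_j = sum (1 - W)(1 - d_j) / sum (1 - W)

The consensus mask used as reference ground truth is the S95 mask: voxels
whose posterior probability of being true foreground is at least 0.95.
Computation is restricted to an evaluation box around the union of the input
masks (the same convention the overlap metrics use for the complement),
which keeps the spatially constant prior meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .grid import ContourMask, require_same_grid

_EPS = 1e-6


class DegenerateMasksError(ValueError):
    """Raised when every input mask is empty."""


@dataclass
class RaterPerformance:
    sensitivity_p: float
    specificity_q: float


@dataclass
class ConsensusResult:
    posterior: np.ndarray          # full-grid W, zeros outside the domain
    s95_mask: ContourMask
    performances: List[RaterPerformance]
    n_iterations: int
    converged: bool
    domain: Tuple[slice, slice, slice]
    prior_pi: float


def evaluation_box(masks: Sequence[np.ndarray], shape,
                   dilate_xy: int = 10, dilate_z: int = 2):
    """Bounding box of the union of masks, dilated in-plane and in slices."""
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m
    if not union.any():
        raise DegenerateMasksError("all input masks are empty")
    idx = np.argwhere(union)
    pad = np.array([dilate_xy, dilate_xy, dilate_z])
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def staple(masks: Sequence[ContourMask],
           prior_pi: Optional[float] = None,
           init_p: float = 0.99,
           init_q: float = 0.99,
           tol: float = 1e-6,
           max_iter: int = 100,
           confidence: float = 0.95,
           dilate_xy: int = 10,
           dilate_z: int = 2) -> ConsensusResult:
    """Run binary STAPLE on two or more masks sharing a grid."""
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least two input masks")
    grid = masks[0].grid
    for m in masks[1:]:
        require_same_grid(grid, m.grid, "STAPLE input masks")
    arrays = [m.data for m in masks]
    box = evaluation_box(arrays, grid.shape, dilate_xy, dilate_z)

    d = np.stack([a[box].reshape(-1) for a in arrays]).astype(np.float64)  # (J, N)
    n_raters, n_vox = d.shape
    pi = float(np.mean(d)) if prior_pi is None else float(prior_pi)
    pi = float(np.clip(pi, _EPS, 1.0 - _EPS))

    p = np.full(n_raters, float(init_p))
    q = np.full(n_raters, float(init_q))
    w = np.full(n_vox, pi)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_a = np.log(pi) + (
            d.T @ np.log(p) + (1.0 - d).T @ np.log(1.0 - p)
        )
        log_b = np.log(1.0 - pi) + (
            d.T @ np.log(1.0 - q) + (1.0 - d).T @ np.log(q)
        )
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        w_new = a / (a + b)
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        # M-step
        sw = w.sum()
        swc = (1.0 - w).sum()
        p = (d @ w) / max(sw, _EPS)
        q = ((1.0 - d) @ (1.0 - w)) / max(swc, _EPS)
        p = np.clip(p, _EPS, 1.0 - _EPS)
        q = np.clip(q, _EPS, 1.0 - _EPS)
        if delta < tol:
            converged = True
            break

    posterior = np.zeros(grid.shape, dtype=np.float64)
    posterior[box] = w.reshape(posterior[box].shape)
    s95 = s95_threshold(posterior, grid, confidence=confidence,
                        like=masks[0])
    perfs = [RaterPerformance(float(pj), float(qj)) for pj, qj in zip(p, q)]
    return ConsensusResult(posterior, s95, perfs, it, converged, box, pi)


def s95_threshold(posterior: np.ndarray, grid, confidence: float = 0.95,
                  like: Optional[ContourMask] = None) -> ContourMask:
    """Consensus mask at a confidence level: voxels with W >= confidence."""
    post = np.asarray(posterior, dtype=float)
    if post.min() < 0 or post.max() > 1:
        raise ValueError("posterior values must lie in [0, 1]")
    data = post >= confidence
    tags = {}
    if like is not None:
        tags = dict(organ=like.organ, phase_index=like.phase_index,
                    series=like.series)
    return ContourMask(data, grid, source="s95", **tags)
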