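"""Synthetic respiratory-correlated 4D-MRI phantom with analytic ground truth.

The phantom emulates the study conditions of amplitude-binned T2-weighted
respiratory 4D MRI: ten respiratory bins (phase 0 = full exhalation), a
2 x 2 mm in-plane / 5 mm slice voxel grid, five organs (right and left
lungs, heart, liver, stomach) embedded in a body ellipse, diaphragm SI
excursions of 1-2.6 cm, organ centre-of-mass motion smaller than the
ipsilateral diaphragm motion, and volume-conserving non-lung organs.

Motion model
------------
A single SI-dominant analytic displacement field, scaled per phase by the
phase amplitude fraction (1 - cos)/2.  The field is assembled from

* a background envelope: com_fraction x (lateral amplitude blend) x a smooth
  axial profile that rises from zero at the inferior grid edge, is flat
  through the abdomen, and decays to zero above the lung apex;
* per-lung "swept ellipsoid" bumps carrying the full diaphragm amplitude at
  the lung base (exactly the configured amplitude at the diaphragm dome) and
  decaying toward the apex -- the lungs deform;
* per-organ plateaus for heart, liver and stomach overlaid hierarchically:
  inside each plateau (the organ swept through its full pull range, plus an
  interpolation margin) the field is exactly constant, so these organs
  translate rigidly at every phase and conserve volume up to voxelization.

The field maps fixed-image points x to reference points x + u(x) (the same
pull-back convention the registration module uses), so a positive SI
component renders the anatomy shifted inferiorly, as in inhalation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import (
    OAR_ORGANS,
    ORGAN_LABELS,
    AnatomyLabelMap,
    ContourMask,
    DisplacementField,
    GeometryError,
    Grid,
    PhaseVolume,
)
from .registration import warp_image, warp_mask


class ConfigurationError(ValueError):
    """Raised when a phantom configuration cannot be realized."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OrganShape:
    """Ellipsoid organ: centre and semi-axes as fractions of the field of view."""

    center_frac: Tuple[float, float, float]
    semiaxes_frac: Tuple[float, float, float]

    def center_mm(self, fov: np.ndarray) -> np.ndarray:
        return np.asarray(self.center_frac) * fov

    def semiaxes_mm(self, fov: np.ndarray) -> np.ndarray:
        return np.asarray(self.semiaxes_frac) * fov


def default_organ_geometry() -> Dict[str, OrganShape]:
    """Anatomy layout: lungs superior, liver inferior right, stomach inferior
    left, heart in the mediastinum between and above them."""
    return {
        "right_lung": OrganShape((0.30, 0.50, 0.72), (0.145, 0.21, 0.20)),
        "left_lung": OrganShape((0.70, 0.50, 0.72), (0.145, 0.21, 0.20)),
        "heart": OrganShape((0.52, 0.44, 0.56), (0.115, 0.115, 0.105)),
        "liver": OrganShape((0.30, 0.52, 0.22), (0.155, 0.22, 0.115)),
        "stomach": OrganShape((0.67, 0.45, 0.24), (0.115, 0.14, 0.10)),
    }


#: T2W-like organ mean intensities (arbitrary units); pairwise separation is
#: large against the default noise so the phantom is segmentable.
DEFAULT_INTENSITY_MEANS = {
    "air": 0.0,
    "right_lung": 150.0,
    "left_lung": 230.0,
    "body": 330.0,
    "liver": 440.0,
    "heart": 560.0,
    "stomach": 700.0,
}

#: in-plane body ellipse, fractions of FOV
BODY_SEMIAXES_FRAC = (0.46, 0.40)


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: Tuple[int, int, int] = (96, 96, 48)
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 5.0)
    n_phases: int = 10
    diaphragm_amplitude_right_mm: float = 16.0
    diaphragm_amplitude_left_mm: float = 17.0
    com_fraction: float = 0.75        # liver/stomach COM vs ipsilateral dome
    heart_fraction: float = 0.65      # heart plateau vs mean dome amplitude
    noise_sigma: float = 15.0
    texture_amplitude: Optional[float] = None  # default: 1.6 * noise_sigma
    texture_corr_mm: float = 15.0
    organ_geometry: Optional[Dict[str, OrganShape]] = None
    intensity_means: Optional[Dict[str, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ConfigurationError("n_phases must be >= 2")
        if min(self.diaphragm_amplitude_right_mm, self.diaphragm_amplitude_left_mm) < 0:
            raise ConfigurationError("diaphragm amplitudes must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing must be strictly positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing_mm)

    @property
    def geometry(self) -> Dict[str, OrganShape]:
        return self.organ_geometry or default_organ_geometry()

    @property
    def means(self) -> Dict[str, float]:
        return self.intensity_means or DEFAULT_INTENSITY_MEANS

    @property
    def texture_amp(self) -> float:
        if self.texture_amplitude is None:
            return 1.6 * self.noise_sigma
        return self.texture_amplitude

    def amplitude_mm(self, side: str) -> float:
        return {
            "right": self.diaphragm_amplitude_right_mm,
            "left": self.diaphragm_amplitude_left_mm,
        }[side]


def phase_amplitude_fraction(phase_index: int, n_phases: int) -> float:
    """Amplitude fraction of a respiratory bin: (1 - cos)/2 of the bin fraction.

    Bins are amplitude-ordered: zero at phase 0 (full exhalation), one at the
    last phase (full inhalation), with the cosine spacing concentrating bins
    near the respiratory extremes where a breather dwells longest.
    """
    if n_phases == 1:
        return 0.0
    return 0.5 * (1.0 - math.cos(math.pi * phase_index / (n_phases - 1)))


# ---------------------------------------------------------------------------
# anatomy


def _open_coords(grid: Grid):
    ax = grid.coordinate_axes()
    return ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]


def build_anatomy(config: PhantomConfig) -> Tuple[AnatomyLabelMap, PhaseVolume]:
    """Build the label map and the noise-free reference intensity volume.

    The reference intensity is the per-label mean plus a smooth, seeded
    texture field inside the body (providing the intensity landmarks that
    drive registration); per-phase acquisition noise is added at render time.
    """
    grid = config.grid
    fov = grid.fov_mm
    x, y, z = _open_coords(grid)
    labels = np.zeros(grid.shape, dtype=np.uint8)

    bx, by = np.asarray(BODY_SEMIAXES_FRAC) * fov[:2]
    cx, cy = 0.5 * fov[0], 0.5 * fov[1]
    body = ((x - cx) / bx) ** 2 + ((y - cy) / by) ** 2 <= 1.0
    labels[np.broadcast_to(body, grid.shape)] = ORGAN_LABELS["body"]

    # paint order makes labels pairwise disjoint; later organs carve earlier ones
    for organ in ("right_lung", "left_lung", "heart", "liver", "stomach"):
        shape = config.geometry[organ]
        c = shape.center_mm(fov)
        s = shape.semiaxes_mm(fov)
        inside = (
            ((x - c[0]) / s[0]) ** 2
            + ((y - c[1]) / s[1]) ** 2
            + ((z - c[2]) / s[2]) ** 2
            <= 1.0
        )
        labels[inside] = ORGAN_LABELS[organ]

    for organ in OAR_ORGANS:
        n = int((labels == ORGAN_LABELS[organ]).sum())
        if n < 100:
            raise ConfigurationError(
                f"grid too small to place organ {organ!r} ({n} voxels < 100)"
            )
    if not (labels == ORGAN_LABELS["body"]).any():
        raise ConfigurationError("grid too small to place organ 'body'")

    intensity = np.zeros(grid.shape, dtype=np.float32)
    means = config.means
    intensity[labels == 0] = means["air"]
    intensity[labels == ORGAN_LABELS["body"]] = means["body"]
    for organ in OAR_ORGANS:
        intensity[labels == ORGAN_LABELS[organ]] = means[organ]

    if config.texture_amp > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
        white = rng.standard_normal(grid.shape)
        sig_vox = [config.texture_corr_mm / s for s in grid.spacing_mm]
        tex = ndimage.gaussian_filter(white, sig_vox)
        sd = tex.std()
        if sd > 0:
            tex = tex / sd * config.texture_amp
        intensity[labels > 0] += tex.astype(np.float32)[labels > 0]

    return AnatomyLabelMap(labels, grid), PhaseVolume(intensity, grid, phase_index=0)


# ---------------------------------------------------------------------------
# analytic motion field


def _smootherstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _cos_sq_fall(t: np.ndarray) -> np.ndarray:
    """1 at t<=0, 0 at t>=1, cos^2 in between."""
    t = np.clip(t, 0.0, 1.0)
    return np.cos(0.5 * np.pi * t) ** 2


def _swept_bump(x, y, z, center: np.ndarray, semi: np.ndarray, sweep_mm: float,
                margin_mm: float, fade: float = 0.28) -> np.ndarray:
    """Soft indicator of an ellipsoid swept inferiorly by ``sweep_mm``.

    Weight is exactly 1 inside the swept ellipsoid grown by ``margin_mm``
    and falls to 0 over ``fade`` in the scaled radial coordinate.
    """
    a, b, c = semi + margin_mm
    dx = (x - center[0]) / a
    dy = (y - center[1]) / b
    dz = z - center[2]
    dzn = np.where(dz > 0, dz / c, np.where(dz >= -sweep_mm, 0.0, (dz + sweep_mm) / c))
    rho = np.sqrt(dx * dx + dy * dy + dzn * dzn)
    return _cos_sq_fall((rho - 1.0) / fade)


def _lateral_amplitude(x, config: PhantomConfig, fov: np.ndarray) -> np.ndarray:
    """Right/left diaphragm amplitude blend across the midline (plateaus
    beyond +-5 mm so each hemithorax sees its own amplitude exactly)."""
    t = _smootherstep((x - 0.5 * fov[0]) / 10.0 + 0.5)
    return (
        config.diaphragm_amplitude_right_mm
        + (config.diaphragm_amplitude_left_mm - config.diaphragm_amplitude_right_mm) * t
    )


def motion_scale_field(config: PhantomConfig) -> np.ndarray:
    """SI displacement magnitude (mm) at full amplitude, per voxel."""
    grid = config.grid
    fov = grid.fov_mm
    x, y, z = _open_coords(grid)
    geo = config.geometry

    a_lat = _lateral_amplitude(x, config, fov)
    lung_bottom = min(
        (geo[o].center_mm(fov)[2] - geo[o].semiaxes_mm(fov)[2])
        for o in ("right_lung", "left_lung")
    )
    apex = max(
        (geo[o].center_mm(fov)[2] + geo[o].semiaxes_mm(fov)[2])
        for o in ("right_lung", "left_lung")
    )
    z_top = 0.964 * fov[2]
    rise = _smootherstep(z / 40.0)
    fall = _cos_sq_fall((z - lung_bottom) / max(z_top - lung_bottom, 1e-6))
    s_ab = np.where(z <= lung_bottom, rise, rise * fall)
    base = config.com_fraction * a_lat * s_ab
    base = np.broadcast_to(base, grid.shape).astype(np.float64)

    # lungs: full amplitude at the base (exact at the diaphragm dome),
    # decaying toward the apex -- the lungs deform
    w_lungs = np.zeros(grid.shape)
    t_lungs = np.zeros(grid.shape)
    for organ, side in (("right_lung", "right"), ("left_lung", "left")):
        amp = config.amplitude_mm(side)
        shape = geo[organ]
        c = shape.center_mm(fov)
        s = shape.semiaxes_mm(fov)
        bottom = c[2] - s[2]
        knee = bottom + 0.6 * s[2]
        h = _cos_sq_fall((z - knee) / max(apex + 8.0 - knee, 1e-6))
        w = _swept_bump(x, y, z, c, s, sweep_mm=amp, margin_mm=0.0)
        w_lungs = w_lungs + w
        t_lungs = t_lungs + w * np.broadcast_to(amp * h, grid.shape)
    wl = np.minimum(w_lungs, 1.0)
    m = (1.0 - wl) * base + np.where(
        w_lungs > 0, t_lungs / np.maximum(w_lungs, 1e-12), 0.0
    ) * wl

    # volume-conserving organs: exactly constant plateaus over the organ plus
    # its full pull range plus an interpolation margin, overlaid hierarchically
    margin = float(max(config.spacing_mm)) + 1.0
    targets = {
        "liver": config.com_fraction * config.diaphragm_amplitude_right_mm,
        "stomach": config.com_fraction * config.diaphragm_amplitude_left_mm,
        "heart": config.heart_fraction
        * 0.5
        * (config.diaphragm_amplitude_right_mm + config.diaphragm_amplitude_left_mm),
    }
    for organ in ("liver", "stomach", "heart"):
        shape = geo[organ]
        w = _swept_bump(
            x, y, z,
            shape.center_mm(fov),
            shape.semiaxes_mm(fov),
            sweep_mm=targets[organ],
            margin_mm=margin,
        )
        m = (1.0 - w) * m + w * targets[organ]

    return np.ascontiguousarray(m, dtype=np.float64)


def analytic_motion_field(config: PhantomConfig, phase_amplitude: float,
                          scale_field: Optional[np.ndarray] = None,
                          ) -> DisplacementField:
    """Ground-truth displacement field at a given amplitude fraction.

    ``scale_field`` may carry a precomputed :func:`motion_scale_field` to
    avoid recomputation across phases.
    """
    if not 0.0 <= phase_amplitude <= 1.0:
        raise ValueError(f"phase_amplitude must be in [0, 1], got {phase_amplitude}")
    grid = config.grid
    if scale_field is None:
        scale_field = motion_scale_field(config)
    vec = np.zeros(grid.shape + (3,), dtype=np.float32)
    vec[..., 2] = phase_amplitude * scale_field
    return DisplacementField(vec, grid)


def dome_voxel_index(lung_mask: ContourMask) -> Tuple[int, int, int]:
    """Diaphragm dome landmark: most inferior occupied slice of the lung over
    the column at the lung's in-plane centre of mass."""
    if lung_mask.is_empty():
        raise ValueError("empty lung mask has no diaphragm dome")
    idx = np.argwhere(lung_mask.data)
    i, j = np.round(idx[:, :2].mean(axis=0)).astype(int)
    col = np.flatnonzero(lung_mask.data[i, j, :])
    if col.size == 0:
        raise ValueError(f"lung column at in-plane COM ({i},{j}) is empty")
    return int(i), int(j), int(col.min())


# ---------------------------------------------------------------------------
# phase rendering


@dataclass
class GroundTruthPhase:
    phase_index: int
    phase_amplitude: float
    masks: Dict[str, ContourMask]
    dvf_from_reference: DisplacementField


def render_phase(anatomy: AnatomyLabelMap, reference: PhaseVolume,
                 dvf: DisplacementField, noise_sigma: float,
                 seed) -> Tuple[PhaseVolume, GroundTruthPhase]:
    """Warp the reference through ``dvf`` and add acquisition noise.

    The masks depend only on the deformation, never on the noise seed.
    """
    if not anatomy.grid.same_as(dvf.grid) or not reference.grid.same_as(dvf.grid):
        raise GeometryError("anatomy, reference and DVF must share a grid")
    warped = warp_image(reference, dvf)
    intensity = warped.intensity
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, noise_sigma, size=intensity.shape
        ).astype(np.float32)
    phase_idx = getattr(dvf, "phase_index", 0)
    vol = PhaseVolume(intensity, reference.grid, phase_index=phase_idx)
    masks = {
        organ: warp_mask(anatomy.organ_mask(organ), dvf)
        for organ in OAR_ORGANS
    }
    truth = GroundTruthPhase(phase_idx, float("nan"), masks, dvf)
    return vol, truth


@dataclass
class Phantom4D:
    """A complete synthetic subject: reference anatomy plus one volume and
    ground truth per respiratory bin (navigator-consistent series)."""

    config: PhantomConfig
    anatomy: AnatomyLabelMap
    reference: PhaseVolume
    phases: List[PhaseVolume]
    truths: List[GroundTruthPhase]

    @property
    def grid(self) -> Grid:
        return self.config.grid

    def truth_masks(self, organ: str) -> List[ContourMask]:
        return [t.masks[organ] for t in self.truths]


def generate_phantom(config: PhantomConfig) -> Phantom4D:
    """Generate the full deterministic 4D phantom for one subject."""
    anatomy, reference = build_anatomy(config)
    scale = motion_scale_field(config)
    phases: List[PhaseVolume] = []
    truths: List[GroundTruthPhase] = []
    for p in range(config.n_phases):
        alpha = phase_amplitude_fraction(p, config.n_phases)
        dvf = analytic_motion_field(config, alpha, scale_field=scale)
        vol, truth = render_phase(
            anatomy, reference, dvf, config.noise_sigma,
            seed=np.random.SeedSequence([int(config.seed), 1000 + p]),
        )
        vol.phase_index = p
        truth.phase_index = p
        truth.phase_amplitude = alpha
        for organ, m in truth.masks.items():
            truth.masks[organ] = m.tagged(phase_index=p, organ=organ, source="truth")
        phases.append(vol)
        truths.append(truth)
    return Phantom4D(config, anatomy, reference, phases, truths)


# ---------------------------------------------------------------------------
# simulated observers


@dataclass(frozen=True)
class RaterProfile:
    """A simulated human observer.

    The contour boundary is displaced by a spatially correlated noise field
    of scale ``boundary_sigma_mm`` plus a systematic in/out ``bias_mm``;
    with probability ``outlier_rate`` the most superior or inferior occupied
    slab is grossly corrupted (truncated or over-extended by >= 2 slices),
    emulating the gross flaws seen at superior-inferior organ edges.
    """

    boundary_sigma_mm: float = 1.5
    bias_mm: float = 0.0
    outlier_rate: float = 0.0
    corr_length_mm: float = 8.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.boundary_sigma_mm < 0:
            raise ValueError("boundary_sigma_mm must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")


def corrupt_si_edge(data: np.ndarray, rng: np.random.Generator,
                    min_slices: int = 2) -> np.ndarray:
    """Grossly corrupt the most superior or inferior occupied slab of a mask:
    truncate it or over-extend it by at least ``min_slices`` slices."""
    out = data.copy()
    ks = np.flatnonzero(out.any(axis=(0, 1)))
    if ks.size == 0:
        return out
    superior = bool(rng.random() < 0.5)
    extend = bool(rng.random() < 0.5)
    n = int(min_slices + rng.integers(0, 2))
    nz = out.shape[2]
    if superior:
        k_edge = int(ks.max())
        if extend:
            for d in range(1, n + 1):
                if k_edge + d < nz:
                    out[:, :, k_edge + d] = out[:, :, k_edge]
        else:
            out[:, :, max(0, k_edge - n + 1): k_edge + 1] = False
    else:
        k_edge = int(ks.min())
        if extend:
            for d in range(1, n + 1):
                if k_edge - d >= 0:
                    out[:, :, k_edge - d] = out[:, :, k_edge]
        else:
            out[:, :, k_edge: k_edge + n] = False
    return out


def _signed_distance(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed distance to the mask surface (negative inside), in mm.

    The raw voxel-centre distance transform overshoots by half a voxel on
    each side of the boundary (the surface runs midway between centres); the
    overshoot is removed by projecting half the voxel pitch onto the local
    surface normal, which matters on anisotropic grids.
    """
    phi = ndimage.distance_transform_edt(
        ~mask, sampling=spacing
    ) - ndimage.distance_transform_edt(mask, sampling=spacing)
    g = np.gradient(phi, *spacing)
    norm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    norm = np.where(norm > 1e-9, norm, 1.0)
    h_half = 0.5 * np.sqrt(
        sum((g[a] / norm * spacing[a]) ** 2 for a in range(3))
    )
    return phi - np.sign(phi) * h_half


def _crop_slices(data: np.ndarray, pad_vox: Sequence[int]):
    idx = np.argwhere(data)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad_vox, data.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def simulate_rater(true_mask: ContourMask, profile: RaterProfile,
                   rng: Optional[np.random.Generator] = None) -> ContourMask:
    """Simulate a human delineation of ``true_mask`` under ``profile``.

    Implemented as a level-set perturbation: the signed distance to the true
    boundary is thresholded at ``bias + eta`` where eta is a Gaussian random
    field smoothed over ``corr_length_mm`` and scaled to ``boundary_sigma_mm``.
    The identity profile (zero sigma, bias and outlier rate) returns the
    input unchanged.
    """
    if true_mask.is_empty():
        raise ValueError("cannot simulate a rater on an empty mask")
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    data = true_mask.data
    if profile.boundary_sigma_mm == 0 and profile.bias_mm == 0:
        out = data.copy()
    else:
        spacing = np.asarray(true_mask.grid.spacing_mm)
        pad_mm = (
            3.0 * profile.corr_length_mm
            + 4.0 * profile.boundary_sigma_mm
            + abs(profile.bias_mm)
            + 6.0
        )
        pad_vox = np.maximum(np.ceil(pad_mm / spacing).astype(int), 4)
        sl = _crop_slices(data, pad_vox)
        sub = data[sl]
        phi = _signed_distance(sub, spacing)
        eta = 0.0
        if profile.boundary_sigma_mm > 0:
            white = rng.standard_normal(sub.shape)
            smooth = ndimage.gaussian_filter(
                white, [profile.corr_length_mm / s for s in spacing]
            )
            sd = smooth.std()
            if sd > 0:
                eta = smooth / sd * profile.boundary_sigma_mm
        new_sub = phi <= profile.bias_mm + eta
        if profile.boundary_sigma_mm > 0 and new_sub.any():
            lab, nlab = ndimage.label(new_sub)
            if nlab > 1:
                sizes = ndimage.sum_labels(new_sub, lab, index=range(1, nlab + 1))
                new_sub = lab == (1 + int(np.argmax(sizes)))
        out = np.zeros_like(data)
        out[sl] = new_sub
    if profile.outlier_rate > 0 and rng.random() < profile.outlier_rate:
        out = corrupt_si_edge(out, rng)
    return true_mask.tagged(data=out, source="manual")


def calibrate_rater_profile(true_mask: ContourMask, jaccard_lo: float,
                            jaccard_hi: float, n_draws: int = 20,
                            seed: int = 0, bias_mm: float = 0.0,
                            max_iter: int = 30) -> RaterProfile:
    """Tune ``boundary_sigma_mm`` so the mean Jaccard of the simulated rater
    against the truth lands in [jaccard_lo, jaccard_hi] over seeded draws.

    Uses bisection; the same per-draw noise seeds are reused at every trial
    sigma, making mean Jaccard monotone in sigma.
    """
    if not 0.0 < jaccard_lo < jaccard_hi <= 1.0:
        raise ValueError("require 0 < jaccard_lo < jaccard_hi <= 1")

    truth = true_mask.data

    def mean_jaccard(sigma: float) -> float:
        js = []
        for i in range(n_draws):
            prof = RaterProfile(boundary_sigma_mm=sigma, bias_mm=bias_mm)
            drawn = simulate_rater(
                true_mask, prof, rng=np.random.default_rng([int(seed), i])
            )
            inter = np.logical_and(drawn.data, truth).sum()
            union = np.logical_or(drawn.data, truth).sum()
            js.append(inter / union if union else 1.0)
        return float(np.mean(js))

    lo, hi = 0.05, 12.0
    if mean_jaccard(hi) > jaccard_hi:
        raise ValueError("target Jaccard interval unreachable (too low a sigma range)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        j = mean_jaccard(mid)
        if jaccard_lo <= j <= jaccard_hi:
            return RaterProfile(boundary_sigma_mm=mid, bias_mm=bias_mm, seed=seed)
        if j > jaccard_hi:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge to Jaccard in [{jaccard_lo}, {jaccard_hi}]"
    )
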