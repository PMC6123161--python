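"""NIfTI / YAML / JSON input-output for volumes, masks and displacement fields.

Volumes and masks are written one file per phase per organ as ``.nii.gz``
with the grid geometry in the affine (diagonal spacing, translation origin);
displacement fields are 4-D NIfTI with the vector component last.  A JSON
manifest ties a simulated series together (phases, organs, provenance, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import nibabel as nib
import numpy as np
import yaml

from .grid import ContourMask, DisplacementField, Grid, PhaseVolume

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised for files this package cannot interpret."""


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag(list(grid.spacing_mm) + [1.0])
    aff[:3, 3] = grid.origin_mm
    return aff


def _grid_from_img(img) -> Grid:
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off, 0.0, atol=1e-5):
        raise FormatError(
            f"{getattr(img, 'file_map', '?')}: only axis-aligned affines are supported"
        )
    spacing = tuple(float(s) for s in np.diag(aff[:3, :3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return Grid(img.shape[:3], spacing, origin)


def save_volume(vol: PhaseVolume, path: PathLike) -> None:
    img = nib.Nifti1Image(vol.intensity.astype(np.float32), _affine(vol.grid))
    nib.save(img, str(path))


def load_volume(path: PathLike, phase_index: int = 0) -> PhaseVolume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return PhaseVolume(data, _grid_from_img(img), phase_index=phase_index)


def save_mask(mask: ContourMask, path: PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def load_mask(path: PathLike, **tags) -> ContourMask:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask, got shape {img.shape}")
    data = np.asanyarray(img.dataobj) > 0
    return ContourMask(data, _grid_from_img(img), **tags)


def save_dvf(dvf: DisplacementField, path: PathLike) -> None:
    img = nib.Nifti1Image(dvf.vectors.astype(np.float32), _affine(dvf.grid))
    nib.save(img, str(path))


def load_dvf(path: PathLike) -> DisplacementField:
    img = nib.load(str(path))
    if img.ndim != 4 or img.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 4-D displacement field with 3 components, "
            f"got shape {img.shape}"
        )
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return DisplacementField(data, _grid_from_img(img))


def save_manifest(manifest: Dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def load_manifest(path: PathLike) -> Dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_yaml_config(path: PathLike) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return cfg


def write_series(out_dir: PathLike, phases, truths, seed: int,
                 series: str = "navigator") -> Path:
    """Write a simulated 4D series: per-phase volumes, per-organ masks, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for vol, truth in zip(phases, truths):
        p = vol.phase_index
        vol_name = f"{series}_phase{p:02d}.nii.gz"
        save_volume(vol, out / vol_name)
        organs = {}
        for organ, mask in truth.masks.items():
            m_name = f"{series}_phase{p:02d}_{organ}.nii.gz"
            save_mask(mask, out / m_name)
            organs[organ] = m_name
        entries.append({"phase": p, "volume": vol_name, "masks": organs})
    manifest = {
        "series": series,
        "seed": seed,
        "n_phases": len(phases),
        "spacing_mm": phases[0].grid.spacing_mm,
        "shape": phases[0].grid.shape,
        "phases": entries,
    }
    path = out / f"{series}_manifest.json"
    save_manifest(manifest, path)
    return path
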