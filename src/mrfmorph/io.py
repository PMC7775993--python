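"""NIfTI import/export for maps, phantoms, and synthetic contrasts."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .matching import QuantitativeMaps

__all__ = ["save_volume", "load_volume", "save_maps", "load_maps"]


def save_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None, descrip: str = ""
) -> None:
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_maps(maps: QuantitativeMaps, out_dir: str | Path) -> None:
    """Write t1/t2/score/scale volumes as t1.nii.gz etc. in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, vol in (
        ("t1", maps.t1_map),
        ("t2", maps.t2_map),
        ("score", maps.match_score),
        ("scale", maps.scale_map),
    ):
        save_volume(vol, out / f"{name}.nii.gz", maps.affine)


def load_maps(in_dir: str | Path, voxel_mm: float = 1.0) -> QuantitativeMaps:
    in_dir = Path(in_dir)
    vols = {}
    affine = None
    for name in ("t1", "t2", "score", "scale"):
        vols[name], affine = load_volume(in_dir / f"{name}.nii.gz")
    return QuantitativeMaps(
        t1_map=vols["t1"],
        t2_map=vols["t2"],
        match_score=vols["score"],
        scale_map=vols["scale"],
        voxel_mm=voxel_mm,
        affine=affine,
    )
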