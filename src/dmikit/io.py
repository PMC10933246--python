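"""NIfTI / CSV output helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .simulate.atlas import LabelAtlas


def save_volume(
    values: np.ndarray,
    voxel_mm: tuple[float, float, float],
    path: str | Path,
    description: str = "",
) -> None:
    """Write a 3D volume as NIfTI with a diagonal affine from the voxel size."""
    affine = np.diag(list(voxel_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    if description:
        img.header["descrip"] = description[:79].encode()
    nib.save(img, str(path))


def save_atlas(atlas: LabelAtlas, path: str | Path) -> None:
    affine = np.diag(list(atlas.voxel_mm) + [1.0])
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)
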