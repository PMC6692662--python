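"""Voxel-raster I/O: NIfTI through nibabel and legacy-VTK ASCII export.

Tissue-label volumes and derived field maps are exchanged as NIfTI with a
diagonal affine carrying the voxel spacing (mm).  For visualization in VTK
viewers, structured grids are written in the legacy ASCII STRUCTURED_POINTS
format — a plain-text format simple enough to emit directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional

import nibabel as nib
import numpy as np

from .phantom import TissueLabelVolume

__all__ = [
    "save_labels_nifti",
    "load_labels_nifti",
    "save_map_nifti",
    "write_vtk_structured_points",
]


def _affine(spacing, origin) -> np.ndarray:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = origin
    return affine


def save_labels_nifti(volume: TissueLabelVolume, path: str | Path) -> None:
    """Write a tissue-label volume as int16 NIfTI (spacing in the affine)."""
    img = nib.Nifti1Image(volume.labels.astype(np.int16),
                          _affine(volume.spacing, volume.origin))
    descrip = ";".join(f"{k}={v}" for v, k in sorted(
        (v, k) for k, v in volume.names.items()))
    img.header["descrip"] = descrip[:79].encode()
    nib.save(img, str(path))


def load_labels_nifti(path: str | Path,
                      names: Mapping[int, str]) -> TissueLabelVolume:
    """Read a tissue-label volume; ``names`` maps label value -> tissue."""
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    labels = np.asarray(img.dataobj).astype(np.int16)
    return TissueLabelVolume(labels=labels, spacing=spacing, origin=origin,
                             names=dict(names))


def save_map_nifti(data: np.ndarray, volume: TissueLabelVolume,
                   path: str | Path) -> None:
    """Write a scalar voxel map (e.g. |E| or |J|) on the volume's grid."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def write_vtk_structured_points(
    path: str | Path,
    volume: TissueLabelVolume,
    scalars: Dict[str, np.ndarray],
) -> None:
    """Write scalar voxel maps as a legacy-VTK ASCII STRUCTURED_POINTS file."""
    shape = volume.labels.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("peristim structured grid export\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {shape[0]} {shape[1]} {shape[2]}\n")
        fh.write("ORIGIN {:g} {:g} {:g}\n".format(*volume.origin))
        fh.write("SPACING {:g} {:g} {:g}\n".format(*volume.spacing))
        fh.write(f"POINT_DATA {int(np.prod(shape))}\n")
        for name, data in scalars.items():
            if data.shape != shape:
                raise ValueError(f"scalar field {name!r} shape mismatch")
            fh.write(f"SCALARS {name.replace(' ', '_')} float 1\n")
            fh.write("LOOKUP_TABLE default\n")
            flat = np.nan_to_num(
                np.asarray(data, dtype=np.float32)).ravel(order="F")
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.6g")
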