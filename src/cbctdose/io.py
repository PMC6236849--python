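"""Volume and vector-field IO: MetaImage (.mha/.mhd) and NIfTI (.nii/.nii.gz).

SimpleITK handles the file formats; this module maps between its (x, y, z)
size / [z, y, x] array convention and the package's [x, y, z]-indexed arrays.
Only axis-aligned (identity direction) volumes are supported; origin and
spacing round-trip bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grids import Geometry, ScalarGrid, VectorField

_IDENTITY = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


def _check_direction(img: sitk.Image, path) -> None:
    d = np.array(img.GetDirection())
    if not np.allclose(d, _IDENTITY, atol=1e-6):
        raise ValueError(
            f"{path}: oblique direction cosines are not supported "
            f"(axis-aligned volumes only)"
        )


def read_volume(path: str | Path, unit_tag: str = "unitless") -> ScalarGrid:
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    values = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(float)
    geom = Geometry(origin=img.GetOrigin(), spacing=img.GetSpacing(), size=img.GetSize())
    return ScalarGrid(geom, values, unit_tag)


def write_volume(grid: ScalarGrid, path: str | Path) -> None:
    arr = np.ascontiguousarray(grid.values.transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetOrigin(grid.geometry.origin)
    img.SetSpacing(grid.geometry.spacing)
    img.SetMetaData("unit_tag", grid.unit_tag)
    sitk.WriteImage(img, str(path))


def read_vector_field(path: str | Path) -> VectorField:
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # [z, y, x, 3]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component vector image")
    disp = np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(float)
    geom = Geometry(origin=img.GetOrigin(), spacing=img.GetSpacing(), size=img.GetSize())
    return VectorField(geom, disp)


def write_vector_field(field: VectorField, path: str | Path) -> None:
    arr = np.ascontiguousarray(field.displacements.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetOrigin(field.geometry.origin)
    img.SetSpacing(field.geometry.spacing)
    sitk.WriteImage(img, str(path))
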