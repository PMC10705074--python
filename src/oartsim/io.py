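"""NIfTI / CSV / YAML round-trips for masks, doses and displacement fields.

Masks and dose grids are written as NIfTI-1 with a diagonal affine built
from the grid geometry; displacement fields use the common 4D convention
(three vector components along the last axis).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import yaml

from .deformation import DisplacementField
from .dosimetry import DoseGrid
from .geometry import GridGeometry, StructureMask

__all__ = [
    "write_mask",
    "read_mask",
    "write_dose",
    "read_dose",
    "write_dvf",
    "read_dvf",
    "read_config",
    "write_json",
]

PathLike = Union[str, Path]


def _geometry_from_nifti(img) -> GridGeometry:
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return GridGeometry(tuple(int(s) for s in img.shape[:3]), spacing, origin)


def write_mask(mask: StructureMask, path: PathLike) -> None:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), mask.geometry.affine()
    )
    img.header["descrip"] = mask.label.encode()[:79]
    nib.save(img, str(path))


def read_mask(path: PathLike, label: str = "") -> StructureMask:
    img = nib.load(str(path))
    return StructureMask(
        _geometry_from_nifti(img), np.asarray(img.dataobj) > 0.5, label
    )


def write_dose(dose: DoseGrid, path: PathLike) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), dose.geometry.affine())
    img.header["descrip"] = f"rx={dose.prescribed_dose:g}Gy".encode()
    nib.save(img, str(path))


def read_dose(path: PathLike, prescribed_dose: float) -> DoseGrid:
    img = nib.load(str(path))
    return DoseGrid(
        _geometry_from_nifti(img),
        np.asarray(img.dataobj, dtype=np.float64),
        prescribed_dose,
    )


def write_dvf(dvf: DisplacementField, path: PathLike) -> None:
    # (x, y, z, 3) layout, vector components last
    data = np.moveaxis(dvf.vectors, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, dvf.geometry.affine()), str(path))


def read_dvf(path: PathLike) -> DisplacementField:
    img = nib.load(str(path))
    geom = _geometry_from_nifti(img)
    vectors = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    support = StructureMask(
        geom, (vectors != 0).any(axis=0), "dvf-support"
    )
    return DisplacementField(geom, vectors, support)


def read_config(path: PathLike) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
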