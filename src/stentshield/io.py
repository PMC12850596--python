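"""File interchange: field maps, images and result records.

Field maps travel as CSV matrices with a JSON sidecar holding coordinates,
resolution and provenance, or as NIfTI volumes with millimetre spacing in
the header.  Magnitude images for flip-angle mapping are accepted as CSV
matrices or NIfTI files.
"""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np

from .fields import FieldMap
from .geometry import SpecError


def save_fieldmap_csv(fmap: FieldMap, prefix) -> tuple[pathlib.Path, pathlib.Path]:
    """Write ``<prefix>.csv`` (values) and ``<prefix>.json`` (sidecar)."""
    prefix = pathlib.Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    sidecar_path = prefix.with_suffix(".json")
    np.savetxt(csv_path, fmap.values, delimiter=",")
    sidecar = {
        "kind": fmap.kind,
        "x_m": fmap.x.tolist(),
        "t_m": fmap.t.tolist(),
        "resolution_m": fmap.resolution,
        "masked_fraction": fmap.masked_fraction,
        "axes": "rows: transverse t, columns: axial x",
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    mask_path = prefix.parent / (prefix.name + "_mask.csv")
    np.savetxt(mask_path, fmap.mask.astype(int), fmt="%d", delimiter=",")
    return csv_path, sidecar_path


def save_fieldmap_nifti(fmap: FieldMap, path) -> pathlib.Path:
    """Write the map as a NIfTI image with mm voxel spacing in the header."""
    path = pathlib.Path(path)
    res_mm = fmap.resolution * 1e3
    affine = np.diag([res_mm, res_mm, 1.0, 1.0])
    img = nib.Nifti1Image(fmap.values.astype(np.float32), affine)
    img.header.set_zooms((res_mm, res_mm))
    nib.save(img, str(path))
    return path


def load_image(path) -> np.ndarray:
    """Read a 2-D magnitude image from CSV or NIfTI."""
    path = pathlib.Path(path)
    if path.suffix in (".nii", ".gz"):
        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return np.squeeze(data)
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter=","))
    except ValueError as exc:
        raise SpecError(f"cannot parse image file {path}: {exc}") from exc


def save_image(array: np.ndarray, path) -> pathlib.Path:
    """Write a 2-D image as CSV (or NIfTI when the suffix says so)."""
    path = pathlib.Path(path)
    if path.suffix == ".nii":
        nib.save(nib.Nifti1Image(np.asarray(array, np.float32), np.eye(4)), str(path))
    else:
        np.savetxt(path, np.asarray(array, float), delimiter=",")
    return path


def save_result_json(result_dict: dict, path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.write_text(json.dumps(result_dict, indent=2, sort_keys=True) + "\n")
    return path
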