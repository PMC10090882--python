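"""File formats: NIfTI label maps, landmark JSON sidecars, CSV tables.

The measurement-table schema is fixed:

``species, specimen_id, clade, thermo_class, body_mass_g, skull_vol_mm3,
hull_vol_mm3, nasal_sa_mm2, nasal_vol_mm3, resp_sa_mm2, resp_vol_mm3``
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .morphometry import DEFAULT_LABELS, LabeledVolume
from .reconstruct import ConstraintLandmarks

__all__ = [
    "MEASUREMENT_COLUMNS",
    "MeasurementValidationError",
    "load_labeled_volume",
    "load_landmarks",
    "load_measurements",
    "save_labeled_volume",
    "save_landmarks",
]

MEASUREMENT_COLUMNS = [
    "species",
    "specimen_id",
    "clade",
    "thermo_class",
    "body_mass_g",
    "skull_vol_mm3",
    "hull_vol_mm3",
    "nasal_sa_mm2",
    "nasal_vol_mm3",
    "resp_sa_mm2",
    "resp_vol_mm3",
]

_SIZE_COLUMNS = MEASUREMENT_COLUMNS[4:]


class MeasurementValidationError(ValueError):
    pass


def save_labeled_volume(vol: LabeledVolume, path: str | Path, labels_path=None) -> None:
    """Write a label map as NIfTI with the voxel spacing in the affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.grid, dtype=np.int16), affine)
    nib.save(img, str(path))
    if labels_path is not None:
        Path(labels_path).write_text(json.dumps(vol.labels, indent=2))


def load_labeled_volume(path: str | Path, labels_path=None) -> LabeledVolume:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj).astype(np.int32)
    affine = img.affine
    spacing = tuple(float(abs(affine[k, k])) for k in range(3))
    origin = tuple(float(affine[k, 3]) for k in range(3))
    labels = dict(DEFAULT_LABELS)
    if labels_path is not None:
        labels = {k: int(v) for k, v in json.loads(Path(labels_path).read_text()).items()}
    return LabeledVolume(grid=grid, spacing=spacing, origin=origin, labels=labels)


def save_landmarks(lm: ConstraintLandmarks, path: str | Path) -> None:
    Path(path).write_text(json.dumps(lm.to_dict(), indent=2))


def load_landmarks(path: str | Path) -> ConstraintLandmarks:
    return ConstraintLandmarks.from_dict(json.loads(Path(path).read_text()))


def load_measurements(path: str | Path) -> pd.DataFrame:
    """Load and validate a measurement table.

    All schema columns must be present; size columns must be numeric and
    strictly positive where not missing.  Body mass may be missing (such
    rows are simply excluded from body-mass comparisons downstream); the
    other size parameters are required.  Errors name the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementValidationError(f"missing columns: {missing}")
    for col in _SIZE_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise MeasurementValidationError(f"column {col!r} is not numeric: {exc}") from exc
        bad = df[col].notna() & (df[col] <= 0)
        if bad.any():
            row = df.index[bad][0]
            raise MeasurementValidationError(
                f"non-positive value {df.loc[row, col]!r} in column {col!r}, row {row} "
                f"(specimen {df.loc[row, 'specimen_id']!r})"
            )
        if col != "body_mass_g" and df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise MeasurementValidationError(
                f"missing value in required column {col!r}, row {row}"
            )
    return df
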