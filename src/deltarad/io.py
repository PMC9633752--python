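"""Volume/mask I/O and the treatment-course cohort table.

Volumes and masks are exchanged as NIfTI-1 files and held in memory as plain
numpy arrays plus a voxel-spacing triple.  Masks must live on the identical
grid as their image (no resampling is performed anywhere in the package).
The cohort table is a CSV with one row per treated lesion carrying the
prescription, fractionation, response label and clinical covariates; a
packaged copy of the study cohort (22 liver lesions treated with MR-guided
SBRT) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "ROIMask",
    "PatientRecord",
    "FormatError",
    "AlignmentError",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_cohort_table",
    "load_packaged_cohort",
    "packaged_cohort_path",
]


class FormatError(ValueError):
    """Raised for unreadable, non-3D, or non-finite image data."""


class AlignmentError(ValueError):
    """Raised when a mask does not share its image's grid."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary MR units), indexed ``[x, y, z]``.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise FormatError(f"expected 3D data, got {data.ndim}D")
        if data.size == 0:
            raise FormatError("empty volume")
        if not np.all(np.isfinite(data)):
            raise FormatError("volume contains non-finite intensities")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"invalid voxel spacing {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ROIMask:
    """Boolean lesion mask aligned voxel-for-voxel with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise AlignmentError(f"expected 3D mask, got {data.ndim}D")
        data = data.astype(bool)
        if not data.any():
            raise AlignmentError("mask contains no voxels")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class PatientRecord:
    """One treated lesion: fractionation, response label, covariates."""

    patient_id: str
    poor_response: bool
    age: float
    rx_dose: float          # total prescription, Gy
    n_fractions: int
    tumor_size: float       # largest dimension, cm
    diagnosis: str          # HCC | ICC | LM
    sex: Optional[str] = None
    ethnicity: Optional[str] = None
    kps: Optional[float] = None
    cirrhosis: Optional[bool] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rx_dose <= 0:
            raise ValueError(f"rx_dose must be > 0, got {self.rx_dose}")
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")
        if self.tumor_size <= 0:
            raise ValueError(f"tumor_size must be > 0, got {self.tumor_size}")


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def load_volume(path) -> ImageVolume:
    """Read a NIfTI volume; spacing comes from the header zooms.

    Raises :class:`FormatError` for non-3D data or non-finite voxels and
    ``FileNotFoundError`` for a missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data=np.asarray(data, dtype=np.float64), spacing=tuple(zooms))


def save_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1, spacing in the affine and header zooms."""
    img = nib.Nifti1Image(np.asarray(volume.data), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_mask(path, reference: ImageVolume) -> ROIMask:
    """Read a binary mask and validate alignment with ``reference``.

    Any nonzero voxel counts as inside the ROI.  Raises
    :class:`AlignmentError` on shape mismatch or an empty mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != reference.shape:
        raise AlignmentError(
            f"mask shape {data.shape} != volume shape {reference.shape}"
        )
    return ROIMask(data=data != 0, spacing=reference.spacing)


def save_mask(mask: ROIMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_from_spacing(mask.spacing)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


_REQUIRED_COLUMNS = [
    "patient_id",
    "poor_response",
    "age",
    "rx_dose",
    "n_fractions",
    "tumor_size",
    "diagnosis",
]
_OPTIONAL_COLUMNS = ["sex", "ethnicity", "kps", "cirrhosis"]

_TRUTHY = {"yes", "true", "1", "y"}
_FALSY = {"no", "false", "0", "n"}


def _parse_bool(value, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse {column}={value!r} as boolean")


def load_cohort_table(path) -> list[PatientRecord]:
    """Load a cohort CSV into validated :class:`PatientRecord` rows.

    Required columns: ``patient_id, poor_response, age, rx_dose,
    n_fractions, tumor_size, diagnosis``; the covariates ``sex, ethnicity,
    kps, cirrhosis`` are optional and recorded as absent (``None``) when the
    column is missing or the cell is empty.  Unrecognized columns are kept
    in ``record.extra``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table has no rows")

    records = []
    extra_cols = [
        c for c in df.columns if c not in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
    ]
    for _, row in df.iterrows():
        try:
            n_fractions = int(row["n_fractions"])
            rx_dose = float(row["rx_dose"])
            age = float(row["age"])
            tumor_size = float(row["tumor_size"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric field in row patient_id={row['patient_id']}: {exc}"
            ) from exc
        kwargs = {}
        for col in _OPTIONAL_COLUMNS:
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip():
                if col == "cirrhosis":
                    kwargs[col] = _parse_bool(row[col], col)
                elif col == "kps":
                    kwargs[col] = float(row[col])
                else:
                    kwargs[col] = str(row[col])
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                poor_response=_parse_bool(row["poor_response"], "poor_response"),
                age=age,
                rx_dose=rx_dose,
                n_fractions=n_fractions,
                tumor_size=tumor_size,
                diagnosis=str(row["diagnosis"]),
                extra={c: row[c] for c in extra_cols},
                **kwargs,
            )
        )
    return records


def packaged_cohort_path() -> Path:
    """Path of the packaged study cohort table (22 liver lesions)."""
    return Path(resources.files("deltarad") / "data" / "cohort_table1.csv")


def load_packaged_cohort() -> list[PatientRecord]:
    """Load the packaged 22-patient study cohort."""
    return load_cohort_table(packaged_cohort_path())
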