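"""Core volumetric containers and file I/O.

Every module in the package shares one grid convention: a volume is a 3-D
array indexed ``(slice, row, col)``, 0-based, with axis 0 the axial slice
axis.  Per-slice operations always iterate axis 0.  A 2-D image is simply a
volume with a single slice.

NIfTI (via nibabel) is the canonical interchange format; DICOM series
reading (via pydicom, slope/intercept applied) is supported for ingesting
scanner output.  MRI intensities are stored as floats even when the source
is integer, because the normalization pipeline is division-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class Modality(str, enum.Enum):
    """What kind of signal a volume holds."""

    MRI = "MRI"
    CT = "CT"
    PSEUDO_CT = "PSEUDO_CT"
    MAP = "MAP"


#: Tissue codes used throughout the package.
AIR_LUNG = 0
SOFT_TISSUE = 1
FAT = 2
TISSUE_NAMES = {AIR_LUNG: "air/lung", SOFT_TISSUE: "soft tissue", FAT: "fat"}


@dataclass
class Volume:
    """A 3-D scalar image with physical spacing and a modality tag.

    Parameters
    ----------
    data:
        3-D array indexed ``(slice, row, col)``.
    spacing:
        Millimetres per axis, in the same ``(slice, row, col)`` order.
    modality:
        One of :class:`Modality`; defaults to MRI.
    units:
        Free-text unit string, e.g. ``"a.u."`` for MRI or ``"HU"`` for CT.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.MRI
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data: np.ndarray, modality: Modality | None = None,
                  units: str | None = None) -> "Volume":
        """A new volume on the same grid with replaced data/tags."""
        return Volume(
            data=np.asarray(data),
            spacing=self.spacing,
            modality=self.modality if modality is None else modality,
            units=self.units if units is None else units,
        )

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class TissueLabelMap:
    """Per-voxel hard tissue labels: 0 air/lung, 1 soft tissue, 2 fat."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 2:
            self.labels = self.labels[np.newaxis]
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("labels must be integers")
            self.labels = rounded.astype(np.int32)
        if self.labels.size and not np.isin(self.labels, (AIR_LUNG, SOFT_TISSUE, FAT)).all():
            bad = np.unique(self.labels[~np.isin(self.labels, (0, 1, 2))])
            raise ValueError(f"label codes outside {{0,1,2}}: {bad}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


# ---------------------------------------------------------------------------
# NIfTI I/O
#
# On disk the array is stored in (col, row, slice) axis order so that the
# NIfTI third axis is the slice axis, matching how viewers treat z.  The
# modality/units tags ride in the 80-byte descrip field.


def _descrip(vol: Volume) -> bytes:
    s = f"modality={vol.modality.value};units={vol.units}"
    return s.encode()[:79]


def _parse_descrip(raw: bytes) -> tuple[Modality | None, str | None]:
    try:
        text = raw.decode(errors="ignore").strip("\x00")
    except Exception:
        return None, None
    modality, units = None, None
    for part in text.split(";"):
        if part.startswith("modality="):
            try:
                modality = Modality(part[len("modality="):])
            except ValueError:
                pass
        elif part.startswith("units="):
            units = part[len("units="):]
    return modality, units


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz); float32 on disk."""
    import nibabel as nib

    path = Path(path)
    zooms = (vol.spacing[2], vol.spacing[1], vol.spacing[0])
    affine = np.diag([*zooms, 1.0])
    img = nib.Nifti1Image(vol.data.transpose(2, 1, 0).astype(np.float32), affine)
    img.header.set_zooms(zooms)
    img.header["descrip"] = _descrip(vol)
    nib.save(img, str(path))


def read_volume(path: str | Path, format: str | None = None) -> Volume:
    """Read a volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_dir"``; when omitted it is inferred
    (directories are treated as DICOM series).  CT volumes read from DICOM
    carry units "HU" with rescale slope/intercept applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected 3-D NIfTI, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    modality, units = _parse_descrip(bytes(img.header["descrip"].tobytes()))
    return Volume(
        data=arr.transpose(2, 1, 0).astype(np.float64),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        modality=modality or Modality.MRI,
        units=units if units is not None else "a.u.",
    )


def _read_dicom_dir(path: Path) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    def slice_pos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=slice_pos)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise ValueError("non-scalar / non-2-D pixel data in DICOM slice")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    data = np.stack(slices, axis=0)

    ds0 = datasets[0]
    row_sp, col_sp = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    if len(datasets) > 1 and hasattr(ds0, "ImagePositionPatient"):
        gaps = np.diff([slice_pos(ds) for ds in datasets])
        if np.ptp(gaps) > 1e-3:
            raise ValueError("inconsistent slice spacing in DICOM series")
        slice_sp = float(abs(gaps[0]))
    else:
        slice_sp = float(getattr(ds0, "SliceThickness", 1.0))

    is_ct = getattr(ds0, "Modality", "") == "CT"
    return Volume(
        data=data,
        spacing=(slice_sp, row_sp, col_sp),
        modality=Modality.CT if is_ct else Modality.MRI,
        units="HU" if is_ct else "a.u.",
    )


def write_labels(labels: TissueLabelMap, path: str | Path) -> None:
    """Write a tissue label map as an integer NIfTI."""
    import nibabel as nib

    zooms = (labels.spacing[2], labels.spacing[1], labels.spacing[0])
    affine = np.diag([*zooms, 1.0])
    img = nib.Nifti1Image(labels.labels.transpose(2, 1, 0).astype(np.int16), affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(Path(path)))


def read_labels(path: str | Path) -> TissueLabelMap:
    vol = read_volume(path, format="nifti")
    return TissueLabelMap(labels=np.rint(vol.data).astype(np.int32), spacing=vol.spacing)
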