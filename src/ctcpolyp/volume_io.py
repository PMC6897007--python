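"""CT volume I/O and intensity conversion.

Volumes are carried as :class:`CtVolume`: a 3-D grid of Hounsfield Units
(HU) with physical voxel spacing in millimetres.  Voxel indices are 0-based
``(slice, row, col)``; physical coordinates are ``index * spacing``; all
reported lengths are millimetres.  HU are stored as 16-bit signed integers
and converted to display grey levels only at output boundaries.

DICOM series are read/written with :mod:`pydicom` (rescale slope/intercept
applied so voxels are HU), NIfTI-1 with :mod:`nibabel`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

log = logging.getLogger(__name__)

HU_MIN = -1024
HU_MAX = 3071

#: In-plane pixel sizes (mm) typical of abdominal CTC acquisitions
#: (512-pixel matrix over a 28-50 cm field of view).  Values outside this
#: range are accepted with a warning.
PIXEL_SIZE_RANGE_MM = (0.546875, 0.9765625)


@dataclass
class CtVolume:
    """A 3-D CT volume in Hounsfield Units.

    Parameters
    ----------
    voxels :
        ``(n_slices, n_rows, n_cols)`` array of integer HU.
    spacing :
        ``(row, col, slice)`` voxel spacing in mm, all strictly positive.
    kvp :
        Peak tube kilovoltage of the acquisition, if known.
    meta :
        Free-form acquisition tags.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    kvp: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if self.voxels.dtype != np.int16:
            self.voxels = np.clip(np.rint(self.voxels), HU_MIN, HU_MAX).astype(np.int16)
        if self.voxels.size and (
            self.voxels.min() < HU_MIN or self.voxels.max() > HU_MAX
        ):
            raise ValueError(f"HU values must lie in [{HU_MIN}, {HU_MAX}]")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values (mm)")
        lo, hi = PIXEL_SIZE_RANGE_MM
        for s in self.spacing[:2]:
            if not (lo <= s <= hi):
                warnings.warn(
                    f"in-plane pixel size {s:.4f} mm outside the usual CTC "
                    f"range [{lo}, {hi}] mm",
                    stacklevel=2,
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        """In-plane (row, col) spacing in mm."""
        return self.spacing[0], self.spacing[1]

    @property
    def slice_spacing(self) -> float:
        return self.spacing[2]

    def copy(self) -> "CtVolume":
        return CtVolume(self.voxels.copy(), self.spacing, self.kvp, dict(self.meta))


@dataclass(frozen=True)
class WindowLevel:
    """Display window: centre ``C`` and width ``W`` in HU, ``bits`` grey bits.

    The left border is ``P1 = C - W/2``; HU at or below ``P1`` map to 0, HU
    at or above ``P1 + W`` map to ``2**bits - 1``, with a linear ramp in
    between.
    """

    center: float
    width: float
    bits: int = 8

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if self.bits not in (8, 12, 16):
            raise ValueError("display bits must be one of 8, 12, 16")

    @property
    def p1(self) -> float:
        return self.center - self.width / 2.0


def attenuation_to_hu(mu_t: float | np.ndarray, mu_w: float) -> float | np.ndarray:
    """Convert a linear attenuation coefficient to HU.

    ``HU = 1000 * (mu_t - mu_w) / mu_w`` with water at 0 HU and air
    (``mu = 0``) at -1000 HU.
    """
    if mu_w <= 0:
        raise ValueError("water attenuation coefficient must be positive")
    return 1000.0 * (np.asarray(mu_t, dtype=float) - mu_w) / mu_w if isinstance(
        mu_t, np.ndarray
    ) else 1000.0 * (mu_t - mu_w) / mu_w


def apply_window(
    data: CtVolume | np.ndarray, wl: WindowLevel
) -> np.ndarray:
    """Map HU to integer display grey levels in ``[0, 2**bits - 1]``."""
    hu = data.voxels if isinstance(data, CtVolume) else np.asarray(data)
    gmax = 2**wl.bits - 1
    ramp = (hu.astype(float) - wl.p1) / wl.width * gmax
    out = np.floor(np.clip(ramp, 0, gmax) + 0.5)
    dtype = np.uint8 if wl.bits == 8 else np.uint16
    return out.astype(dtype)


# --- DICOM attribute completeness -------------------------------------------

#: Built-in required-attribute subset used by :func:`validate_dicom`.
#: Type 1 attributes must be present and non-empty; type 2 must be present
#: but may be empty.  This is a fixed, documented subset sufficient for the
#: pipeline, not the full PS3.3 conformance tables.
REQUIRED_TYPE1 = (
    "Rows",
    "Columns",
    "PixelSpacing",
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "RescaleIntercept",
    "RescaleSlope",
    "Modality",
    "StudyInstanceUID",
    "SeriesInstanceUID",
)
REQUIRED_TYPE2 = (
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientSex",
    "SliceThickness",
    "KVP",
)


def _is_empty(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, (list, tuple)) and len(value) == 0:
        return True
    return str(value) == ""


def validate_dicom(meta: Mapping[str, Any]) -> list[str]:
    """Report missing required DICOM attributes (report-only, never raises).

    Returns the keyword names of type-1 attributes that are absent or empty
    and type-2 attributes that are absent (empty type-2 values are allowed).
    """
    violations: list[str] = []
    get = meta.get if hasattr(meta, "get") else lambda k, d=None: getattr(meta, k, d)
    sentinel = object()
    for name in REQUIRED_TYPE1:
        value = get(name, sentinel)
        if value is sentinel or _is_empty(value):
            violations.append(name)
    for name in REQUIRED_TYPE2:
        value = get(name, sentinel)
        if value is sentinel:
            violations.append(name)
    return violations


# --- DICOM read/write --------------------------------------------------------

def write_dicom_series(vol: CtVolume, directory: str | Path) -> list[Path]:
    """Write a volume as a single-series DICOM stack (one file per slice)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    series_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    # store as unsigned with intercept -1024 so all HU are representable
    intercept = float(HU_MIN)
    stored = (vol.voxels.astype(np.int32) - HU_MIN).astype(np.uint16)
    for i in range(vol.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = vol.meta.get("PatientName", "PHANTOM^CTC")
        ds.PatientID = vol.meta.get("PatientID", "PHANTOM")
        ds.PatientBirthDate = ""
        ds.PatientSex = ""
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * vol.slice_spacing]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.spacing[0], vol.spacing[1]]
        ds.SliceThickness = vol.slice_spacing
        if vol.kvp is not None:
            ds.KVP = vol.kvp
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = 1.0
        ds.PixelData = stored[i].tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def _read_dicom_dir(directory: Path) -> CtVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:  # non-DICOM files in the directory are skipped
            log.debug("skipping non-DICOM file %s", p)
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")
    series = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series) > 1:
        raise ValueError(f"directory holds {len(series)} series; expected one")

    def position(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=position)
    first = datasets[0]
    if not hasattr(first, "RescaleSlope") or not hasattr(first, "RescaleIntercept"):
        warnings.warn("missing rescale tags; assuming identity rescale", stacklevel=2)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    hu = np.stack(
        [ds.pixel_array.astype(np.float64) * slope + intercept for ds in datasets]
    )
    pixel_spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        slice_sp = abs(position(datasets[1]) - position(datasets[0])) or float(
            getattr(first, "SliceThickness", 1.0)
        )
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0))
    kvp = getattr(first, "KVP", None)
    meta = {
        kw: getattr(first, kw)
        for kw in (*REQUIRED_TYPE1, *REQUIRED_TYPE2)
        if hasattr(first, kw)
    }
    return CtVolume(
        hu,
        (float(pixel_spacing[0]), float(pixel_spacing[1]), float(slice_sp)),
        kvp=float(kvp) if kvp not in (None, "") else None,
        meta=meta,
    )


# --- NIfTI read/write --------------------------------------------------------

def write_nifti(vol: CtVolume, path: str | Path) -> Path:
    """Write a volume (or mask) as NIfTI-1; kVp is kept in the descrip field."""
    import nibabel as nib

    path = Path(path)
    # nibabel convention: (x, y, z) = (col, row, slice)
    data = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0))
    affine = np.diag([vol.spacing[1], vol.spacing[0], vol.spacing[2], 1.0])
    img = nib.Nifti1Image(data, affine)
    if vol.kvp is not None:
        img.header["descrip"] = f"kvp={vol.kvp:g}".encode()
    nib.save(img, str(path))
    return path


def write_mask_nifti(
    mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path
) -> Path:
    """Write a boolean mask as an 8-bit NIfTI."""
    import nibabel as nib

    affine = np.diag([spacing[1], spacing[0], spacing[2], 1.0])
    data = np.ascontiguousarray(mask.astype(np.uint8).transpose(2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return Path(path)


def _read_nifti(path: Path) -> CtVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[1]), float(zooms[0]), float(zooms[2]))
    kvp = None
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(
        "ascii", "ignore"
    )
    if descrip.startswith("kvp="):
        try:
            kvp = float(descrip[4:])
        except ValueError:
            pass
    return CtVolume(data, spacing, kvp=kvp)


def read_mask_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj).transpose(2, 1, 0) > 0


def read_volume(path: str | Path) -> CtVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    Slices are sorted by patient position and the rescale slope/intercept is
    applied so voxel values are HU.  Mixed series in one directory raise.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    raise ValueError(f"cannot determine volume format for {path}")
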