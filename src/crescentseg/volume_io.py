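"""Reading and writing CT series and binary masks.

One in-memory representation is used everywhere: a 3-D voxel grid indexed
``(slice, row, col)`` with explicit geometry — in-plane pixel spacing
``(row, col)`` in millimetres and a scalar inter-slice spacing in
millimetres.  Slice index 0 is the lowest anatomical position.

Three on-disk formats are supported:

* classic DICOM series — a directory of single-frame ``.dcm`` files, one
  per slice, ordered by ``ImagePositionPatient`` (never by file name);
* NIfTI (``.nii`` / ``.nii.gz``) via nibabel, data stored ``(x, y, z)``
  with spacings in the affine zooms;
* a portable ``.npz`` array archive used for programmatic fixtures.

DICOM patient-position metadata is used only to order slices and derive
the inter-slice spacing; no resampling or reorientation is performed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CTVolume",
    "MaskVolume",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "normalize_intensity",
]

#: relative tolerance beyond which inter-slice gaps are reported non-uniform
SLICE_SPACING_RTOL = 1e-3


def _check_geometry(voxels: np.ndarray, pixel_spacing, slice_spacing: float) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"voxels must be 3-D (slice, row, col), got ndim={voxels.ndim}")
    ps = tuple(float(s) for s in pixel_spacing)
    if len(ps) != 2:
        raise ValueError("pixel_spacing must be a (row, col) pair")
    if min(ps) <= 0 or float(slice_spacing) <= 0:
        raise ValueError("all spacings must be strictly positive")


@dataclass
class CTVolume:
    """An ordered axial slice stack with voxel geometry.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, rows, cols)
        Scalar grid; slice 0 is the lowest anatomical position.
    pixel_spacing : (float, float)
        In-plane (row, col) spacing in mm.
    slice_spacing : float
        Distance between adjacent slice centres in mm.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_spacing: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_geometry(self.voxels, self.pixel_spacing, self.slice_spacing)
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        self.slice_spacing = float(self.slice_spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_spacing

    def same_geometry(self, other: "CTVolume | MaskVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.pixel_spacing, other.pixel_spacing)
            and np.isclose(self.slice_spacing, other.slice_spacing)
        )


@dataclass
class MaskVolume:
    """A binary grid congruent to a :class:`CTVolume` (values in {0, 1})."""

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_spacing: float

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        _check_geometry(vox, self.pixel_spacing, self.slice_spacing)
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask voxels must take values in {0, 1}")
        self.voxels = vox.astype(np.uint8)
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        self.slice_spacing = float(self.slice_spacing)

    n_slices = CTVolume.n_slices
    shape = CTVolume.shape
    voxel_volume_mm3 = CTVolume.voxel_volume_mm3
    same_geometry = CTVolume.same_geometry


# ---------------------------------------------------------------------------
# format detection


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if path.is_dir():
        return "dicom"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "archive"
    raise ValueError(f"cannot infer format of {path}; pass format= explicitly")


# ---------------------------------------------------------------------------
# NIfTI

# Internally voxels are (slice, row, col); NIfTI data is written (x, y, z) =
# (col, row, slice), so a plain transpose converts between the two and the
# affine zooms are (col_spacing, row_spacing, slice_spacing).


def _write_nifti(voxels: np.ndarray, pixel_spacing, slice_spacing, path: Path) -> None:
    affine = np.diag([pixel_spacing[1], pixel_spacing[0], slice_spacing, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(voxels.T), affine)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    voxels = np.ascontiguousarray(data.T)
    return voxels, (float(zooms[1]), float(zooms[0])), float(zooms[2])


# ---------------------------------------------------------------------------
# array archive


def _write_archive(voxels, pixel_spacing, slice_spacing, path: Path) -> None:
    np.savez(
        path,
        voxels=voxels,
        pixel_spacing=np.asarray(pixel_spacing, dtype=np.float64),
        slice_spacing=np.float64(slice_spacing),
    )


def _read_archive(path: Path):
    with np.load(path) as z:
        voxels = z["voxels"]
        ps = z["pixel_spacing"]
        ss = float(z["slice_spacing"])
    return voxels, (float(ps[0]), float(ps[1])), ss


# ---------------------------------------------------------------------------
# DICOM


def write_dicom_series(volume: CTVolume, directory: str | os.PathLike) -> None:
    """Write one classic CT series, one int16 file per slice.

    Voxel values are rounded to the nearest integer (rescale slope 1,
    intercept 0), so the round trip is exact only for integer-valued
    volumes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    n, rows, cols = volume.shape
    for i in range(n):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "anonymous"
        ds.PatientID = "anonymous"
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(i * volume.slice_spacing)]
        ds.PixelSpacing = [float(volume.pixel_spacing[0]), float(volume.pixel_spacing[1])]
        ds.SliceThickness = float(volume.slice_spacing)
        ds.SpacingBetweenSlices = float(volume.slice_spacing)
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = rows
        ds.Columns = cols
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = np.round(volume.voxels[i]).astype(np.int16).tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) > 1:
        raise ValueError(
            f"directory {directory} mixes {len(series_uids)} distinct series; "
            "expected exactly one SeriesInstanceUID"
        )

    for attr in ("PixelSpacing", "ImagePositionPatient"):
        missing = [f.name for f, ds in zip(files, datasets) if not hasattr(ds, attr)]
        if missing:
            raise ValueError(f"DICOM metadata attribute {attr} missing in {missing[0]}")

    # sort by through-plane position, never by file name
    order = sorted(range(len(datasets)), key=lambda i: float(datasets[i].ImagePositionPatient[2]))
    datasets = [datasets[i] for i in order]

    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    gaps = np.diff(zs)
    if len(gaps):
        if (gaps <= 0).any():
            raise ValueError("duplicate or non-increasing slice positions in series")
        spacing = float(np.mean(gaps))
        dev = float(np.max(np.abs(gaps - spacing)))
        if dev > SLICE_SPACING_RTOL * spacing:
            warnings.warn(
                f"non-uniform slice gaps in {directory}: max deviation {dev:.4g} mm "
                f"from mean spacing {spacing:.4g} mm",
                stacklevel=3,
            )
    else:
        spacing = float(getattr(datasets[0], "SpacingBetweenSlices", 1.0))

    ps = datasets[0].PixelSpacing
    pixel_spacing = (float(ps[0]), float(ps[1]))

    planes = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    return np.stack(planes), pixel_spacing, spacing


# ---------------------------------------------------------------------------
# public API


def read_series(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read one CT series from ``path``.

    Parameters
    ----------
    path : str or Path
        A DICOM directory, a NIfTI file, or an ``.npz`` archive.
    format : {"dicom", "nifti", "archive"}, optional
        Inferred from the path when omitted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "dicom":
        voxels, ps, ss = _read_dicom_series(path)
    elif fmt == "nifti":
        voxels, ps, ss = _read_nifti(path)
    elif fmt == "archive":
        voxels, ps, ss = _read_archive(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CTVolume(voxels, ps, ss)


def write_series(volume: CTVolume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a CT series; format inferred from the path when omitted."""
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif name.endswith(".npz"):
            format = "archive"
        else:  # extensionless target: a DICOM directory to be created
            format = "dicom"
    fmt = format
    if fmt == "dicom":
        write_dicom_series(volume, path)
    elif fmt == "nifti":
        _write_nifti(volume.voxels, volume.pixel_spacing, volume.slice_spacing, path)
    elif fmt == "archive":
        _write_archive(volume.voxels, volume.pixel_spacing, volume.slice_spacing, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_mask(path: str | os.PathLike, format: str | None = None) -> MaskVolume:
    """Read a binary mask (NIfTI or archive)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        voxels, ps, ss = _read_nifti(path)
    elif fmt == "archive":
        voxels, ps, ss = _read_archive(path)
    else:
        raise ValueError(f"masks support nifti or archive, not {fmt!r}")
    return MaskVolume(np.rint(voxels).astype(np.uint8), ps, ss)


def write_mask(mask: MaskVolume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a binary mask as unsigned 8-bit, readable back by :func:`read_mask`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        _write_nifti(mask.voxels.astype(np.uint8), mask.pixel_spacing, mask.slice_spacing, path)
    elif fmt == "archive":
        _write_archive(mask.voxels.astype(np.uint8), mask.pixel_spacing, mask.slice_spacing, path)
    else:
        raise ValueError(f"masks support nifti or archive, not {fmt!r}")


def normalize_intensity(
    volume: CTVolume, low: float | None = None, high: float | None = None
) -> CTVolume:
    """Clip voxels to ``[low, high]`` and map affinely onto ``[0, 1]``.

    When no window is given the volume's own ``[min, max]`` is used, which
    preserves the full contrast of the input.  A constant volume maps to
    all zeros.  Geometry is unchanged.
    """
    explicit = low is not None or high is not None
    lo = float(volume.voxels.min()) if low is None else float(low)
    hi = float(volume.voxels.max()) if high is None else float(high)
    if lo >= hi:
        if explicit:
            raise ValueError(f"require low < high, got low={lo}, high={hi}")
        # degenerate constant volume under the default window
        return replace(volume, voxels=np.zeros_like(volume.voxels, dtype=np.float32))
    out = (np.clip(volume.voxels, lo, hi) - lo) / (hi - lo)
    return replace(volume, voxels=out.astype(np.float32))
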