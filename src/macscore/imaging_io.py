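"""Reading CT volumes and exposing calibrated Hounsfield-unit data.

Supported inputs are DICOM series directories, NIfTI files (``.nii`` /
``.nii.gz``) and NRRD files.  All volumes are normalised to a single
in-memory convention:

* voxel array axes are ``(z, y, x)`` — axis 0 indexes axial slices;
* voxel indices are 0-based;
* the world position of voxel ``(k, j, i)`` is
  ``origin + (k * slice_spacing, j * pixel_spacing[0], i * pixel_spacing[1])``
  in millimetres, ordered ``(z, y, x)``.

No resampling happens at load time: the calcium score depends on the
native slice thickness, so any resampling must be requested explicitly
(see :mod:`macscore.phantom.simulate_acquisition`).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Tube voltages (kVp) seen on clinical CT scanners.
KNOWN_TUBE_VOLTAGES = (70, 80, 90, 100, 120, 140)

#: Plausible Hounsfield-unit range for calibrated CT data.
HU_RANGE = (-1024.0, 4000.0)


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a CT volume."""


class SeriesInconsistencyError(VolumeFormatError):
    """Raised when slices of a DICOM series disagree on geometry."""


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with geometry metadata.

    Attributes
    ----------
    voxels:
        ``(z, y, x)`` float array of Hounsfield units.
    pixel_spacing:
        In-plane spacing ``(row mm, col mm)`` i.e. ``(dy, dx)``.
    slice_thickness:
        Nominal reconstructed slice thickness in mm.
    slice_spacing:
        Spacing between consecutive slice centres in mm.
    origin:
        World position of voxel ``(0, 0, 0)`` in mm, ordered ``(z, y, x)``.
    axial_axis:
        Array axis indexing axial slices (always 0 in this package).
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axial_axis: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.slice_thickness <= 0 or self.slice_spacing <= 0:
            raise ValueError("slice thickness/spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        lo, hi = HU_RANGE
        vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
        if vmin < lo - 1.0 or vmax > hi + 1.0:
            logger.warning(
                "HU values [%.0f, %.0f] outside the plausible range %s; "
                "check rescale calibration", vmin, vmax, HU_RANGE,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel in mm²."""
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centres along each axis (z, y, x)."""
        nz, ny, nx = self.voxels.shape
        z = self.origin[0] + np.arange(nz) * self.slice_spacing
        y = self.origin[1] + np.arange(ny) * self.pixel_spacing[0]
        x = self.origin[2] + np.arange(nx) * self.pixel_spacing[1]
        return z, y, x

    def world_to_index(self, point_mm: Sequence[float]) -> tuple[float, float, float]:
        """Continuous voxel index of a world-mm point ``(z, y, x)``."""
        return (
            (point_mm[0] - self.origin[0]) / self.slice_spacing,
            (point_mm[1] - self.origin[1]) / self.pixel_spacing[0],
            (point_mm[2] - self.origin[2]) / self.pixel_spacing[1],
        )

    def contains_point(self, point_mm: Sequence[float]) -> bool:
        idx = self.world_to_index(point_mm)
        return all(-0.5 <= c <= n - 0.5 for c, n in zip(idx, self.voxels.shape))


@dataclass
class AcquisitionMeta:
    """Acquisition parameters relevant to score comparability.

    Missing header fields are explicit ``None`` values, never silently
    defaulted — paired-protocol comparisons need to know what is unknown.
    """

    tube_voltage: Optional[float] = None
    slice_thickness: Optional[float] = None
    pixel_spacing: Optional[tuple[float, float]] = None
    has_contrast: Optional[bool] = None
    source_id: str = ""
    missing_fields: list[str] = field(default_factory=list)


def _detect_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom"
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise VolumeFormatError(f"cannot infer volume format of {path!r}")


def load_volume(path: str, format_hint: Optional[str] = None) -> CTVolume:
    """Load a CT volume and convert it to calibrated Hounsfield units.

    Parameters
    ----------
    path:
        A NIfTI/NRRD file or a directory containing one DICOM series.
    format_hint:
        One of ``"dicom"``, ``"nifti"``, ``"nrrd"``; inferred from the
        path when omitted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format_hint or _detect_format(path)
    if fmt == "nifti":
        return _load_nifti(path)
    if fmt == "nrrd":
        return _load_nrrd(path)
    if fmt == "dicom":
        return _load_dicom_series(path)
    raise VolumeFormatError(f"unknown format {fmt!r}")


def _load_nifti(path: str) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several error types
        raise VolumeFormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise VolumeFormatError(f"expected 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) for axes (i, j, k)
    # nibabel axes are (i, j, k) = (x, y, z); canonicalise to (z, y, x)
    voxels = np.transpose(data, (2, 1, 0))
    t = img.affine[:3, 3]
    return CTVolume(
        voxels=voxels,
        pixel_spacing=(float(zooms[1]), float(zooms[0])),
        slice_thickness=float(zooms[2]),
        slice_spacing=float(zooms[2]),
        origin=(float(t[2]), float(t[1]), float(t[0])),
    )


def save_nifti(volume: CTVolume, path: str) -> None:
    """Write a volume as NIfTI (the package's canonical exchange format)."""
    import nibabel as nib

    data = np.transpose(volume.voxels, (2, 1, 0))
    dy, dx = volume.pixel_spacing
    dz = volume.slice_spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[0, 3] = volume.origin[2]
    affine[1, 3] = volume.origin[1]
    affine[2, 3] = volume.origin[0]
    nib.save(nib.Nifti1Image(data, affine), path)


def _load_nrrd(path: str) -> CTVolume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(path)
    except Exception as exc:
        raise VolumeFormatError(f"cannot read NRRD file {path!r}: {exc}") from exc
    voxels = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    if voxels.ndim != 3:
        raise VolumeFormatError(f"expected 3D NRRD, got shape {voxels.shape}")
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return CTVolume(
        voxels=voxels,
        pixel_spacing=(float(sy), float(sx)),
        slice_thickness=float(sz),
        slice_spacing=float(sz),
        origin=(float(oz), float(oy), float(ox)),
    )


def save_nrrd(volume: CTVolume, path: str) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing((volume.pixel_spacing[1], volume.pixel_spacing[0], volume.slice_spacing))
    img.SetOrigin((volume.origin[2], volume.origin[1], volume.origin[0]))
    sitk.WriteImage(img, path)


def _load_dicom_series(directory: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, notes)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise VolumeFormatError(f"no DICOM images found in {directory!r}")

    orientations = {tuple(round(float(v), 6) for v in ds.ImageOrientationPatient)
                    for ds in datasets if hasattr(ds, "ImageOrientationPatient")}
    if len(orientations) > 1:
        raise SeriesInconsistencyError(
            f"series mixes {len(orientations)} ImageOrientationPatient values"
        )

    if orientations:
        row_dir, col_dir = np.array(next(iter(orientations))).reshape(2, 3)
        normal = np.cross(row_dir, col_dir)
    else:
        normal = np.array([0.0, 0.0, 1.0])

    def slice_pos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=slice_pos)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    first = datasets[0]
    ps = getattr(first, "PixelSpacing", None)
    if ps is None:
        raise VolumeFormatError("DICOM series lacks PixelSpacing")
    pixel_spacing = (float(ps[0]), float(ps[1]))

    positions = [slice_pos(ds) for ds in datasets]
    if len(positions) > 1:
        deltas = np.diff(positions)
        slice_spacing = float(np.median(deltas))
        if slice_spacing <= 0 or np.ptp(deltas) > 0.01 * abs(slice_spacing):
            raise SeriesInconsistencyError("irregular DICOM slice positions")
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))
    thickness = float(getattr(first, "SliceThickness", slice_spacing))

    if hasattr(first, "ImagePositionPatient"):
        p = np.asarray(first.ImagePositionPatient, float)
        origin = (float(np.dot(p, normal)), float(p[1]), float(p[0]))
    else:
        origin = (0.0, 0.0, 0.0)

    return CTVolume(
        voxels=voxels,
        pixel_spacing=pixel_spacing,
        slice_thickness=thickness,
        slice_spacing=slice_spacing,
        origin=origin,
    )


def volume_metadata(volume: CTVolume, headers: Mapping[str, object]) -> AcquisitionMeta:
    """Extract the acquisition metadata used in paired-protocol reports.

    ``headers`` is a flat mapping of DICOM-style keyword → value (``KVP``,
    ``SliceThickness``, ``PixelSpacing``, ``ContrastBolusAgent``). Absent
    fields become ``None`` and are listed in ``missing_fields``.
    """
    missing: list[str] = []

    kvp = headers.get("KVP")
    if kvp is None:
        missing.append("KVP")
        logger.warning("tube voltage (KVP) absent from headers")
        tube_voltage = None
    else:
        tube_voltage = float(kvp)
        if int(tube_voltage) not in KNOWN_TUBE_VOLTAGES:
            logger.warning("unusual tube voltage %.0f kVp", tube_voltage)

    st = headers.get("SliceThickness")
    if st is None:
        missing.append("SliceThickness")
        thickness = volume.slice_thickness
    else:
        thickness = float(st)

    ps = headers.get("PixelSpacing")
    if ps is None:
        missing.append("PixelSpacing")
        spacing: Optional[tuple[float, float]] = volume.pixel_spacing
    else:
        spacing = (float(ps[0]), float(ps[1]))  # type: ignore[index]

    contrast = headers.get("ContrastBolusAgent")
    has_contrast = None if contrast is None else bool(contrast)
    if contrast is None:
        missing.append("ContrastBolusAgent")

    return AcquisitionMeta(
        tube_voltage=tube_voltage,
        slice_thickness=thickness,
        pixel_spacing=spacing,
        has_contrast=has_contrast,
        source_id=str(headers.get("StationName", "")),
        missing_fields=missing,
    )
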