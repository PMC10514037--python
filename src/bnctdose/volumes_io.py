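"""Oriented 3-D image volumes, ROI rasterization and grid resampling.

All physical coordinates are in the DICOM LPS patient frame, in millimetres.
A voxel value sits at the voxel *center*; the center of voxel ``(i, j, k)``
is ``origin + direction @ (spacing * (i, j, k))``.  NIfTI files (which use
RAS) are converted on read/write.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk
from matplotlib.path import Path as PolygonPath

logger = logging.getLogger(__name__)

MODALITIES = ("CT", "PET", "DOSE", "MASK", "TNR")

#: sign flips taking RAS (NIfTI) coordinates to LPS (DICOM) and back.
_LPS_FROM_RAS = np.diag([-1.0, -1.0, 1.0])

WATER_DENSITY_G_CM3 = 1.0
#: (HU, g/cm3) anchors for the piecewise-linear density lookup: air, water, bone.
DEFAULT_HU_CALIBRATION = ((-1000.0, 0.00121), (0.0, 1.0), (1000.0, 1.85))


@dataclass
class ImageVolume:
    """A 3-D scalar grid with spacing, origin and orientation.

    Parameters
    ----------
    data:
        3-D array, indexed ``[i, j, k]`` along the three grid axes.  Units
        depend on ``modality``: HU for CT, raw intensity for PET, Gy/s or
        Gy-Eq/s for DOSE, dimensionless for MASK and TNR.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        LPS coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    direction:
        3x3 orthonormal matrix whose columns are the patient-space unit
        vectors of the grid axes.
    modality:
        One of ``CT, PET, DOSE, MASK, TNR``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)
    direction: np.ndarray = field(default=None)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.direction is None:
            self.direction = np.eye(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal within 1e-6")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to LPS mm."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map LPS mm points, shape (..., 3), to continuous voxel indices."""
        points = np.asarray(points, dtype=float)
        return ((points - self.origin) @ self.direction) / self.spacing

    def same_grid(self, other: "ImageVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned LPS bounding box over the eight corner voxel centers."""
        n = np.array(self.shape) - 1
        corners = np.array([[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])])
        pts = self.index_to_physical(corners)
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class RoiMask:
    """Boolean voxel mask aligned to a reference :class:`ImageVolume`."""

    mask: np.ndarray
    name: str
    voxel_volume_mm3: float
    voxel_mass_kg: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")
        if not self.mask.any():
            raise ValueError(f"empty ROI {self.name!r}: no voxel selected")
        if self.voxel_mass_kg <= 0:
            raise ValueError("voxel_mass_kg must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def density_from_hu(hu, calibration: Sequence[tuple[float, float]] = DEFAULT_HU_CALIBRATION):
    """Piecewise-linear HU -> mass density (g/cm3), clamped at the end anchors."""
    pts = sorted(calibration)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return np.interp(hu, xs, ys)


def voxel_mass_kg(voxel_volume_mm3: float, density_g_cm3: float = WATER_DENSITY_G_CM3) -> float:
    """Mass of one voxel in kg (volume mm3 x density g/cm3)."""
    return voxel_volume_mm3 * 1e-3 * density_g_cm3 * 1e-3


# -- file IO ---------------------------------------------------------------


def read_volume(path, kind: str, modality: str | None = None) -> ImageVolume:
    """Read an image volume from a NIfTI file or a DICOM series directory.

    For DICOM, slices are sorted along the slice normal, uniform slice
    spacing is enforced, and the rescale slope/intercept is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind == "nifti":
        return _read_nifti(path, modality or "CT")
    if kind == "dicom-series":
        return _read_dicom_series(path, modality)
    raise ValueError(f"unsupported kind {kind!r}; expected 'nifti' or 'dicom-series'")


def _read_nifti(path: Path, modality: str) -> ImageVolume:
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    lin = _LPS_FROM_RAS @ affine[:3, :3]
    origin = _LPS_FROM_RAS @ affine[:3, 3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate affine (zero-length axis)")
    direction = lin / spacing
    data = np.asarray(img.dataobj).astype(np.float64)
    return ImageVolume(data=data, spacing=spacing, origin=origin, direction=direction, modality=modality)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI; MASK volumes are stored as uint8."""
    lin = _LPS_FROM_RAS @ (vol.direction * vol.spacing)
    affine = np.eye(4)
    affine[:3, :3] = lin
    affine[:3, 3] = _LPS_FROM_RAS @ vol.origin
    data = vol.data.astype(np.uint8) if vol.modality == "MASK" else np.asarray(vol.data, dtype=np.float64)
    nib.save(nib.Nifti1Image(data, affine), str(path))


_DICOM_MODALITY = {"CT": "CT", "PT": "PET", "PET": "PET", "RTDOSE": "DOSE"}


def _read_dicom_series(path: Path, modality: str | None) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise ValueError(f"{path}: no DICOM files found")
    datasets = [(f, pydicom.dcmread(str(f))) for f in files]
    series_uids = {ds.SeriesInstanceUID for _, ds in datasets}
    if len(series_uids) != 1:
        raise ValueError(f"{path}: files belong to {len(series_uids)} different series")
    ds0 = datasets[0][1]
    dcm_modality = str(getattr(ds0, "Modality", ""))
    if dcm_modality not in _DICOM_MODALITY:
        raise ValueError(f"{path}: unsupported DICOM modality {dcm_modality!r}")
    if modality is None:
        modality = _DICOM_MODALITY[dcm_modality]

    iop = np.asarray(ds0.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]  # row_dir: along increasing column index
    normal = np.cross(row_dir, col_dir)
    order = sorted(datasets, key=lambda fd: float(np.dot(np.asarray(fd[1].ImagePositionPatient, float), normal)))
    positions = np.array([np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for _, ds in order])
    if len(order) < 2:
        raise ValueError(f"{path}: a DICOM series needs at least two slices")
    steps = np.diff(positions)
    slice_step = float(np.median(steps))
    bad = np.nonzero(np.abs(steps - slice_step) > 1e-3)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-uniform slice spacing at slice {order[bad[0] + 1][0].name} "
            f"(step {steps[bad[0]]:.4f} mm vs {slice_step:.4f} mm)"
        )

    planes = []
    for _, ds in order:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is [row, col]; volume axes are (col, row, slice).
    data = np.stack(planes, axis=-1).transpose(1, 0, 2)
    pixel_spacing = np.asarray(ds0.PixelSpacing, dtype=float)  # (row, col)
    spacing = np.array([pixel_spacing[1], pixel_spacing[0], abs(slice_step)])
    direction = np.column_stack([row_dir, col_dir, normal * np.sign(slice_step)])
    origin = np.asarray(order[0][1].ImagePositionPatient, dtype=float)
    return ImageVolume(data=data, spacing=spacing, origin=origin, direction=direction, modality=modality)


# -- ROI rasterization -----------------------------------------------------


def rasterize_roi(
    contours,
    reference: ImageVolume,
    name: str = "ROI",
    density_g_cm3: float = WATER_DENSITY_G_CM3,
) -> RoiMask:
    """Build an :class:`RoiMask` on the reference grid.

    ``contours`` may be a boolean array / MASK volume aligned to the
    reference, or an iterable of planar polygons given as (N, 3) arrays of
    LPS mm points (RT-STRUCT style, one polygon per slice).  A voxel belongs
    to the ROI iff its center lies inside a polygon on its slice (even-odd
    rule; no partial-voxel weighting).
    """
    if isinstance(contours, ImageVolume):
        contours = contours.data
    if isinstance(contours, np.ndarray) and contours.ndim == 3:
        if contours.shape != reference.shape:
            raise ValueError(f"mask shape {contours.shape} != reference shape {reference.shape}")
        mask = contours.astype(bool)
    else:
        mask = _rasterize_polygons(contours, reference)
    vol = reference.voxel_volume_mm3
    return RoiMask(mask=mask, name=name, voxel_volume_mm3=vol, voxel_mass_kg=voxel_mass_kg(vol, density_g_cm3))


def _rasterize_polygons(contours: Iterable[np.ndarray], reference: ImageVolume) -> np.ndarray:
    mask = np.zeros(reference.shape, dtype=bool)
    n_contours = 0
    for contour in contours:
        n_contours += 1
        pts = np.asarray(contour, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
            raise ValueError(f"contour {n_contours} must be an (N>=3, 3) point array")
        idx = reference.physical_to_index(pts)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        if np.any(hi < -0.5) or np.any(lo > np.array(reference.shape) - 0.5):
            raise ValueError(f"contour {n_contours} lies outside the reference extent")
        if np.ptp(idx[:, 2]) > 1e-3:
            raise ValueError(f"contour {n_contours} is not planar within a slice")
        k = int(round(float(idx[0, 2])))
        if not 0 <= k < reference.shape[2]:
            continue
        # NB: Path(..., closed=True) would treat the last vertex as the
        # CLOSEPOLY marker; a plain Path is implicitly closed for containment.
        poly = PolygonPath(idx[:, :2])
        i0 = max(int(np.floor(lo[0])), 0)
        i1 = min(int(np.ceil(hi[0])), reference.shape[0] - 1)
        j0 = max(int(np.floor(lo[1])), 0)
        j1 = min(int(np.ceil(hi[1])), reference.shape[1] - 1)
        ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
        centers = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
        inside = poly.contains_points(centers)
        mask[ii.ravel()[inside], jj.ravel()[inside], k] = True
    if n_contours == 0:
        raise ValueError("no contours supplied")
    if not mask.any():
        raise ValueError("empty ROI: contours enclose no voxel center")
    return mask


# -- resampling ------------------------------------------------------------


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.astype(np.float64).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(vol.direction.flatten()))
    return img


def resample_to(
    src: ImageVolume,
    reference: ImageVolume,
    rigid_transform: np.ndarray | None = None,
) -> ImageVolume:
    """Resample ``src`` onto the grid of ``reference`` by trilinear interpolation.

    Voxels of the reference grid falling outside the source extent are filled
    with 0; their count is logged.  ``rigid_transform`` is an optional 4x4
    homogeneous matrix mapping reference-frame points into the source frame
    (default identity, i.e. the two volumes share a patient frame).
    """
    if rigid_transform is None and src.same_grid(reference):
        return ImageVolume(src.data.copy(), reference.spacing, reference.origin,
                           reference.direction, modality=src.modality)
    lo_s, hi_s = src.physical_bounds()
    lo_r, hi_r = reference.physical_bounds()
    if np.any(hi_s < lo_r) or np.any(lo_s > hi_r):
        raise ValueError("source and reference volumes do not overlap in patient space")

    if rigid_transform is None:
        tf = sitk.Transform()
    else:
        rigid_transform = np.asarray(rigid_transform, dtype=float).reshape(4, 4)
        tf = sitk.AffineTransform(3)
        tf.SetMatrix(rigid_transform[:3, :3].flatten())
        tf.SetTranslation(rigid_transform[:3, 3])

    ref_img = _to_sitk(reference)
    out = sitk.Resample(_to_sitk(src), ref_img, tf, sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    data = sitk.GetArrayFromImage(out).transpose(2, 1, 0)

    ones = ImageVolume(np.ones(src.shape), src.spacing, src.origin, src.direction, modality=src.modality)
    cover = sitk.Resample(_to_sitk(ones), ref_img, tf, sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    outside = int((sitk.GetArrayFromImage(cover) < 1.0 - 1e-9).sum())
    if outside:
        logger.info("resample_to: %d reference voxels outside source extent filled with 0", outside)
    return ImageVolume(data=data, spacing=reference.spacing, origin=reference.origin,
                       direction=reference.direction, modality=src.modality)
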