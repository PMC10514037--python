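"""Synthetic CT/PET phantoms with known ground-truth TNR fields.

The generator emulates the clinical acquisition chain that makes
PET-derived boron maps imperfect: a ground-truth tracer distribution is
defined at CT resolution, blurred by an isotropic Gaussian PET point-spread
function, block-averaged down to a coarser PET grid (the PET/CT voxel-size
mismatch), and optionally corrupted with Poisson noise.  Block averaging is
mean-preserving, so total activity is conserved up to blur leakage at the
tumor boundary — which is exactly the partial-volume effect under study.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import gaussian_filter

from .suv_tnr import SuvContext, TnrMap, compute_suv_map, compute_tnr_map
from .volumes_io import ImageVolume, RoiMask, rasterize_roi, resample_to

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Geometry, truth field and acquisition parameters of one phantom.

    The default grids mirror a typical brain PET/CT mismatch: ~1 mm
    isotropic CT voxels versus ~5 x 5 x 3 mm PET voxels.  PET spacing is
    constrained to integer multiples of the CT spacing so that the
    downsampling is an exact block average.
    """

    ct_shape: tuple = (60, 60, 60)
    ct_spacing_mm: tuple = (1.0, 1.0, 1.0)
    pet_downsample: tuple = (5, 5, 3)  # CT voxels per PET voxel, per axis
    tumor_center_mm: tuple | None = None  # default: grid center
    tumor_radii_mm: tuple | float = 10.0
    #: truth TNR field inside the tumor: ("uniform", t) |
    #: ("gradient", lo, hi) along x | ("blob", peak, sigma_mm[, floor]) |
    #: ("bimodal", t_low, t_high) split by the mid-sagittal plane
    tnr_field: tuple = ("uniform", 2.5)
    psf_fwhm_mm: float = 5.0
    poisson_noise_scale: float | None = None  # expected counts per unit intensity
    seed: int = 0
    baseline_suv: float = 1.0
    normal_box_index: tuple = ((4, 4, 22), (14, 14, 38))  # half-open index ranges
    injected_dose_bq: float = 3.7e8
    body_weight_kg: float = 70.0

    def __post_init__(self) -> None:
        self.ct_shape = tuple(int(n) for n in self.ct_shape)
        self.ct_spacing_mm = tuple(float(s) for s in self.ct_spacing_mm)
        self.pet_downsample = tuple(int(f) for f in self.pet_downsample)
        if any(f < 1 for f in self.pet_downsample):
            raise ValueError("pet_downsample factors must be >= 1")
        if any(n % f for n, f in zip(self.ct_shape, self.pet_downsample)):
            raise ValueError("ct_shape must be divisible by pet_downsample on every axis")
        if np.isscalar(self.tumor_radii_mm):
            self.tumor_radii_mm = (float(self.tumor_radii_mm),) * 3
        else:
            self.tumor_radii_mm = tuple(float(r) for r in self.tumor_radii_mm)
        if self.tumor_center_mm is None:
            self.tumor_center_mm = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.ct_shape, self.ct_spacing_mm)
            )
        else:
            self.tumor_center_mm = tuple(float(c) for c in self.tumor_center_mm)


@dataclass
class Phantom:
    """A generated phantom with its ground truth."""

    ct: ImageVolume
    pet: ImageVolume
    tumor: RoiMask
    normal: RoiMask
    truth_tnr: ImageVolume
    suv_context: SuvContext
    truth_summary: dict = field(default_factory=dict)


def _truth_tnr_field(spec: PhantomSpec, coords, inside: np.ndarray) -> np.ndarray:
    x = coords[0][:, None, None]
    cx, _, _ = spec.tumor_center_mm
    rx = spec.tumor_radii_mm[0]
    kind, *params = spec.tnr_field
    if kind == "uniform":
        (t,) = params
        tnr_in = np.full(spec.ct_shape, float(t))
    elif kind == "gradient":
        lo, hi = params
        ramp = lo + (hi - lo) * (x - (cx - rx)) / (2.0 * rx)
        tnr_in = np.broadcast_to(ramp, spec.ct_shape)
    elif kind == "blob":
        peak, sigma = params[0], params[1]
        floor = params[2] if len(params) > 2 else 1.0
        d2 = sum(
            ((c.reshape([-1 if a == i else 1 for a in range(3)]) - cc) ** 2)
            for i, (c, cc) in enumerate(zip(coords, spec.tumor_center_mm))
        )
        tnr_in = floor + (peak - floor) * np.exp(-d2 / (2.0 * sigma**2))
    elif kind == "bimodal":
        t_low, t_high = params
        tnr_in = np.where(np.broadcast_to(x, spec.ct_shape) < cx, t_low, t_high)
    else:
        raise ValueError(f"unknown truth TNR field kind {kind!r}")
    truth = np.ones(spec.ct_shape)
    truth[inside] = np.broadcast_to(tnr_in, spec.ct_shape)[inside]
    if np.any(truth < 0):
        raise ValueError("truth TNR field has negative values")
    return truth


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Generate CT, PET, ROI masks and the ground-truth TNR volume.

    The PET image is the truth activity (baseline SUV times TNR) after PSF
    blur, exact block-average downsampling, optional Poisson noise, and
    conversion to raw intensity consistent with the phantom's SUV metadata.
    Identical spec + seed reproduce the phantom bit for bit.
    """
    shape = spec.ct_shape
    spacing = np.asarray(spec.ct_spacing_mm)
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    extent = [(c[0], c[-1]) for c in coords]
    for c, r, (lo, hi) in zip(spec.tumor_center_mm, spec.tumor_radii_mm, extent):
        if c - r < lo or c + r > hi:
            raise ValueError("tumor extends outside the CT grid")

    d2 = sum(
        ((c.reshape([-1 if a == i else 1 for a in range(3)]) - cc) / rr) ** 2
        for i, (c, cc, rr) in enumerate(zip(coords, spec.tumor_center_mm, spec.tumor_radii_mm))
    )
    tumor_mask = d2 <= 1.0

    ct = ImageVolume(np.zeros(shape), spacing, modality="CT")  # water-equivalent HU
    truth = _truth_tnr_field(spec, coords, tumor_mask)
    truth_tnr = ImageVolume(truth, spacing, modality="TNR")

    activity = spec.baseline_suv * truth
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spacing
        activity = gaussian_filter(activity, sigma=sigma_vox, mode="nearest")
    f = spec.pet_downsample
    pet_data = activity.reshape(
        shape[0] // f[0], f[0], shape[1] // f[1], f[1], shape[2] // f[2], f[2]
    ).mean(axis=(1, 3, 5))
    if spec.poisson_noise_scale:
        rng = np.random.default_rng(spec.seed)
        scale = float(spec.poisson_noise_scale)
        pet_data = rng.poisson(np.clip(pet_data, 0, None) * scale) / scale

    ctx = SuvContext(spec.injected_dose_bq, spec.body_weight_kg)
    # raw intensity such that the SUV formula returns the activity field
    pet_data = pet_data * ctx.injected_dose_bq * ctx.decay_factor / ctx.body_weight_kg
    pet_spacing = spacing * f
    pet_origin = (np.asarray(f) - 1) / 2.0 * spacing
    pet = ImageVolume(pet_data, pet_spacing, origin=pet_origin, modality="PET")

    tumor = rasterize_roi(tumor_mask, ct, name="GTV")
    (i0, j0, k0), (i1, j1, k1) = spec.normal_box_index
    normal_mask = np.zeros(shape, dtype=bool)
    normal_mask[i0:i1, j0:j1, k0:k1] = True
    normal = rasterize_roi(normal_mask, ct, name="normal")

    tt = truth[tumor_mask]
    summary = {
        "tnr_mean": float(tt.mean()),
        "tnr_min": float(tt.min()),
        "tnr_max": float(tt.max()),
        "n_tumor_voxels": int(tumor_mask.sum()),
    }
    return Phantom(ct=ct, pet=pet, tumor=tumor, normal=normal, truth_tnr=truth_tnr,
                   suv_context=ctx, truth_summary=summary)


def recover_tnr(phantom: Phantom) -> TnrMap:
    """Run the PET-to-TNR measurement chain on a phantom.

    Resamples the PET image onto the CT grid, converts to SUV and divides by
    the normal-ROI mean — the quantity a planning system would extract.
    Comparing its ROI statistics against ``truth_summary`` isolates the
    partial-volume error of the acquisition chain.
    """
    pet_on_ct = resample_to(phantom.pet, phantom.ct)
    suv = compute_suv_map(pet_on_ct, phantom.suv_context)
    return compute_tnr_map(suv, phantom.tumor, phantom.normal)


def write_synthetic_dicom_series(
    directory,
    data: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    origin_mm=(0.0, 0.0, 0.0),
    rescale_slope: float = 1.0,
    rescale_intercept: float = 0.0,
    slice_offsets_mm: np.ndarray | None = None,
) -> Path:
    """Write a minimal synthetic CT DICOM series for I/O round-trip tests.

    ``data`` is an integer-valued ``[i, j, k]`` array; stored pixels are
    ``(data - intercept) / slope``.  ``slice_offsets_mm`` optionally perturbs
    individual slice positions (to fabricate a non-uniform series).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("data must be 3-D")
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    offsets = np.zeros(data.shape[2]) if slice_offsets_mm is None else np.asarray(slice_offsets_mm)

    for k in range(data.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "SYN000"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(origin_mm[0]), float(origin_mm[1]),
            float(origin_mm[2] + k * spacing_mm[2] + offsets[k]),
        ]
        ds.PixelSpacing = [float(spacing_mm[1]), float(spacing_mm[0])]  # row, col
        ds.SliceThickness = float(spacing_mm[2])
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.Rows, ds.Columns = data.shape[1], data.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.round((data[:, :, k].T - rescale_intercept) / rescale_slope)
        ds.PixelData = stored.astype(np.int16).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(str(directory / f"slice_{k:03d}.dcm"), ds,
                         enforce_file_format=True)
    return directory
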