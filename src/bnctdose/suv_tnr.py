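"""Standardized uptake value (SUV) and tumor-to-normal ratio (TNR) maps.

The per-voxel SUV is computed from attenuation-corrected PET intensities,

    SUV(V) = intensity(V) * ACF * body_weight / (injected_dose * 2**(-dt/T)),

with ``dt`` the signed measurement-minus-scan time in minutes and ``T`` the
tracer half-life (F-18 by default).  The TNR of a tumor voxel is its SUV
divided by the mean SUV of a user-chosen normal-tissue ROI; the ROI-mean TNR
therefore equals the classical SUV_mean,tumor / SUV_mean,normal ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .volumes_io import ImageVolume, RoiMask

F18_HALF_LIFE_MIN = 109.771


@dataclass
class SuvContext:
    """PET acquisition metadata required for SUV computation.

    ``delta_minutes`` is the signed (measurement time - scan time) interval;
    it may be given directly or derived from timestamps via
    :meth:`from_times`.  ``acf`` is the attenuation correction factor, a
    scalar (1.0 for data already corrected at reconstruction) or a per-voxel
    map.
    """

    injected_dose_bq: float
    body_weight_kg: float
    delta_minutes: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN
    acf: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0:
            raise ValueError("injected_dose_bq must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")

    @classmethod
    def from_times(
        cls,
        injected_dose_bq: float,
        body_weight_kg: float,
        measurement_time: datetime,
        scan_time: datetime,
        **kwargs,
    ) -> "SuvContext":
        dt = (measurement_time - scan_time).total_seconds() / 60.0
        return cls(injected_dose_bq, body_weight_kg, delta_minutes=dt, **kwargs)

    @property
    def decay_factor(self) -> float:
        """2**(-dt / half_life): residual activity fraction at measurement."""
        return float(2.0 ** (-self.delta_minutes / self.half_life_min))


@dataclass
class TnrMap:
    """Per-voxel TNR over a tumor ROI, with its normal-tissue baseline."""

    volume: ImageVolume  # TNR on the full reference grid, 0 outside the ROI
    mask: RoiMask
    values: np.ndarray  # 1-D, ROI voxels in C order
    baseline_suv_mean: float
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.baseline_suv_mean <= 0:
            raise ValueError("baseline_suv_mean must be positive")
        if np.any(self.values < 0):
            raise ValueError("TNR values must be non-negative")
        if not self.summary:
            self.summary = {
                "min": float(self.values.min()),
                "max": float(self.values.max()),
                "mean": float(self.values.mean()),
            }
        if abs(self.summary["mean"] - self.values.mean()) > 1e-9:
            raise ValueError("summary mean inconsistent with values")


def compute_suv_map(pet: ImageVolume, ctx: SuvContext) -> ImageVolume:
    """Per-voxel SUV (kg/ml) from PET intensity and acquisition metadata."""
    suv = pet.data * np.asarray(ctx.acf) * ctx.body_weight_kg / (ctx.injected_dose_bq * ctx.decay_factor)
    return ImageVolume(suv, pet.spacing, pet.origin, pet.direction, modality="PET")


def suv_mean(suv: ImageVolume, roi: RoiMask) -> float:
    """Unweighted arithmetic mean SUV over the ROI voxels."""
    if suv.shape != roi.mask.shape:
        raise ValueError("SUV volume and ROI mask are on different grids")
    if not roi.mask.any():
        raise ValueError(f"empty ROI {roi.name!r}")
    return float(suv.data[roi.mask].mean())


def compute_tnr_map(suv: ImageVolume, tumor: RoiMask, normal: RoiMask) -> TnrMap:
    """Per-voxel TNR over the tumor ROI: SUV(V) / SUV_mean(normal)."""
    baseline = suv_mean(suv, normal)
    if baseline <= 0:
        raise ValueError("normal-tissue mean SUV must be positive")
    values = suv.data[tumor.mask] / baseline
    grid = np.zeros(suv.shape)
    grid[tumor.mask] = values
    volume = ImageVolume(grid, suv.spacing, suv.origin, suv.direction, modality="TNR")
    return TnrMap(volume=volume, mask=tumor, values=values, baseline_suv_mean=baseline)


def tnr_histogram(tnr: TnrMap, n_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of TNR values plus the cumulative volume fraction >= TNR.

    Returns ``(edges, counts, cum_fraction)`` with ``len(edges) == n_bins+1``;
    ``cum_fraction[j]`` is the fraction of ROI voxels falling in bins ``j``
    and above, so it starts at exactly 1 and ends at exactly 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = tnr.values
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        hi = lo + max(abs(lo), 1.0) * 1e-9  # single-valued: one occupied bin
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    suffix = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    return edges, counts, suffix / values.size
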