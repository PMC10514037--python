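"""Groupwise quantization of per-voxel boron concentration with atom conservation.

A dose engine cannot carry one material per voxel, so the per-voxel boron
signal (SUV, or equivalently TNR after baseline normalization) is quantized
into ``I`` evenly spaced groups between the ROI minimum and maximum.  The
group midpoints are

    mid_i = (upper - lower) / I * (i - 0.5) + lower,      i = 1..I,

and a voxel's group index is ``ceil(I * (v - lower) / (upper - lower))``,
clamped to [1, I] (the lower bound itself would otherwise yield index 0).
Quantization slightly changes the total boron content, so a normalization
factor

    k = sum_V v(V) / sum_i N_i * mid_i

restores exact conservation: the grouped per-voxel atom count
``xi * k * mid_{i(V)}`` sums to the exact total ``xi * sum_V v(V)``.

``xi`` converts the (dimensionless) TNR-scaled signal to boron-10 atoms per
voxel.  It is anchored to a prescribed blood boron-10 concentration: a voxel
at TNR 1 carries the blood level, so its boron-10 mass is
``blood_ppm * 1e-6 * voxel_mass``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

B10_ATOMIC_MASS_U = 10.0129
ATOMIC_MASS_UNIT_KG = 1.66053906892e-27
B10_MASS_KG = B10_ATOMIC_MASS_U * ATOMIC_MASS_UNIT_KG


@dataclass
class BoronGrouping:
    """Result of groupwise quantization over one ROI."""

    n_groups: int
    suv_lower: float
    suv_upper: float
    midpoints: np.ndarray  # (I,) group concentration values
    group_index: np.ndarray  # per-voxel, 1-based, in [1, I]
    counts: np.ndarray  # (I,) voxels per group
    k: float  # conservation normalization factor
    xi: float | None = None  # boron-10 atoms per unit signal per voxel

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.group_index = np.asarray(self.group_index, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.k <= 0:
            raise ValueError("normalization factor k must be positive")
        if int(self.counts.sum()) != self.group_index.size:
            raise ValueError("group counts do not sum to the voxel count")

    def to_dict(self) -> dict:
        return {
            "n_groups": int(self.n_groups),
            "suv_lower": float(self.suv_lower),
            "suv_upper": float(self.suv_upper),
            "k": float(self.k),
            "xi": None if self.xi is None else float(self.xi),
            "midpoints": self.midpoints.tolist(),
            "counts": self.counts.tolist(),
        }


@dataclass
class BoronMap:
    """Per-voxel boron-10 atom counts, exact and grouped."""

    n_b10_exact: np.ndarray
    n_b10_grouped: np.ndarray
    blood_b10_ppm: float

    def __post_init__(self) -> None:
        if np.any(self.n_b10_exact < 0) or np.any(self.n_b10_grouped < 0):
            raise ValueError("atom counts must be non-negative")


def groupwise(values: np.ndarray, n_groups: int) -> BoronGrouping:
    """Quantize ``values`` into ``n_groups`` even bins with conservation factor k.

    A degenerate ROI (all values equal) collapses to a single group at that
    value with k = 1.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("at least one voxel is required")
    lower, upper = float(values.min()), float(values.max())

    if upper == lower:
        midpoints = np.array([lower])
        index = np.ones(values.size, dtype=int)
        counts = np.array([values.size])
        return BoronGrouping(1, lower, upper, midpoints, index, counts, k=1.0)

    i = np.arange(1, n_groups + 1)
    midpoints = (upper - lower) / n_groups * (i - 0.5) + lower
    index = np.ceil(n_groups * (values - lower) / (upper - lower)).astype(int)
    np.clip(index, 1, n_groups, out=index)
    counts = np.bincount(index, minlength=n_groups + 1)[1:]
    k = float(values.sum() / np.dot(counts, midpoints))
    return BoronGrouping(n_groups, lower, upper, midpoints, index, counts, k=k)


def calibrate_xi(blood_b10_ppm: float, voxel_mass_kg: float) -> float:
    """Boron-10 atoms per voxel per unit TNR.

    A voxel at TNR t carries a boron-10 mass fraction ``blood_b10_ppm * t *
    1e-6`` of its mass, i.e. ``xi * t`` atoms with
    ``xi = blood_ppm * 1e-6 * voxel_mass / m(B-10)``.
    """
    if blood_b10_ppm < 0:
        raise ValueError("blood_b10_ppm must be non-negative")
    if voxel_mass_kg <= 0:
        raise ValueError("voxel_mass_kg must be positive")
    return blood_b10_ppm * 1e-6 * voxel_mass_kg / B10_MASS_KG


def exact_atoms(grouping: BoronGrouping, values: np.ndarray) -> np.ndarray:
    """Per-voxel boron-10 atoms from the original signal: N(V) = xi * v(V)."""
    if grouping.xi is None:
        raise ValueError("xi is not calibrated; call calibrate_xi first")
    return grouping.xi * np.asarray(values, dtype=float)


def assign_grouped_atoms(grouping: BoronGrouping) -> np.ndarray:
    """Per-voxel boron-10 atoms from the grouped signal: xi * k * mid_{i(V)}."""
    if grouping.xi is None:
        raise ValueError("xi is not calibrated; call calibrate_xi first")
    return grouping.xi * grouping.k * grouping.midpoints[grouping.group_index - 1]


def boron_maps(grouping: BoronGrouping, values: np.ndarray, blood_b10_ppm: float) -> BoronMap:
    """Exact and grouped per-voxel atom counts for one ROI."""
    return BoronMap(
        n_b10_exact=exact_atoms(grouping, values),
        n_b10_grouped=assign_grouped_atoms(grouping),
        blood_b10_ppm=blood_b10_ppm,
    )


def material_count(m_kinds: int, n_groups: int) -> int:
    """Total number of materials a dose engine must carry: M x I."""
    if m_kinds < 1 or n_groups < 1:
        raise ValueError("material kinds and group count must be >= 1")
    return m_kinds * n_groups
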