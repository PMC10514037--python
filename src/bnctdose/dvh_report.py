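"""Dose-volume histograms, dose statistics and homo-vs-hetero comparison tables.

Statistics follow radiotherapy reporting conventions: Dmax/Dmin are
single-voxel extrema, Dmean the unweighted ROI mean, and D80 the dose rate
covering 80 % of the ROI volume, obtained by linear interpolation on the
descending-sorted voxel doses at rank 0.8 N.  Reported rates are in
cGy-Eq/s; internal fields stay in SI (Gy-Eq/s).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_engine import DoseField
from .volumes_io import ImageVolume, RoiMask

GY_TO_CGY = 100.0


@dataclass
class DvhResult:
    """Cumulative DVH curve plus the four summary statistics (Gy-Eq/s)."""

    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    d_max: float
    d_min: float
    d_mean: float
    d_80: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("DVH volume fraction must be non-increasing")
        if not (self.d_min - 1e-12 <= self.d_80 <= self.d_max + 1e-12):
            raise ValueError("D80 outside [Dmin, Dmax]")
        if not (self.d_min - 1e-12 <= self.d_mean <= self.d_max + 1e-12):
            raise ValueError("Dmean outside [Dmin, Dmax]")

    @property
    def stats(self) -> dict:
        return {"d_max": self.d_max, "d_min": self.d_min, "d_mean": self.d_mean, "d_80": self.d_80}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy_eq_s": self.dose_axis, "volume_fraction": self.volume_fraction})


@dataclass
class MethodResult:
    """One dose-calculation mode bundled for comparison."""

    dose: DoseField
    dvh: DvhResult
    tnr: np.ndarray  # full-grid TNR used by this mode


def coverage_dose(doses: np.ndarray, coverage: float) -> float:
    """Dose covering ``coverage`` of the volume (rank-interpolated, bin-free)."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    ordered = np.sort(np.asarray(doses, dtype=float))[::-1]
    ranks = np.arange(1, ordered.size + 1, dtype=float)
    return float(np.interp(coverage * ordered.size, ranks, ordered))


def compute_dvh(dose, roi: RoiMask, n_bins: int = 200) -> DvhResult:
    """Cumulative DVH over the ROI voxels (equal voxel volumes).

    ``dose`` is a per-voxel array (Gy-Eq/s) or a :class:`DoseField`, whose
    weighted total is then used.
    """
    if isinstance(dose, DoseField):
        dose = dose.d_bnct
    dose = np.asarray(dose, dtype=float)
    if dose.shape != roi.mask.shape:
        raise ValueError("dose grid does not match the ROI mask")
    if not roi.mask.any():
        raise ValueError(f"empty ROI {roi.name!r}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = dose[roi.mask]
    top = float(values.max())
    axis = np.linspace(0.0, top if top > 0 else 1.0, n_bins + 1)
    fraction = (values[None, :] >= axis[:, None]).mean(axis=1)
    fraction[0] = 1.0  # dose >= 0 by construction
    return DvhResult(
        dose_axis=axis,
        volume_fraction=fraction,
        d_max=top,
        d_min=float(values.min()),
        d_mean=float(values.mean()),
        d_80=coverage_dose(values, 0.80),
    )


def percent_difference(homo: float, hetero: float) -> float:
    """Difference convention of the comparison tables: 100 (hetero-homo)/homo."""
    return 100.0 * (hetero - homo) / homo


def component_fractions(d_b: float, d_n: float, d_p: float) -> tuple[float, float, float]:
    """Percentages of each weighted component against their sum."""
    total = d_b + d_n + d_p
    if total <= 0:
        raise ValueError("component sum must be positive")
    return tuple(100.0 * c / total for c in (d_b, d_n, d_p))


_STAT_NAMES = ("d_max", "d_min", "d_mean", "d_80")


def _components_at(method: MethodResult, flat_index: int) -> dict:
    db, dn, dp = (c.ravel()[flat_index] * GY_TO_CGY for c in method.dose.weighted_components())
    pb, pn, pp = component_fractions(db, dn, dp)
    return {
        "tnr": float(method.tnr.ravel()[flat_index]),
        "d_b_cgy_eq_s": float(db), "d_n_cgy_eq_s": float(dn), "d_p_cgy_eq_s": float(dp),
        "d_b_pct": pb, "d_n_pct": pn, "d_p_pct": pp,
    }


def compare_methods(
    homo: MethodResult,
    hetero: MethodResult,
    roi: RoiMask,
    roi_name: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dose-statistic and component-breakdown comparison tables.

    Returns ``(stats, components)``.  ``stats`` has one row per method with
    Dmax/Dmin/Dmean/D80 in cGy-Eq/s plus a ``difference_pct`` row,
    ``100 (hetero - homo) / homo`` per statistic.  ``components`` reports
    TNR and the weighted dose components (with percentages of their sum) at
    the maximum- and minimum-dose voxel of each method, plus difference rows.
    """
    name = roi_name or roi.name
    for m in (homo, hetero):
        if m.dose.d_phy_b10.shape != roi.mask.shape:
            raise ValueError("dose field grid does not match the ROI mask")

    rows = []
    for method, res in (("homo", homo), ("hetero", hetero)):
        rows.append({"roi": name, "method": method,
                     **{s: res.dvh.stats[s] * GY_TO_CGY for s in _STAT_NAMES}})
    diff = {"roi": name, "method": "difference_pct"}
    for s in _STAT_NAMES:
        diff[s] = percent_difference(homo.dvh.stats[s], hetero.dvh.stats[s])
    stats = pd.DataFrame(rows + [diff])

    comp_rows = []
    flat = {m: res.dose.d_bnct.copy() for m, res in (("homo", homo), ("hetero", hetero))}
    outside = ~roi.mask
    for category, pick in (("d_max", np.nanargmax), ("d_min", np.nanargmin)):
        per_method = {}
        for method, res in (("homo", homo), ("hetero", hetero)):
            masked = flat[method]
            masked = np.where(outside, np.nan, masked)
            idx = int(pick(masked))
            per_method[method] = _components_at(res, idx)
            comp_rows.append({"roi": name, "dose_category": category, "method": method,
                              **per_method[method]})
        d = {"roi": name, "dose_category": category, "method": "difference_pct"}
        for key in ("tnr", "d_b_cgy_eq_s", "d_n_cgy_eq_s", "d_p_cgy_eq_s"):
            d[key] = percent_difference(per_method["homo"][key], per_method["hetero"][key])
        comp_rows.append(d)
    return stats, pd.DataFrame(comp_rows)


def dose_slice(
    dose: DoseField,
    axis: str,
    index: int,
    kind: str = "bioequivalent",
    geometry: ImageVolume | None = None,
) -> tuple[np.ndarray, dict]:
    """Extract a 2-D dose plane for display.

    ``kind='bioequivalent'`` returns the weighted total (Gy-Eq/s);
    ``kind='physical'`` the unweighted component sum (Gy/s).  The metadata
    dict carries the in-plane axes and, when a geometry is given, the
    physical extent in mm.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    if kind == "bioequivalent":
        grid = dose.d_bnct
    elif kind == "physical":
        grid = dose.d_physical_total
    else:
        raise ValueError("kind must be 'bioequivalent' or 'physical'")
    if not 0 <= index < grid.shape[ax]:
        raise IndexError(f"slice index {index} out of range for axis {axis}")
    plane = np.take(grid, index, axis=ax)
    in_plane = [a for a in "xyz" if a != axis]
    meta = {"axis": axis, "index": index, "kind": kind, "plane_axes": in_plane}
    if geometry is not None:
        axes = [i for i in range(3) if i != ax]
        meta["extent_mm"] = [
            0.0, float(geometry.spacing[axes[0]] * grid.shape[axes[0]]),
            0.0, float(geometry.spacing[axes[1]] * grid.shape[axes[1]]),
        ]
    return plane, meta
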