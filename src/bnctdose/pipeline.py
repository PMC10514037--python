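"""End-to-end orchestration: phantom or real inputs -> SUV/TNR -> grouping ->
homo/hetero dose -> DVH and comparison reports.

Every stage reads and writes plain artifacts (NIfTI, CSV, JSON) in one
output directory, so runs are resumable, auditable and reproducible from the
serialized effective configuration.  The homogeneous-boron mode assigns
every tumor voxel the ROI-mean TNR; the heterogeneous mode transports with
the grouped boron map and scores dose with the exact per-voxel map.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boron_grouping as bg
from . import dose_engine as de
from . import dvh_report as dvh
from . import suv_tnr as st
from . import volumes_io as vio
from .phantom_gen import Phantom, PhantomSpec, build_phantom

logger = logging.getLogger(__name__)

MODES = ("homo", "hetero")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run.

    Defaults follow common BNCT practice: 50 concentration groups, CBE 3.8
    for tumor with BPA, RBE 3.2 (neutron) and 1.0 (photon), and a 25 ppm
    blood boron-10 level anchoring the TNR-to-atoms conversion.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    inputs: dict | None = None  # optional paths overriding phantom artifacts
    roi_name: str = "GTV"
    n_groups: int = 50
    blood_b10_ppm: float = 25.0
    density_g_cm3: float = 1.0
    weights: de.RadiobiologyWeights = field(default_factory=de.RadiobiologyWeights)
    beam: de.BeamConfig = field(default_factory=de.BeamConfig)
    mode: str = "both"  # homo | hetero | both
    seed: int = 0
    hist_bins: int = 20
    dvh_bins: int = 200
    slice_axis: str = "y"

    def __post_init__(self) -> None:
        if self.mode not in ("homo", "hetero", "both"):
            raise ValueError("mode must be 'homo', 'hetero' or 'both'")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.blood_b10_ppm <= 0:
            raise ValueError("blood_b10_ppm must be positive")

    @property
    def modes(self) -> tuple[str, ...]:
        return MODES if self.mode == "both" else (self.mode,)

    # -- lossless serialization -------------------------------------------

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("ct_shape", "ct_spacing_mm", "pet_downsample", "tnr_field",
                        "tumor_radii_mm", "tumor_center_mm"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            if "normal_box_index" in ph:
                ph["normal_box_index"] = tuple(tuple(v) for v in ph["normal_box_index"])
            d["phantom"] = PhantomSpec(**ph)
        if "weights" in d and isinstance(d["weights"], dict):
            d["weights"] = de.RadiobiologyWeights(**d["weights"])
        if "beam" in d and isinstance(d["beam"], dict):
            d["beam"] = de.BeamConfig(**d["beam"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML-safe round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    """In-memory bundle of the main pipeline outputs."""

    config: RunConfig
    outdir: Path
    tnr: st.TnrMap
    grouping: bg.BoronGrouping
    methods: dict  # mode -> dvh.MethodResult
    stats: pd.DataFrame | None
    components: pd.DataFrame | None
    truth_summary: dict | None = None


# -- stage helpers ---------------------------------------------------------


def _path(config: RunConfig, outdir: Path, key: str, default_name: str) -> Path:
    if config.inputs and key in config.inputs:
        return Path(config.inputs[key])
    return outdir / default_name


def _read_mask(config: RunConfig, outdir: Path, key: str, default_name: str,
               reference: vio.ImageVolume, name: str) -> vio.RoiMask:
    vol = vio.read_volume(_path(config, outdir, key, default_name), "nifti", modality="MASK")
    return vio.rasterize_roi(vol.data > 0.5, reference, name=name,
                             density_g_cm3=config.density_g_cm3)


def _read_suv_context(path: Path) -> st.SuvContext:
    d = json.loads(Path(path).read_text())
    return st.SuvContext(**d)


# -- stages ----------------------------------------------------------------


def stage_phantom(config: RunConfig, outdir: Path) -> Phantom:
    """Generate the synthetic phantom and write its artifacts."""
    outdir.mkdir(parents=True, exist_ok=True)
    spec = replace(config.phantom, seed=config.seed)
    phantom = build_phantom(spec)
    vio.write_volume(phantom.ct, outdir / "ct.nii")
    vio.write_volume(phantom.pet, outdir / "pet.nii")
    for roi, fname in ((phantom.tumor, "tumor_mask.nii"), (phantom.normal, "normal_mask.nii")):
        mask_vol = vio.ImageVolume(roi.mask.astype(np.uint8), phantom.ct.spacing,
                                   phantom.ct.origin, phantom.ct.direction, modality="MASK")
        vio.write_volume(mask_vol, outdir / fname)
    vio.write_volume(phantom.truth_tnr, outdir / "truth_tnr.nii")
    ctx = phantom.suv_context
    (outdir / "suv_context.json").write_text(json.dumps({
        "injected_dose_bq": ctx.injected_dose_bq,
        "body_weight_kg": ctx.body_weight_kg,
        "delta_minutes": ctx.delta_minutes,
        "half_life_min": ctx.half_life_min,
        "acf": float(np.asarray(ctx.acf).mean()),
    }, indent=1))
    (outdir / "phantom_summary.json").write_text(json.dumps(phantom.truth_summary, indent=1))
    return phantom


def stage_suv(config: RunConfig, outdir: Path) -> st.TnrMap:
    """PET -> CT-grid SUV map -> per-voxel TNR map and histogram."""
    ct = vio.read_volume(_path(config, outdir, "ct", "ct.nii"), "nifti", modality="CT")
    pet = vio.read_volume(_path(config, outdir, "pet", "pet.nii"), "nifti", modality="PET")
    ctx = _read_suv_context(_path(config, outdir, "suv_context", "suv_context.json"))
    tumor = _read_mask(config, outdir, "tumor_mask", "tumor_mask.nii", ct, config.roi_name)
    normal = _read_mask(config, outdir, "normal_mask", "normal_mask.nii", ct, "normal")

    pet_on_ct = vio.resample_to(pet, ct)
    suv = st.compute_suv_map(pet_on_ct, ctx)
    tnr = st.compute_tnr_map(suv, tumor, normal)
    vio.write_volume(suv, outdir / "suv.nii")
    vio.write_volume(tnr.volume, outdir / "tnr.nii")

    edges, counts, cum = st.tnr_histogram(tnr, config.hist_bins)
    pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "count": counts, "cum_volume_fraction": cum[:-1],
    }).to_csv(outdir / "tnr_histogram.csv", index=False)
    (outdir / "tnr_summary.json").write_text(json.dumps(
        {**tnr.summary, "baseline_suv_mean": tnr.baseline_suv_mean}, indent=1))
    return tnr


def stage_group(config: RunConfig, outdir: Path) -> bg.BoronGrouping:
    """Groupwise quantization, xi calibration and per-voxel atom maps."""
    ct = vio.read_volume(_path(config, outdir, "ct", "ct.nii"), "nifti", modality="CT")
    tumor = _read_mask(config, outdir, "tumor_mask", "tumor_mask.nii", ct, config.roi_name)
    tnr_vol = vio.read_volume(outdir / "tnr.nii", "nifti", modality="TNR")
    values = tnr_vol.data[tumor.mask]

    grouping = bg.groupwise(values, config.n_groups)
    grouping.xi = bg.calibrate_xi(config.blood_b10_ppm, tumor.voxel_mass_kg)
    maps = bg.boron_maps(grouping, values, config.blood_b10_ppm)

    grids = {}
    for name, voxel_atoms in (
        ("atoms_exact", maps.n_b10_exact),
        ("atoms_grouped", maps.n_b10_grouped),
        ("atoms_homo", np.full(values.shape, grouping.xi * values.mean())),
    ):
        grid = np.zeros(ct.shape)
        grid[tumor.mask] = voxel_atoms
        grids[name] = grid
        vio.write_volume(vio.ImageVolume(grid, ct.spacing, ct.origin, ct.direction,
                                         modality="DOSE"), outdir / f"{name}.nii")
    report = grouping.to_dict()
    report["material_count"] = bg.material_count(1, grouping.n_groups)
    report["blood_b10_ppm"] = config.blood_b10_ppm
    report["total_atoms_exact"] = float(maps.n_b10_exact.sum())
    report["total_atoms_grouped"] = float(maps.n_b10_grouped.sum())
    (outdir / "grouping.json").write_text(json.dumps(report, indent=1))
    return grouping


def stage_dose(config: RunConfig, outdir: Path) -> dict:
    """Run the flux engine and score dose components for each mode."""
    ct = vio.read_volume(_path(config, outdir, "ct", "ct.nii"), "nifti", modality="CT")
    tumor = _read_mask(config, outdir, "tumor_mask", "tumor_mask.nii", ct, config.roi_name)
    atoms = {
        name: vio.read_volume(outdir / f"atoms_{name}.nii", "nifti", modality="DOSE").data
        for name in ("exact", "grouped", "homo")
    }
    fields = {}
    for mode in config.modes:
        transport = atoms["homo"] if mode == "homo" else atoms["grouped"]
        score = atoms["homo"] if mode == "homo" else atoms["exact"]
        f = de.compute_dose_field(transport, score, ct, config.beam, config.weights,
                                  tumor.voxel_mass_kg)
        fields[mode] = f
        for comp, grid in (("b10", f.d_phy_b10), ("n", f.d_phy_n), ("p", f.d_phy_p),
                           ("total", f.d_bnct)):
            vio.write_volume(vio.ImageVolume(grid, ct.spacing, ct.origin, ct.direction,
                                             modality="DOSE"),
                             outdir / f"dose_{mode}_{comp}.nii")
    return fields


def stage_report(config: RunConfig, outdir: Path) -> dict:
    """DVHs, comparison tables, dose slices and the run log."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ct = vio.read_volume(_path(config, outdir, "ct", "ct.nii"), "nifti", modality="CT")
    tumor = _read_mask(config, outdir, "tumor_mask", "tumor_mask.nii", ct, config.roi_name)
    tnr_vol = vio.read_volume(outdir / "tnr.nii", "nifti", modality="TNR")
    weights = config.weights

    methods: dict[str, dvh.MethodResult] = {}
    for mode in config.modes:
        comps = {c: vio.read_volume(outdir / f"dose_{mode}_{c}.nii", "nifti",
                                    modality="DOSE").data for c in ("b10", "n", "p")}
        f = de.DoseField(d_phy_b10=comps["b10"], d_phy_n=comps["n"], d_phy_p=comps["p"],
                         weights=weights, e_cap_j=config.beam.e_cap_j)
        curve = dvh.compute_dvh(f, tumor, n_bins=config.dvh_bins)
        curve.to_dataframe().to_csv(outdir / f"dvh_{mode}.csv", index=False)
        if mode == "homo":
            tnr_grid = np.zeros(ct.shape)
            tnr_grid[tumor.mask] = tnr_vol.data[tumor.mask].mean()
        else:
            tnr_grid = tnr_vol.data
        methods[mode] = dvh.MethodResult(dose=f, dvh=curve, tnr=tnr_grid)

    stats = components = None
    if set(MODES) <= set(methods):
        stats, components = dvh.compare_methods(methods["homo"], methods["hetero"],
                                                tumor, roi_name=config.roi_name)
        stats.to_csv(outdir / "comparison_stats.csv", index=False)
        components.to_csv(outdir / "comparison_components.csv", index=False)

    mid = ct.shape[{"x": 0, "y": 1, "z": 2}[config.slice_axis]] // 2
    for mode, method in methods.items():
        for kind in ("bioequivalent", "physical"):
            plane, meta = dvh.dose_slice(method.dose, config.slice_axis, mid, kind, geometry=ct)
            fig, axp = plt.subplots(figsize=(4, 4))
            im = axp.imshow(plane.T * dvh.GY_TO_CGY, origin="lower",
                            extent=meta.get("extent_mm"), cmap="inferno")
            unit = "cGy-Eq/s" if kind == "bioequivalent" else "cGy/s"
            fig.colorbar(im, ax=axp, label=f"{kind} dose rate ({unit})")
            axp.set_xlabel(f"{meta['plane_axes'][0]} (mm)")
            axp.set_ylabel(f"{meta['plane_axes'][1]} (mm)")
            axp.set_title(f"{mode}, slice {config.slice_axis}={mid}")
            fig.savefig(outdir / f"slice_{mode}_{kind}.png", dpi=110)
            plt.close(fig)
            vio.write_volume(
                vio.ImageVolume(plane[:, :, None], np.append(np.delete(ct.spacing, 1), 1.0),
                                modality="DOSE"),
                outdir / f"slice_{mode}_{kind}.nii")

    log = {
        "config": config.to_dict(),
        "roi_voxels": tumor.n_voxels,
        "voxel_mass_kg": tumor.voxel_mass_kg,
        "modes": list(methods),
        "stats_cgy_eq_s": None if stats is None else stats.to_dict(orient="records"),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return methods


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Run every stage in order and return the assembled results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")

    truth_summary = None
    stages = []
    if config.inputs is None:
        stages.append(("phantom", stage_phantom))
    stages += [("suv", stage_suv), ("group", stage_group),
               ("dose", stage_dose), ("report", stage_report)]
    results = {}
    for name, fn in stages:
        try:
            results[name] = fn(config, outdir)
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    if "phantom" in results:
        truth_summary = results["phantom"].truth_summary

    methods = results["report"]
    stats = components = None
    if (outdir / "comparison_stats.csv").exists():
        stats = pd.read_csv(outdir / "comparison_stats.csv")
        components = pd.read_csv(outdir / "comparison_components.csv")
    return PipelineResult(config=config, outdir=outdir, tnr=results["suv"],
                          grouping=results["group"], methods=methods,
                          stats=stats, components=components, truth_summary=truth_summary)
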