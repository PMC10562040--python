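"""End-to-end study pipeline: generate -> calibrate -> segment -> map ->
dose -> evaluate, with reports and provenance.

The pipeline runs the whole synthetic study deterministically from one
seed: simulate per-insert VM/SECT CT numbers and a labeled phantom, fit
all energy pairs and build the optimal-pair lookup table, threshold-
segment the phantom and build spectral and SECT SPR maps, plan and compute
proton dose on both maps under identical settings, and compare dose
(gamma, relative difference) and R90 ranges per beam.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .evaluation import GammaResult, gamma_index, relative_dose_difference
from .proton_dose import (
    BeamSpec,
    DoseGrid,
    PTVSphere,
    central_axis_profile,
    compute_dose,
    plan_beam,
    r90_range,
    range_comparison,
    _sphere_mask,
)
from .segmentation_spr import (
    SPRMap,
    build_sect_spr_map,
    build_spr_map,
    match_regions,
    threshold_segment,
)
from .spectral_calibration import (
    OptimalPairLUT,
    evaluate_all_pairs,
    find_optimal_pairs,
    group_rmse,
    percent_deviation,
    residual_surface,
    sect_calibrate,
    sect_convert,
)
from .tissue_library import load_gammex_library
from .vm_forward_model import (
    DEFAULT_VM_ENERGIES,
    pediatric_phantom_spec,
    rasterize_phantom,
    simulate_sect_hu,
    vm_means_table,
    write_phantom,
)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "run_pipeline"]

#: Tissues whose anchors define the default segmentation thresholds
#: (midpoints of adjacent anchor CT numbers).
ANCHOR_TISSUES = ("LN-300 lung", "HE Blood 40", "HE Blood 100", "50% CaCO3")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage; partial outputs are retained."""


class PipelineConfig(BaseModel):
    """Configuration of the synthetic end-to-end study."""

    seed: int = 1
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd_hu: float = 10.0
    vm_energies: tuple[float, ...] = DEFAULT_VM_ENERGIES
    thresholds_hu: Optional[tuple[float, ...]] = None  # None -> anchor midpoints
    gantry_angles_deg: tuple[float, ...] = (-45.0, 45.0)
    prescription_gy: float = 60.0
    fractions: int = 30
    rbe: float = 1.1
    sigma_lat_mm: float = 5.0
    energy_step_mev: float = 1.0
    gamma_criteria: tuple[tuple[float, float], ...] = ((2.0, 2.0), (1.0, 1.0))
    low_dose_cutoff_pct: float = 10.0
    method: str = Field(default="both", pattern="^(both|spectral|sect)$")
    outdir: Optional[str] = None
    write_volumes: bool = False


@dataclass
class PipelineResult:
    config: PipelineConfig
    lut: OptimalPairLUT = None
    sect_nodes: tuple = ()
    spectral_rmse_pct: dict = field(default_factory=dict)
    sect_rmse_pct: dict = field(default_factory=dict)
    spectral_residuals_pct: dict = field(default_factory=dict)
    sect_residuals_pct: dict = field(default_factory=dict)
    surface: pd.DataFrame = None
    phantom = None
    label_map = None
    spr_spectral: SPRMap = None
    spr_sect: SPRMap = None
    dose_spectral: DoseGrid = None
    dose_sect: DoseGrid = None
    ranges: pd.DataFrame = None
    gamma: dict[tuple[float, float], GammaResult] = field(default_factory=dict)
    dose_diff_target_pct: float = float("nan")
    dose_diff_entrance_pct: float = float("nan")
    report_paths: dict[str, Path] = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named reporting
                raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("calibrate")
def _calibrate(cfg: PipelineConfig, res: PipelineResult, tissues):
    means = vm_means_table(tissues, cfg.vm_energies)
    models = evaluate_all_pairs(means, tissues)
    anchors = {t.name: simulate_sect_hu(t) for t in tissues}
    res.lut = find_optimal_pairs(models, tissues, anchors)
    res.surface = residual_surface(models)
    grouping = {t.name: t.group for t in tissues}
    res.spectral_residuals_pct = {
        name: e.residual_pct for name, e in res.lut.entries.items()
    }
    res.spectral_rmse_pct = group_rmse(res.spectral_residuals_pct, grouping)
    cal = sect_calibrate(
        [anchors[t.name] for t in tissues],
        [t.reference_spr for t in tissues],
        [t.group for t in tissues],
    )
    res.sect_nodes = cal.nodes
    res.sect_residuals_pct = {
        t.name: percent_deviation(sect_convert(cal, anchors[t.name]), t.reference_spr)
        for t in tissues
    }
    res.sect_rmse_pct = group_rmse(res.sect_residuals_pct, grouping)
    return models, anchors, cal


@_stage("simulate")
def _simulate(cfg: PipelineConfig, tissues):
    spec = pediatric_phantom_spec(
        grid_shape=cfg.grid_shape, spacing=cfg.spacing_mm,
        noise_sd=cfg.noise_sd_hu, seed=cfg.seed,
    )
    return rasterize_phantom(spec, tissues, cfg.vm_energies)


@_stage("segment")
def _segment(cfg: PipelineConfig, res: PipelineResult, phantom, anchors):
    if cfg.thresholds_hu is not None:
        thresholds = cfg.thresholds_hu
    else:
        # air cut at -950 HU, then midpoints of adjacent anchor CT numbers
        hus = sorted(anchors[name] for name in ANCHOR_TISSUES)
        thresholds = (-950.0,) + tuple((a + b) / 2.0 for a, b in zip(hus, hus[1:]))
    lm = threshold_segment(phantom.sect, thresholds)
    return match_regions(lm, res.lut), thresholds


@_stage("map")
def _build_maps(cfg: PipelineConfig, res: PipelineResult, phantom, matched, cal):
    spr_spec = spr_sect = None
    if cfg.method in ("both", "spectral"):
        spr_spec = build_spr_map(phantom.vm, matched, res.lut)
    if cfg.method in ("both", "sect"):
        spr_sect = build_sect_spr_map(
            phantom.sect, cal, phantom.vm.spacing, phantom.vm.origin
        )
    return spr_spec, spr_sect


@_stage("dose")
def _dose(cfg: PipelineConfig, res: PipelineResult, phantom):
    tumor = phantom.spec.regions[-1].shape
    ptv = PTVSphere(center=tumor.center, radius=float(tumor.radii[0]))
    plan_map = res.spr_spectral if res.spr_spectral is not None else res.spr_sect
    beams = [
        plan_beam(
            plan_map,
            BeamSpec(gantry_angle_deg=g, isocenter=ptv.center,
                     prescription_gy=cfg.prescription_gy, fractions=cfg.fractions,
                     rbe=cfg.rbe),
            ptv, energy_step_mev=cfg.energy_step_mev,
        )
        for g in cfg.gantry_angles_deg
    ]
    out = {}
    for tag, spr in (("spectral", res.spr_spectral), ("sect", res.spr_sect)):
        if spr is None:
            continue
        out[tag] = {
            "dose": compute_dose(spr, beams, ptv, sigma_lat_mm=cfg.sigma_lat_mm),
            "profiles": [central_axis_profile(spr, b) for b in beams],
        }
    return beams, ptv, out


@_stage("evaluate")
def _evaluate(cfg: PipelineConfig, res: PipelineResult, beams, ptv, dose_out):
    if "spectral" in dose_out and "sect" in dose_out:
        res.dose_spectral = dose_out["spectral"]["dose"]
        res.dose_sect = dose_out["sect"]["dose"]
        r_spec = [r90_range(p) for p in dose_out["spectral"]["profiles"]]
        r_sect = [r90_range(p) for p in dose_out["sect"]["profiles"]]
        labels = [f"gantry_{b.gantry_angle_deg:+.0f}" for b in beams]
        res.ranges = range_comparison(r_spec, r_sect, labels)
        for dose_pct, dta in cfg.gamma_criteria:
            res.gamma[(dose_pct, dta)] = gamma_index(
                res.dose_sect, res.dose_spectral, dose_pct, dta,
                cutoff_pct=cfg.low_dose_cutoff_pct,
            )
        diff = relative_dose_difference(res.dose_sect, res.dose_spectral)
        grid = res.dose_sect
        target = _sphere_mask(grid.values.shape, grid.spacing, grid.origin, ptv)
        entrance = _entrance_mask(grid, beams, ptv)
        res.dose_diff_target_pct = diff.extreme_in(target)
        res.dose_diff_entrance_pct = diff.extreme_in(entrance)
    elif "spectral" in dose_out:
        res.dose_spectral = dose_out["spectral"]["dose"]
    elif "sect" in dose_out:
        res.dose_sect = dose_out["sect"]["dose"]


def _entrance_mask(grid: DoseGrid, beams, ptv: PTVSphere) -> np.ndarray:
    """Proximal third of each beam path, within the field aperture."""
    shape = grid.values.shape
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    extent = float(np.linalg.norm(np.asarray(shape) * spacing))
    for b in beams:
        d = b.direction
        iso = np.asarray(b.isocenter)
        rel = np.stack([x - iso[0], y - iso[1], z - iso[2]])
        depth = d[0] * rel[0] + d[1] * rel[1] + d[2] * rel[2]  # 0 at isocenter
        lat2 = np.sum(rel**2, axis=0) - depth**2
        entry_depth = -extent / 2.0
        proximal = depth <= entry_depth + (0.0 - entry_depth) / 3.0
        mask |= proximal & (lat2 <= (ptv.radius + 5.0) ** 2)
    return mask


def run_pipeline(config: PipelineConfig, through: str = "evaluate") -> PipelineResult:
    """Run the pipeline up to and including stage ``through``.

    Stages in order: simulate, calibrate, segment, map, dose, evaluate.
    Reports are written when ``config.outdir`` is set; rerunning with the
    same config produces byte-identical reports.
    """
    order = ["simulate", "calibrate", "segment", "map", "dose", "evaluate"]
    if through not in order:
        raise ValueError(f"unknown stage {through!r}")
    stop = order.index(through)
    res = PipelineResult(config=config)
    tissues = load_gammex_library()

    phantom = _simulate(config, tissues)
    res.phantom = phantom
    if stop >= 1:
        models, anchors, cal = _calibrate(config, res, tissues)
    if stop >= 2:
        res.label_map, thresholds = _segment(config, res, phantom, anchors)
    if stop >= 3:
        res.spr_spectral, res.spr_sect = _build_maps(config, res, phantom,
                                                     res.label_map, cal)
    if stop >= 4:
        beams, ptv, dose_out = _dose(config, res, phantom)
    if stop >= 5:
        _evaluate(config, res, beams, ptv, dose_out)

    if config.outdir is not None:
        _write_reports(config, res, through)
    return res


def _write_reports(cfg: PipelineConfig, res: PipelineResult, through: str) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = res.report_paths
    if res.lut is not None:
        paths["lut"] = outdir / "lut.csv"
        res.lut.to_csv(paths["lut"])
        paths["residual_surface"] = outdir / "residual_surface.csv"
        res.surface.to_csv(paths["residual_surface"], index=False)
        paths["sect_nodes"] = outdir / "sect_nodes.csv"
        pd.DataFrame(res.sect_nodes, columns=["hu", "spr"]).to_csv(
            paths["sect_nodes"], index=False
        )
        rmse = pd.DataFrame({
            "group": sorted(res.spectral_rmse_pct),
            "spectral_rmse_pct": [res.spectral_rmse_pct[g]
                                  for g in sorted(res.spectral_rmse_pct)],
            "sect_rmse_pct": [res.sect_rmse_pct.get(g, float("nan"))
                              for g in sorted(res.spectral_rmse_pct)],
        })
        paths["rmse"] = outdir / "rmse.csv"
        rmse.to_csv(paths["rmse"], index=False)
    if res.ranges is not None:
        paths["ranges"] = outdir / "range_comparison.csv"
        res.ranges.to_csv(paths["ranges"], index=False)
    if res.gamma:
        report = {
            "gamma_pass_rate_pct": {
                f"{int(d)}pct_{int(m)}mm": res.gamma[(d, m)].pass_rate
                for d, m in res.gamma
            },
            "max_dose_difference_target_pct": res.dose_diff_target_pct,
            "max_dose_difference_entrance_pct": res.dose_diff_entrance_pct,
        }
        paths["evaluation"] = outdir / "evaluation.json"
        paths["evaluation"].write_text(json.dumps(report, indent=2, sort_keys=True))
    if cfg.write_volumes and res.phantom is not None:
        write_phantom(res.phantom, outdir / "volumes")
    cfg_json = cfg.model_dump_json(indent=2)
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "stage": through,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    paths["provenance"] = outdir / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2, sort_keys=True))
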