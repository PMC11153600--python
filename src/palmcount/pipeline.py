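"""End-to-end orchestration: per-FOV processing, studies, config, logging.

Per FOV the chain is: read (or simulate) the paired videos -> quality filter
-> overcounting merge of the activation video -> density raster -> segment
with torch exclusion -> restrict the pre-activation video to the cell mask ->
exponential base-level fit -> corrected molecule count -> areal density.
Study-level steps then build or apply the depth calibration, aggregate the
weighted depth profile and compare groups.

A study is driven either by a directory of ThunderSTORM CSV pairs listed in
the config, or by the synthetic generator (the config carries the scene and
photokinetics parameters); everything is deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .baseline import BaseLevelFit, correct_count, counts_per_frame, fit_base_level
from .depth_profile import (
    CalibrationProfile,
    DensityMeasurement,
    DepthProfile,
    aggregate_profile,
    build_calibration,
    calibrate,
    compare_groups,
    make_measurement,
    measurements_from_frame,
    measurements_to_frame,
)
from .io import (
    FilterSpec,
    LocalizationTable,
    MergeSpec,
    Molecule,
    TableMeta,
    apply_quality_filter,
    merge_localizations,
    read_table,
)
from .optics import AcquisitionPlan, plan_acquisition
from .segmentation import (
    DensityMap,
    SegmentationResult,
    build_density_map,
    restrict_to_mask,
    segment,
)
from .synthetic import (
    PhotokineticsParams,
    SceneParams,
    generate_scene,
    simulate_fov,
    write_fov,
)

logger = logging.getLogger("palmcount")


@dataclass
class ProcessingSettings:
    """Every knob of the per-FOV chain, at the printed defaults."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    merge: MergeSpec = field(default_factory=MergeSpec)
    pixel_size_nm: float = 20.0
    disk_diameter_nm: float = 1000.0
    lower: float = 0.0
    upper: float = 150.0
    whole_component: bool = False
    map_source: str = "molecules"  # density raster from merged molecules or raw localizations
    with_floor: bool = False
    bin_size: int = 1
    integral_mode: str = "continuous"


@dataclass
class FovResult:
    """Everything the per-FOV chain produced, plus stage record counts."""

    measurement: DensityMeasurement
    molecules: list[Molecule]
    density_map: DensityMap
    segmentation: SegmentationResult
    base_fit: BaseLevelFit
    stage_counts: dict


def process_fov(
    pre: LocalizationTable,
    act: LocalizationTable,
    fov_width_um: float,
    fov_height_um: float,
    settings: ProcessingSettings | None = None,
    fov_id: str = "",
    replicate: int = 0,
    grid_xy_um: tuple[float, float] = (0.0, 0.0),
) -> FovResult:
    """Run the full single-FOV chain on a pre/activation video pair."""
    s = settings if settings is not None else ProcessingSettings()
    pre_f = apply_quality_filter(pre, s.filter)
    act_f = apply_quality_filter(act, s.filter)
    molecules = merge_localizations(act_f, s.merge)

    map_source = molecules if s.map_source == "molecules" else act_f
    dmap = build_density_map(
        map_source,
        fov_width_um,
        fov_height_um,
        pixel_size_nm=s.pixel_size_nm,
        disk_diameter_nm=s.disk_diameter_nm,
    )
    seg = segment(dmap, lower=s.lower, upper=s.upper, whole_component=s.whole_component)

    mol_in, mol_report = restrict_to_mask(molecules, seg)
    pre_in, pre_report = restrict_to_mask(pre_f, seg)

    pre_range = pre.meta.frame_range or (1, 1000)
    act_range = act.meta.frame_range or (pre_range[1] + 1, pre_range[1] + 1000)
    series = counts_per_frame(pre_in, pre_range)
    fit = fit_base_level(
        series,
        fit_window=pre_range,
        prediction_window=act_range,
        with_floor=s.with_floor,
        bin_size=s.bin_size,
        integral_mode=s.integral_mode,
    )
    corrected = correct_count(len(mol_in), fit)

    measurement = make_measurement(
        fov_id=fov_id,
        depth_um=pre.meta.depth_um,
        raw_count=len(mol_in),
        predicted_spurious=fit.predicted_spurious,
        corrected_count=corrected.value,
        area_um2=seg.area_um2,
        replicate=replicate,
        grid_x_um=grid_xy_um[0],
        grid_y_um=grid_xy_um[1],
    )
    if corrected.clamped:
        measurement.flags.append("clamped")
    measurement.flags.extend(fit.flags)

    stage_counts = {
        "pre_raw": len(pre),
        "pre_filtered": len(pre_f),
        "pre_in_mask": len(pre_in),
        "act_raw": len(act),
        "act_filtered": len(act_f),
        "molecules": len(molecules),
        "molecules_in_mask": len(mol_in),
        "pre_outside_raster": pre_report["n_outside_raster"],
        "mol_outside_raster": mol_report["n_outside_raster"],
    }
    return FovResult(measurement, molecules, dmap, seg, fit, stage_counts)


# ---------------------------------------------------------------------------
# Simulated studies
# ---------------------------------------------------------------------------

def density_by_depth(
    plan: AcquisitionPlan, base_density: float, relative_density: Sequence[float] | None
) -> dict[float, float]:
    """Map plane depths to true densities: ``base * relative`` per plane."""
    depths = plan.plane_depths_um
    if relative_density is None:
        return {z: float(base_density) for z in depths}
    if len(relative_density) != len(depths):
        raise ValueError("relative_density length must match the number of planes")
    return {z: float(base_density) * float(r) for z, r in zip(depths, relative_density)}


def simulate_study(
    plan: AcquisitionPlan,
    scene_params: SceneParams,
    kinetics: PhotokineticsParams,
    seed: int,
    n_replicates: int = 1,
    write_dir: str | Path | None = None,
):
    """Yield ``(fov_spec, replicate, pre, act, truth)`` for a whole study.

    One scene is generated per (replicate, lateral position); each of its
    depths is then acquired as a pre/activation video pair.  All randomness
    derives from ``seed`` through a spawned seed tree, so the study is
    reproducible FOV by FOV.
    """
    specs = plan_acquisition(plan)
    positions = sorted({(s.ix, s.iy) for s in specs})
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)
    for rep in range(n_replicates):
        pos_seeds = rep_seeds[rep].spawn(len(positions))
        for (pos, pos_ss) in zip(positions, pos_seeds):
            children = pos_ss.spawn(1 + plan.nz)
            scene = generate_scene(scene_params, seed=np.random.default_rng(children[0]))
            depth_iter = [s for s in specs if (s.ix, s.iy) == pos]
            for k, spec in enumerate(sorted(depth_iter, key=lambda s: s.depth_um)):
                rng = np.random.default_rng(children[1 + k])
                pre, act, truth = simulate_fov(scene, kinetics, spec.depth_um, rng)
                pre.meta.fov_id = act.meta.fov_id = spec.fov_id
                if write_dir is not None:
                    write_fov(pre, act, truth, write_dir, f"r{rep}_{spec.fov_id}")
                yield spec, rep, pre, act, truth


def run_simulated_condition(
    plan: AcquisitionPlan,
    scene_params: SceneParams,
    kinetics: PhotokineticsParams,
    seed: int,
    settings: ProcessingSettings | None = None,
    n_replicates: int = 1,
) -> list[DensityMeasurement]:
    """Simulate one sample condition and process every FOV."""
    measurements = []
    for spec, rep, pre, act, _truth in simulate_study(
        plan, scene_params, kinetics, seed, n_replicates=n_replicates
    ):
        result = process_fov(
            pre,
            act,
            plan.fov_width_um,
            plan.fov_height_um,
            settings,
            fov_id=spec.fov_id,
            replicate=rep,
            grid_xy_um=(spec.x_um, spec.y_um),
        )
        measurements.append(result.measurement)
    return measurements


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_GENERATOR_SEED_MOD = 2**31 - 1


def _sub(cfg: Mapping, key: str) -> dict:
    value = cfg.get(key) or {}
    if not isinstance(value, Mapping):
        raise ValueError(f"config section {key!r} must be a mapping")
    return dict(value)


def settings_from_config(cfg: Mapping) -> ProcessingSettings:
    return ProcessingSettings(
        filter=FilterSpec(**_sub(cfg, "filter")),
        merge=MergeSpec(**_sub(cfg, "merge")),
        **_sub(cfg, "segmentation"),
        **_sub(cfg, "base_level"),
    )


def plan_from_config(cfg: Mapping) -> AcquisitionPlan:
    return AcquisitionPlan(**_sub(cfg, "acquisition"))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


@dataclass
class RunReport:
    """Run summary: outputs written, per-FOV stage counts, failures."""

    output_dir: Path
    measurements: list[DensityMeasurement]
    profile: DepthProfile | None
    calibration: CalibrationProfile | None
    n_failed: int
    files: dict[str, Path]


def run_pipeline(config: Mapping | str | Path, output_dir: str | Path) -> RunReport:
    """Execute a config-driven run and write its CSV/JSON outputs.

    The config (YAML mapping) names either a ``simulation`` section (scene +
    kinetics + acquisition plan) or an ``inputs`` list of per-FOV CSV pairs,
    plus the processing settings; see the README for the schema.  Outputs:
    ``measurements.csv``, ``profile.csv`` (+ normalized), optionally
    ``calibration_profile.csv`` (calibration mode) and ``comparisons.csv``,
    and a ``report.json`` with parameters and per-stage record counts.
    Outputs are deterministic given config + seed.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(logging.INFO)

    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "biofilm")
    settings = settings_from_config(cfg)
    plan = plan_from_config(cfg)
    files: dict[str, Path] = {}
    failures: list[dict] = []
    stage_log: list[dict] = []
    measurements: list[DensityMeasurement] = []

    sim_cfg = cfg.get("simulation")
    inputs = cfg.get("inputs")
    if sim_cfg is None and inputs is None:
        raise ValueError("config needs a 'simulation' section or an 'inputs' list")

    if sim_cfg is not None:
        sim_cfg = dict(sim_cfg)
        base = float(sim_cfg.get("base_density_per_um2", 40.0))
        rel = sim_cfg.get("relative_density")
        if mode == "calibration":
            rel = None
        density = density_by_depth(plan, base, rel)
        scene_params = SceneParams(
            fov_width_um=plan.fov_width_um,
            fov_height_um=plan.fov_height_um,
            plane_depths_um=plan.plane_depths_um,
            molecule_density=density,
            **_sub(sim_cfg, "scene"),
        )
        kinetics = PhotokineticsParams(**_sub(sim_cfg, "kinetics"))
        n_rep = int(sim_cfg.get("n_replicates", 1))
        write_dir = out / "tables" if cfg.get("write_tables") else None
        stream = simulate_study(
            plan, scene_params, kinetics, seed % _GENERATOR_SEED_MOD,
            n_replicates=n_rep, write_dir=write_dir,
        )
        jobs = (
            (spec.fov_id, rep, pre, act, (spec.x_um, spec.y_um))
            for spec, rep, pre, act, _truth in stream
        )
    else:
        def _read_jobs():
            for entry in inputs:
                meta = TableMeta(
                    fov_id=str(entry.get("fov_id", entry["pre"])),
                    depth_um=float(entry.get("depth_um", 0.0)),
                )
                pre = read_table(entry["pre"], meta=replace(meta, role="pre"))
                act = read_table(entry["act"], meta=replace(meta, role="activation"))
                pre.meta.frame_range = tuple(entry.get("pre_frames", (1, 1000)))
                act.meta.frame_range = tuple(entry.get("act_frames", (1001, 2000)))
                xy = (float(entry.get("grid_x_um", 0.0)), float(entry.get("grid_y_um", 0.0)))
                yield meta.fov_id, int(entry.get("replicate", 0)), pre, act, xy

        jobs = _read_jobs()

    for fov_id, rep, pre, act, xy in jobs:
        try:
            result = process_fov(
                pre, act, plan.fov_width_um, plan.fov_height_um, settings,
                fov_id=fov_id, replicate=rep, grid_xy_um=xy,
            )
        except Exception as exc:  # recorded, FOV skipped
            logger.error("FOV %s failed: %s", fov_id, exc)
            failures.append({"fov_id": fov_id, "replicate": rep, "error": str(exc)})
            continue
        logger.info(
            "FOV %s rep %d depth %.1f um: %d molecules, area %.1f um^2, "
            "density %.3f um^-2",
            fov_id, rep, result.measurement.depth_um,
            result.measurement.raw_count, result.measurement.area_um2,
            result.measurement.density,
        )
        stage_log.append({"fov_id": fov_id, "replicate": rep, **result.stage_counts})
        measurements.append(result.measurement)

    files["measurements"] = out / "measurements.csv"
    measurements_to_frame(measurements).to_csv(
        files["measurements"], index=False, lineterminator="\n"
    )

    calibration = None
    if mode == "calibration":
        calibration = build_calibration(measurements)
        files["calibration_profile"] = out / "calibration_profile.csv"
        calibration.to_frame().to_csv(
            files["calibration_profile"], index=False, lineterminator="\n"
        )

    cal_path = cfg.get("calibration")
    calibrated = measurements
    if cal_path:
        cal_df = pd.read_csv(cal_path)
        profile_obj = CalibrationProfile(
            tuple(float(z) for z in cal_df["depth_um"]),
            tuple(float(f) for f in cal_df["factor"]),
            tuple(float(e) for e in cal_df["factor_error"]),
        )
        calibrated = calibrate(measurements, profile_obj)
        files["calibrated_measurements"] = out / "calibrated_measurements.csv"
        measurements_to_frame(calibrated).to_csv(
            files["calibrated_measurements"], index=False, lineterminator="\n"
        )
    elif mode == "biofilm" and sim_cfg is not None:
        logger.warning("no calibration profile configured; profile is uncalibrated")

    profile = None
    valid = [m for m in calibrated if m.valid]
    if valid:
        profile = aggregate_profile(valid, weighting=cfg.get("weighting", "inverse_variance"))
        files["profile"] = out / "profile.csv"
        profile.to_frame().to_csv(files["profile"], index=False, lineterminator="\n")
        if 0.0 in profile.depths_um and profile.mean_density[
            profile.depths_um.index(0.0)
        ] > 0:
            files["profile_normalized"] = out / "profile_normalized.csv"
            profile.normalized().to_frame().to_csv(
                files["profile_normalized"], index=False, lineterminator="\n"
            )

    compare_path = cfg.get("compare_with")
    if compare_path:
        other = measurements_from_frame(pd.read_csv(compare_path))
        rows = []
        by_depth = lambda ms: {
            z: [m.density for m in ms if m.valid and m.depth_um == z]
            for z in sorted({m.depth_um for m in ms if m.valid})
        }
        mine, theirs = by_depth(calibrated), by_depth(other)
        for z in sorted(set(mine) & set(theirs)):
            if len(mine[z]) >= 2 and len(theirs[z]) >= 2:
                t, p = compare_groups(mine[z], theirs[z])
                rows.append({"depth_um": z, "t": t, "p": p,
                             "n_a": len(mine[z]), "n_b": len(theirs[z])})
        files["comparisons"] = out / "comparisons.csv"
        pd.DataFrame(rows, columns=["depth_um", "t", "p", "n_a", "n_b"]).to_csv(
            files["comparisons"], index=False, lineterminator="\n"
        )

    report = {
        "seed": seed,
        "mode": mode,
        "settings": {
            "filter": asdict(settings.filter),
            "merge": asdict(settings.merge),
            "pixel_size_nm": settings.pixel_size_nm,
            "disk_diameter_nm": settings.disk_diameter_nm,
            "lower": settings.lower,
            "upper": settings.upper,
            "whole_component": settings.whole_component,
            "map_source": settings.map_source,
            "with_floor": settings.with_floor,
            "integral_mode": settings.integral_mode,
        },
        "acquisition": asdict(plan),
        "n_fovs_processed": len(measurements),
        "n_fovs_failed": len(failures),
        "failures": failures,
        "stage_counts": stage_log,
    }
    files["report"] = out / "report.json"
    with open(files["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunReport(
        output_dir=out,
        measurements=calibrated,
        profile=profile,
        calibration=calibration,
        n_failed=len(failures),
        files=files,
    )
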