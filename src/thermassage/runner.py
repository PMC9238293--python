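"""Run orchestration: config -> scene -> solve -> coupled flow -> outputs.

This is the glue the analysis drivers and the CLI share. A "scene" bundles
the phantom, its surface conditions and the assembled linear system; runs
write profile tables (CSV), optional field exports (VTK / npz) and a JSON
manifest with the config digest and solver diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import (
    ActuatorLayout,
    AnatomyVolume,
    SpineColumnSpec,
    TissueLayerSpec,
    add_spine_column,
    build_layered_anatomy,
    property_table,
    surface_condition_masks,
)
from .bioheat import (
    SteadySolveOptions,
    SteadySystem,
    TemperatureField,
    ThermalBoundarySpec,
    assemble_steady_system,
    baseline_field,
    solve_steady,
)
from .circulation import (
    FlowModelParams,
    FlowMeasurement,
    calibration_measurements,
    fit_flow_model,
    flow_field,
)
from .config import SimulationConfig, config_digest
from .io import write_field_npz, write_json, write_vtk_structured_points
from .profiles import SweepResult, run_sweep, standard_depths, standard_profiles

log = logging.getLogger("thermassage")

__all__ = ["Scene", "build_scene", "solve_scene", "fit_from_config",
           "run_simulation", "run_full_sweep"]


@dataclass
class Scene:
    """Assembled, ready-to-solve simulation scene."""

    config: SimulationConfig
    volume: AnatomyVolume
    system: SteadySystem
    options: SteadySolveOptions
    actuator_anchor_mm: tuple[float, float]


def _build_volume(cfg: SimulationConfig, spacing_mm: float | None = None) -> AnatomyVolume:
    a = cfg.anatomy
    vol = build_layered_anatomy(
        layers=[TissueLayerSpec(l.name, l.thickness_mm) for l in a.layers],
        lateral_extent_mm=a.lateral_extent_mm,
        vertical_extent_mm=a.vertical_extent_mm,
        depth_extent_mm=a.depth_extent_mm,
        spacing_mm=spacing_mm if spacing_mm is not None else a.spacing_mm,
    )
    if a.spine.enabled:
        vol = add_spine_column(
            vol,
            SpineColumnSpec(
                cord_mm=a.spine.cord_mm,
                csf_mm=a.spine.csf_mm,
                epidural_fat_mm=a.spine.epidural_fat_mm,
                vertebra_mm=a.spine.vertebra_mm,
            ),
            center_x_mm=a.spine.center_x_mm,
            start_depth_mm=a.spine.start_depth_mm,
        )
    return vol


def build_scene(cfg: SimulationConfig, spacing_mm: float | None = None) -> Scene:
    """Build the phantom and assemble the steady system for a config."""
    vol = _build_volume(cfg, spacing_mm)
    src = cfg.sources
    layout = ActuatorLayout(
        centers_mm=tuple(tuple(c) for c in src.actuators.centers_mm),
        radius_mm=src.actuators.radius_mm,
        temperature_C=src.actuators.temperature_C,
    )
    with warnings.catch_warnings():
        # default vertical actuator pairs overlap by design (merged roller)
        warnings.filterwarnings("ignore", message="overlapping actuator discs")
        surface = surface_condition_masks(
            vol, layout, src.mat_temperature_C, src.mat_half_width_mm
        )
    bcs = ThermalBoundarySpec(
        surface=surface,
        cut_temperature_C=src.cut_temperature_C,
        h_W_m2K=src.h_W_m2K,
        ambient_C=src.ambient_C,
        lateral_mode=src.lateral_mode,
    )
    log.debug("assembling %s voxels at %.3g mm", vol.labels.size, vol.spacing_mm)
    system = assemble_steady_system(vol, property_table(), bcs)
    # probe anchor: the first actuator disc in the +x, +y quadrant
    centers = layout.centers_mm
    anchor = max(centers, key=lambda c: (c[0], c[1])) if centers else (0.0, 0.0)
    return Scene(
        config=cfg,
        volume=vol,
        system=system,
        options=SteadySolveOptions(rtol=cfg.solver.rtol, maxiter=cfg.solver.maxiter),
        actuator_anchor_mm=anchor,
    )


def _prolong(coarse: np.ndarray, coarse_vol: AnatomyVolume, fine_vol: AnatomyVolume) -> np.ndarray:
    """Trilinear prolongation of a coarse solution onto a finer grid."""
    from scipy.interpolate import RegularGridInterpolator

    rgi = RegularGridInterpolator(
        (coarse_vol.x_centers_mm, coarse_vol.y_centers_mm, coarse_vol.z_centers_mm),
        coarse, bounds_error=False, fill_value=None,
    )
    X, Y, Z = np.meshgrid(fine_vol.x_centers_mm, fine_vol.y_centers_mm,
                          fine_vol.z_centers_mm, indexing="ij")
    return rgi(np.stack([X, Y, Z], axis=-1))


def solve_scene(scene: Scene, actuator_temperature_C: float | None = None,
                x0: np.ndarray | None = None) -> TemperatureField:
    """Solve a scene, optionally overriding the actuator setting.

    With ``solver.coarse_init`` and spacing < 2 mm, the solve warm-starts
    from a 2x-coarser solution (prolonged trilinearly); the result is still
    iterated to the configured residual on the fine grid.
    """
    cfg = scene.config
    if x0 is None and cfg.solver.coarse_init and scene.volume.spacing_mm < 2.0:
        coarse = build_scene(cfg, spacing_mm=scene.volume.spacing_mm * 2)
        cfield = solve_steady(
            coarse.system, coarse.options,
            rhs=coarse.system.rhs(actuator_temperature_C=actuator_temperature_C),
        )
        x0 = _prolong(cfield.values, coarse.volume, scene.volume)
        log.debug("coarse cascade: %d iterations", cfield.diagnostics["iterations"])
    rhs = scene.system.rhs(actuator_temperature_C=actuator_temperature_C)
    field = solve_steady(scene.system, scene.options, rhs=rhs, x0=x0)
    log.debug("solved: %s", field.diagnostics)
    return field


def fit_from_config(cfg: SimulationConfig) -> FlowModelParams:
    """Fit the circulation transfer model per the config's calibration block."""
    if cfg.circulation.calibration == "builtin":
        data = calibration_measurements()
    else:
        df = pd.read_csv(cfg.circulation.calibration, comment="#")
        try:
            data = [
                FlowMeasurement(float(r.temperature_C), float(r.flow_L_min))
                for r in df.itertuples()
            ]
        except (AttributeError, ValueError) as exc:
            raise ValueError(
                f"malformed calibration CSV {cfg.circulation.calibration!r}: {exc}"
            ) from exc
    return fit_flow_model(data, cfg.circulation.fit_baseline_C, cfg.circulation.form)


def _write_outputs(out_dir: Path, cfg: SimulationConfig, vol: AnatomyVolume,
                   temp: TemperatureField, flow, profiles: Mapping) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    formats = cfg.outputs.formats
    if "vtk" in formats:
        write_vtk_structured_points(out_dir / "temperature.vtk", temp.values,
                                    temp.spacing_mm, "temperature_C")
        write_vtk_structured_points(out_dir / "flow.vtk", flow.values,
                                    temp.spacing_mm, "flow_L_min")
        written += ["temperature.vtk", "flow.vtk"]
    if "npz" in formats:
        write_field_npz(out_dir / "temperature.npz", temp.values, temp.spacing_mm,
                        quantity="temperature_C", diagnostics=temp.diagnostics)
        write_field_npz(out_dir / "flow.npz", flow.values, temp.spacing_mm,
                        quantity="flow_L_min")
        written += ["temperature.npz", "flow.npz"]
    for name, series in profiles.items():
        fname = f"profile_{name}.csv"
        series.to_frame().to_csv(out_dir / fname, index=False, float_format="%.6f")
        written.append(fname)
    return {"files": sorted(written)}


def run_simulation(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Solve one scene and write fields, the standard profiles and a manifest.

    Deterministic: identical configs produce identical profile CSVs.
    Returns the manifest dictionary.
    """
    out_dir = Path(out_dir)
    scene = build_scene(cfg)
    params = fit_from_config(cfg)
    temp = solve_scene(scene)
    base = baseline_field(scene.volume, cfg.circulation.core_temperature_C)
    flow = flow_field(temp, base, params)
    profiles = standard_profiles(temp, flow, scene.actuator_anchor_mm,
                                 standard_depths(scene.volume))
    outputs = _write_outputs(out_dir, cfg, scene.volume, temp, flow, profiles)
    manifest = {
        "version": __version__,
        "config_digest": config_digest(cfg),
        "actuator_temperature_C": cfg.sources.actuators.temperature_C,
        "grid": list(scene.volume.dims),
        "spacing_mm": scene.volume.spacing_mm,
        "solver": temp.diagnostics,
        "flow_params": {"F_o": params.F_o, "F_max": params.F_max,
                        "a": params.a, "b": params.b, "form": params.form},
        "outputs": outputs,
    }
    write_json(out_dir / "manifest.json", manifest)
    return manifest


def run_full_sweep(cfg: SimulationConfig, out_dir: str | Path) -> SweepResult:
    """Run the actuator-temperature sweep and write per-setting outputs."""
    out_dir = Path(out_dir)
    scene = build_scene(cfg)
    params = fit_from_config(cfg)
    result = run_sweep(
        scene.volume, scene.system, params,
        temperatures_C=cfg.sweep_temperatures_C,
        actuator_anchor_mm=scene.actuator_anchor_mm,
        core_temperature_C=cfg.circulation.core_temperature_C,
        options=scene.options,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    for st in result.settings:
        sub = out_dir / f"setting_{st.actuator_temperature_C:g}C"
        if st.error is not None:
            write_json(sub.with_suffix(".error.json"),
                       {"setting_C": st.actuator_temperature_C, "error": st.error})
            continue
        _write_outputs(sub, cfg, scene.volume, st.temperature, st.flow, st.profiles)
    summary = result.summary()
    summary.to_csv(out_dir / "sweep_summary.csv", index=False, float_format="%.6f")
    write_json(out_dir / "manifest.json", {
        "version": __version__,
        "config_digest": config_digest(cfg),
        "settings_C": [st.actuator_temperature_C for st in result.settings],
        "errors": {f"{st.actuator_temperature_C:g}": st.error
                   for st in result.settings if st.error},
    })
    return result
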