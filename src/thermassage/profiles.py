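"""Depth/lateral profile extraction and the actuator-temperature sweep.

Profiles sample a scalar field (temperature or flow) by trilinear
interpolation on the voxel-center grid: depth profiles run anteriorly from
the skin surface at a fixed (x, y) anchor; lateral profiles run across the
back at a fixed depth. The sweep solves the same scene at a series of
actuator settings (one matrix assembly, warm-started solves) and tabulates
the standard probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .anatomy import AnatomyVolume
from .bioheat import (
    SteadySolveOptions,
    SteadySystem,
    TemperatureField,
    baseline_field,
    solve_steady,
)
from .circulation import FlowField, FlowModelParams, flow_field

__all__ = [
    "ProfileSeries",
    "SweepSetting",
    "SweepResult",
    "depth_profile",
    "lateral_profile",
    "slice_extract",
    "run_sweep",
    "DEFAULT_SWEEP_TEMPERATURES_C",
]

DEFAULT_SWEEP_TEMPERATURES_C: tuple[float, ...] = (45.0, 50.0, 55.0, 60.0, 65.0)


@dataclass
class ProfileSeries:
    """1D sampled series along depth or lateral position."""

    coordinate_mm: np.ndarray
    values: np.ndarray
    anchor: dict
    quantity: str  # "temperature_C" | "flow_L_min" | "fold_change"
    axis: str  # "depth" | "lateral"

    def __post_init__(self) -> None:
        self.coordinate_mm = np.asarray(self.coordinate_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.coordinate_mm) <= 0):
            raise ValueError("profile coordinates must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"coordinate_mm": self.coordinate_mm, self.quantity: self.values})
        for k, v in self.anchor.items():
            df[k] = v
        return df


def _interpolator(values: np.ndarray, spacing_mm: float) -> RegularGridInterpolator:
    nx, ny, nz = values.shape
    x = (np.arange(nx) + 0.5) * spacing_mm - nx * spacing_mm / 2.0
    y = (np.arange(ny) + 0.5) * spacing_mm - ny * spacing_mm / 2.0
    z = (np.arange(nz) + 0.5) * spacing_mm
    return RegularGridInterpolator((x, y, z), values)  # error outside grid


def _field_values(fld) -> tuple[np.ndarray, float, str]:
    if isinstance(fld, TemperatureField):
        return fld.values, fld.spacing_mm, "temperature_C"
    if isinstance(fld, FlowField):
        return fld.values, fld.spacing_mm, "flow_L_min"
    raise TypeError(f"unsupported field type {type(fld).__name__}")


def depth_profile(fld, anchor_x_mm: float, anchor_y_mm: float,
                  depths_mm: Sequence[float]) -> ProfileSeries:
    """Sample a field along depth at a fixed surface anchor.

    Depth is measured anteriorly from the skin surface (z = 0); samples use
    trilinear interpolation and raise if any point leaves the grid interior.
    """
    values, spacing, quantity = _field_values(fld)
    depths = np.asarray(depths_mm, dtype=float)
    rgi = _interpolator(values, spacing)
    pts = np.column_stack([
        np.full(depths.shape, anchor_x_mm),
        np.full(depths.shape, anchor_y_mm),
        depths,
    ])
    return ProfileSeries(
        coordinate_mm=depths,
        values=rgi(pts),
        anchor={"anchor_x_mm": anchor_x_mm, "anchor_y_mm": anchor_y_mm},
        quantity=quantity,
        axis="depth",
    )


def lateral_profile(fld, depth_mm: float, anchor_y_mm: float,
                    x_range_mm: tuple[float, float] | None = None) -> ProfileSeries:
    """Sample a field across the lateral (x) extent at a fixed depth.

    Samples at the grid's x voxel centers within ``x_range_mm`` (defaults to
    the full lateral extent).
    """
    values, spacing, quantity = _field_values(fld)
    nx = values.shape[0]
    xs = (np.arange(nx) + 0.5) * spacing - nx * spacing / 2.0
    if x_range_mm is not None:
        lo, hi = x_range_mm
        xs = xs[(xs >= lo) & (xs <= hi)]
        if xs.size == 0:
            raise ValueError("empty lateral range")
    rgi = _interpolator(values, spacing)
    pts = np.column_stack([xs, np.full(xs.shape, anchor_y_mm), np.full(xs.shape, depth_mm)])
    return ProfileSeries(
        coordinate_mm=xs,
        values=rgi(pts),
        anchor={"anchor_y_mm": anchor_y_mm, "depth_mm": depth_mm},
        quantity=quantity,
        axis="lateral",
    )


def slice_extract(fld, axis: str, coordinate_mm: float) -> tuple[np.ndarray, dict]:
    """Extract the grid plane nearest to a physical coordinate.

    ``axis`` is "x" (sagittal), "y" (axial) or "z" (coronal / constant
    depth); returns the 2D array plus metadata with the snapped coordinate
    and the in-plane axis coordinates, ready for contour plotting.
    """
    values, spacing, quantity = _field_values(fld)
    nx, ny, nz = values.shape
    coords = {
        "x": (np.arange(nx) + 0.5) * spacing - nx * spacing / 2.0,
        "y": (np.arange(ny) + 0.5) * spacing - ny * spacing / 2.0,
        "z": (np.arange(nz) + 0.5) * spacing,
    }
    if axis not in coords:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    c = coords[axis]
    if not (c.min() - spacing / 2 <= coordinate_mm <= c.max() + spacing / 2):
        raise ValueError(f"plane {axis}={coordinate_mm} mm outside the domain")
    i = int(np.argmin(np.abs(c - coordinate_mm)))
    plane = np.take(values, i, axis="xyz".index(axis))
    other = [a for a in "xyz" if a != axis]
    meta = {
        "axis": axis,
        "requested_mm": coordinate_mm,
        "snapped_mm": float(c[i]),
        "quantity": quantity,
        "row_axis": other[0],
        "row_mm": coords[other[0]],
        "col_axis": other[1],
        "col_mm": coords[other[1]],
    }
    return plane.copy(), meta


@dataclass
class SweepSetting:
    """Solved scene at one actuator temperature."""

    actuator_temperature_C: float
    temperature: TemperatureField
    flow: FlowField
    profiles: dict[str, ProfileSeries]
    error: str | None = None


@dataclass
class SweepResult:
    """Ordered sweep over actuator settings with standard probes."""

    settings: list[SweepSetting]

    def summary(self) -> pd.DataFrame:
        """Long-form table: one row per (setting, probe, coordinate)."""
        rows = []
        for st in self.settings:
            if st.error is not None:
                continue
            for probe, series in st.profiles.items():
                df = series.to_frame()
                df.insert(0, "setting_C", st.actuator_temperature_C)
                df.insert(1, "probe", probe)
                rows.append(df)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def standard_depths(vol: AnatomyVolume, step_mm: float = 1.0,
                    max_depth_mm: float = 50.0) -> np.ndarray:
    """Whole-millimetre depth samples restricted to the voxel-center range."""
    zc = vol.z_centers_mm
    depths = np.arange(1.0, max_depth_mm + 0.5 * step_mm, step_mm)
    return depths[(depths >= zc[0]) & (depths <= zc[-1])]


def standard_profiles(
    temp: TemperatureField,
    flow: FlowField,
    actuator_anchor_mm: tuple[float, float],
    depths_mm: Sequence[float],
    lateral_depths_mm: Sequence[float] = (20.0, 30.0),
) -> dict[str, ProfileSeries]:
    """The four standard probes: depth at the actuator centroid, depth at the
    rectangle midline, and lateral profiles at fixed depths."""
    ax, ay = actuator_anchor_mm
    out: dict[str, ProfileSeries] = {
        "depth_actuator_temperature": depth_profile(temp, ax, ay, depths_mm),
        "depth_midline_temperature": depth_profile(temp, 0.0, 0.0, depths_mm),
        "depth_actuator_flow": depth_profile(flow, ax, ay, depths_mm),
        "depth_midline_flow": depth_profile(flow, 0.0, 0.0, depths_mm),
    }
    for d in lateral_depths_mm:
        out[f"lateral_{d:g}mm_temperature"] = lateral_profile(temp, d, ay)
        out[f"lateral_{d:g}mm_flow"] = lateral_profile(flow, d, ay)
    return out


def run_sweep(
    vol: AnatomyVolume,
    system: SteadySystem,
    params: FlowModelParams,
    temperatures_C: Sequence[float] = DEFAULT_SWEEP_TEMPERATURES_C,
    actuator_anchor_mm: tuple[float, float] = (60.0, 16.0),
    depths_mm: Sequence[float] | None = None,
    core_temperature_C: float = 37.0,
    options: SteadySolveOptions = SteadySolveOptions(),
) -> SweepResult:
    """Solve the scene across actuator settings and extract standard probes.

    Settings are solved in ascending order reusing one assembled matrix;
    each solve warm-starts from the previous setting. A failed setting is
    recorded with its error and the sweep continues.
    """
    temps = sorted(float(t) for t in temperatures_C)
    if depths_mm is None:
        depths_mm = standard_depths(vol)
    base = baseline_field(vol, core_temperature_C)
    settings: list[SweepSetting] = []
    x0 = None
    for t in temps:
        try:
            fld = solve_steady(system, options, rhs=system.rhs(actuator_temperature_C=t), x0=x0)
            x0 = fld.values
            ff = flow_field(fld, base, params)
            profs = standard_profiles(fld, ff, actuator_anchor_mm, depths_mm)
            settings.append(SweepSetting(t, fld, ff, profs))
        except Exception as exc:  # keep independent settings alive
            settings.append(SweepSetting(t, None, None, {}, error=str(exc)))
    return SweepResult(settings=settings)
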