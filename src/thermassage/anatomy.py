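"""Synthetic layered anatomy of the lumbar back.

The computational domain is a flat voxelized slab standing in for a segmented
MRI of the lower back: tissue layers (skin, subcutaneous fat, muscle, soft
tissue) are stacked along the depth axis, with an optional concentric
spinal-column insert. Coordinates follow the convention

* ``x`` — lateral, midline at ``x = 0`` (mm),
* ``y`` — superior-inferior, ``y = 0`` at the center of the actuator
  rectangle (mm),
* ``z`` — depth from the posterior skin surface, ``z = 0`` at the surface and
  increasing anteriorly (mm).

Voxels are classified by the position of their center; layer boundaries are
half-open ``[lower, upper)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TissueLayerSpec",
    "TissueProperties",
    "AnatomyVolume",
    "ActuatorLayout",
    "SpineColumnSpec",
    "SurfaceAssignment",
    "DEFAULT_LAYERS",
    "DEFAULT_ACTUATOR_CENTERS_MM",
    "ACTUATOR_RADIUS_MM",
    "property_table",
    "build_layered_anatomy",
    "add_spine_column",
    "surface_condition_masks",
]

# Surface condition codes used by SurfaceAssignment.codes
UNCOVERED, MAT, ACTUATOR = 0, 1, 2


@dataclass(frozen=True)
class TissueLayerSpec:
    """One slab in the posterior-to-anterior layer stack."""

    name: str
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")


@dataclass(frozen=True)
class TissueProperties:
    """Thermal and perfusion constants of one tissue.

    Units: k [W m-1 K-1], rho [kg m-3], c [J kg-1 K-1], rho_b [kg m-3],
    c_b [J kg-1 K-1], w_b [1/s], T_b [degC], Q_m [W m-3].
    """

    k: float
    rho: float
    c: float
    rho_b: float
    c_b: float
    w_b: float
    T_b: float
    Q_m: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.rho <= 0 or self.c <= 0:
            raise ValueError("k, rho, c must be positive")
        if self.w_b < 0 or self.Q_m < 0:
            raise ValueError("w_b and Q_m must be non-negative")


def _celsius(kelvin: float) -> float:
    return kelvin - 273.15


# Literature-survey tissue constants (blood temperature stored in degC).
_PROPERTIES: dict[str, TissueProperties] = {
    "skin": TissueProperties(0.37, 1100, 3391, 1057, 3600, 0.0004, _celsius(309.7), 457),
    "muscle": TissueProperties(0.47, 1142, 3432, 1057, 3600, 0.0004, _celsius(309.7), 457),
    "soft tissue": TissueProperties(0.47, 1142, 3432, 1057, 3600, 0.0004, _celsius(309.7), 457),
    "vertebrae": TissueProperties(0.32, 1908, 1313, 1057, 3600, 0.0003, _celsius(309.7), 342),
    "i.v. disc": TissueProperties(0.49, 1100, 3568, 0, 0, 0, _celsius(309.7), 0),
    "subcutaneous fat": TissueProperties(0.21, 1142, 2348, 1057, 3600, 0.00008, _celsius(309.7), 302),
    "epidural fat": TissueProperties(0.21, 1142, 2348, 1057, 3600, 0.00008, _celsius(309.7), 302),
    "CSF": TissueProperties(0.57, 1007, 4096, 0, 0, 0, _celsius(310.0), 0),
    "spinal cord": TissueProperties(0.51, 1075, 3630, 1057, 3600, 0.008, _celsius(309.7), 9121),
}

#: Default posterior-to-anterior layer stack (mm); depth beyond the last
#: layer is filled with the last layer's tissue ("soft tissue").
DEFAULT_LAYERS: tuple[TissueLayerSpec, ...] = (
    TissueLayerSpec("skin", 1.1),
    TissueLayerSpec("subcutaneous fat", 13.0),
    TissueLayerSpec("muscle", 42.0),
    TissueLayerSpec("soft tissue", 2.8),
)

#: Default actuator-disc centers (x, y) in mm: lateral pairs at +-6 cm,
#: vertical separation 32 mm. The vertical pairs overlap (32 mm < the 45 mm
#: disc diameter) and merge into a single two-lobed roller footprint.
DEFAULT_ACTUATOR_CENTERS_MM: tuple[tuple[float, float], ...] = (
    (60.0, 16.0),
    (60.0, -16.0),
    (-60.0, 16.0),
    (-60.0, -16.0),
)

ACTUATOR_RADIUS_MM = 22.5  # 45 mm contact-disc diameter


def property_table() -> Mapping[str, TissueProperties]:
    """Per-tissue thermal and perfusion constants.

    Returns a read-only mapping from tissue label to :class:`TissueProperties`.
    Blood temperatures are stored in degC (309.7 K -> 36.55 degC). The heated
    actuators are represented as boundary conditions, not as a meshed solid,
    so no actuator material appears here.
    """
    return MappingProxyType(_PROPERTIES)


@dataclass
class AnatomyVolume:
    """Voxelized tissue-label grid with isotropic physical spacing.

    ``labels[i, j, k]`` is an index into ``label_names``; axes are (x, y, z).
    """

    labels: np.ndarray
    spacing_mm: float
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)

    # -- geometry -----------------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.dims
        s = self.spacing_mm
        return (nx * s, ny * s, nz * s)

    @property
    def x_centers_mm(self) -> np.ndarray:
        nx = self.dims[0]
        s = self.spacing_mm
        return (np.arange(nx) + 0.5) * s - nx * s / 2.0

    @property
    def y_centers_mm(self) -> np.ndarray:
        ny = self.dims[1]
        s = self.spacing_mm
        return (np.arange(ny) + 0.5) * s - ny * s / 2.0

    @property
    def z_centers_mm(self) -> np.ndarray:
        nz = self.dims[2]
        return (np.arange(nz) + 0.5) * self.spacing_mm

    # -- labels -------------------------------------------------------------
    def code_of(self, name: str) -> int:
        try:
            return self.label_names.index(name)
        except ValueError:
            raise KeyError(f"tissue {name!r} not present in this volume") from None

    def label_at(self, x_mm: float, y_mm: float, z_mm: float) -> str:
        """Tissue name of the voxel whose cell contains the given point."""
        s = self.spacing_mm
        nx, ny, nz = self.dims
        i = int(np.floor((x_mm + nx * s / 2.0) / s))
        j = int(np.floor((y_mm + ny * s / 2.0) / s))
        k = int(np.floor(z_mm / s))
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise ValueError("point outside the anatomy domain")
        return self.label_names[self.labels[i, j, k]]

    def counts(self) -> dict[str, int]:
        """Voxel count per tissue label."""
        binc = np.bincount(self.labels.ravel(), minlength=len(self.label_names))
        return {name: int(binc[c]) for c, name in enumerate(self.label_names)}


def _n_voxels(extent_mm: float, spacing_mm: float) -> int:
    # round up to whole voxels; tolerate float fuzz when spacing divides extent
    n = int(np.ceil(extent_mm / spacing_mm - 1e-9))
    if n < 1:
        raise ValueError("extent smaller than one voxel")
    return n


def build_layered_anatomy(
    layers: Sequence[TissueLayerSpec] = DEFAULT_LAYERS,
    lateral_extent_mm: float = 300.0,
    vertical_extent_mm: float = 200.0,
    depth_extent_mm: float = 100.0,
    spacing_mm: float = 1.0,
    fill_label: str | None = None,
) -> AnatomyVolume:
    """Stack tissue slabs along depth into a voxelized phantom.

    Layers are laid posterior-to-anterior in the given order; any depth beyond
    the cumulative stack is filled with ``fill_label`` (default: the last
    layer's tissue). A voxel belongs to the layer containing its center.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    layers = list(layers)
    if not layers:
        raise ValueError("layer list must not be empty")
    names = [ly.name for ly in layers]
    if len(set(names)) != len(names):
        raise ValueError("layer names must be unique within a stack")
    table = property_table()
    for name in names:
        if name not in table:
            raise KeyError(f"unregistered tissue {name!r}")
    total = sum(ly.thickness_mm for ly in layers)
    if depth_extent_mm < total:
        raise ValueError(
            f"depth extent {depth_extent_mm} mm shorter than layer stack {total} mm"
        )
    fill = fill_label if fill_label is not None else layers[-1].name
    if fill not in table:
        raise KeyError(f"unregistered fill tissue {fill!r}")

    label_names = tuple(dict.fromkeys(names + [fill]))
    nx = _n_voxels(lateral_extent_mm, spacing_mm)
    ny = _n_voxels(vertical_extent_mm, spacing_mm)
    nz = _n_voxels(depth_extent_mm, spacing_mm)

    z = (np.arange(nz) + 0.5) * spacing_mm
    column = np.full(nz, label_names.index(fill), dtype=np.int16)
    lower = 0.0
    for ly in layers:
        upper = lower + ly.thickness_mm
        inside = (z >= lower) & (z < upper)
        column[inside] = label_names.index(ly.name)
        lower = upper
    labels = np.broadcast_to(column, (nx, ny, nz)).copy()
    return AnatomyVolume(labels=labels, spacing_mm=spacing_mm, label_names=label_names)


@dataclass(frozen=True)
class SpineColumnSpec:
    """Concentric shell thicknesses (mm) of the spinal-column insert.

    The insert is a cylinder along the superior-inferior (y) axis: spinal cord
    core, then CSF, epidural fat and vertebra shells outward.
    """

    cord_mm: float = 1.9
    csf_mm: float = 2.9
    epidural_fat_mm: float = 2.2
    vertebra_mm: float = 15.0

    @property
    def outer_radius_mm(self) -> float:
        return self.cord_mm + self.csf_mm + self.epidural_fat_mm + self.vertebra_mm


def add_spine_column(
    vol: AnatomyVolume,
    column_spec: SpineColumnSpec | None = None,
    center_x_mm: float = 0.0,
    start_depth_mm: float = 20.0,
) -> AnatomyVolume:
    """Embed a concentric spinal column into a layered volume.

    ``column_spec=None`` disables the insert and returns the volume unchanged.
    The cylinder axis runs along y at ``x = center_x_mm`` and depth
    ``start_depth_mm + outer radius``; shells overwrite the layer labels.
    """
    if column_spec is None:
        return vol
    if start_depth_mm <= 0:
        raise ValueError("spine column would overlap the z=0 skin surface")
    outer = column_spec.outer_radius_mm
    center_z = start_depth_mm + outer
    ex, _, ez = vol.extent_mm
    if center_z + outer > ez:
        raise ValueError("spine column does not fit within the depth extent")
    if abs(center_x_mm) + outer > ex / 2.0:
        raise ValueError("spine column does not fit within the lateral extent")

    shells = [
        ("vertebrae", outer),
        ("epidural fat", outer - column_spec.vertebra_mm),
        ("CSF", outer - column_spec.vertebra_mm - column_spec.epidural_fat_mm),
        ("spinal cord", column_spec.cord_mm),
    ]
    label_names = tuple(dict.fromkeys(vol.label_names + tuple(n for n, _ in shells)))
    labels = vol.labels.astype(np.int16).copy()
    x = vol.x_centers_mm[:, None]
    z = vol.z_centers_mm[None, :]
    r = np.hypot(x - center_x_mm, z - center_z)  # (nx, nz), independent of y
    plane = labels[:, 0, :].copy()
    for name, radius in shells:  # outer -> inner, inner discs overwrite
        plane = np.where(r < radius, label_names.index(name), plane)
    labels = np.where(r[:, None, :] < outer, plane[:, None, :], labels)
    return AnatomyVolume(labels=labels, spacing_mm=vol.spacing_mm, label_names=label_names)


@dataclass(frozen=True)
class ActuatorLayout:
    """Heated contact discs on the skin surface (Dirichlet patches)."""

    centers_mm: tuple[tuple[float, float], ...] = DEFAULT_ACTUATOR_CENTERS_MM
    radius_mm: float = ACTUATOR_RADIUS_MM
    temperature_C: float = 45.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("actuator radius must be positive")
        if not (45.0 <= self.temperature_C <= 65.0):
            warnings.warn(
                f"actuator temperature {self.temperature_C} degC is outside the "
                "device's 45-65 degC operating range",
                stacklevel=2,
            )


@dataclass
class SurfaceAssignment:
    """Condition assigned to every z=0 surface voxel.

    ``codes`` is an (nx, ny) integer array with values UNCOVERED (0), MAT (1)
    or ACTUATOR (2); precedence actuator > mat > uncovered.
    """

    codes: np.ndarray
    actuator_temperature_C: float
    mat_temperature_C: float

    @property
    def actuator_mask(self) -> np.ndarray:
        return self.codes == ACTUATOR

    @property
    def mat_mask(self) -> np.ndarray:
        return self.codes == MAT

    @property
    def uncovered_mask(self) -> np.ndarray:
        return self.codes == UNCOVERED


def surface_condition_masks(
    vol: AnatomyVolume,
    actuators: ActuatorLayout | None,
    mat_temperature_C: float = 40.0,
    mat_half_width_mm: float | None = None,
) -> SurfaceAssignment:
    """Assign a thermal condition to each posterior-surface voxel.

    A voxel is "actuator" iff its center lies within a contact disc; remaining
    voxels are "mat" where covered by the heating mat (full surface unless
    ``mat_half_width_mm`` limits its lateral half-width), else uncovered
    (convective). Discs clipped by the domain edge raise; discs overlapping
    each other merge (they share one temperature) with a warning.
    """
    nx, ny, _ = vol.dims
    codes = np.zeros((nx, ny), dtype=np.int8)
    x = vol.x_centers_mm[:, None]
    y = vol.y_centers_mm[None, :]

    if mat_half_width_mm is None:
        codes[:] = MAT
    else:
        codes[np.broadcast_to(np.abs(x) <= mat_half_width_mm, (nx, ny))] = MAT

    act_T = float("nan")
    if actuators is not None and len(actuators.centers_mm) > 0:
        act_T = actuators.temperature_C
        r = actuators.radius_mm
        ex, ey, _ = vol.extent_mm
        centers = [tuple(c) for c in actuators.centers_mm]
        for cx, cy in centers:
            if abs(cx) + r > ex / 2.0 or abs(cy) + r > ey / 2.0:
                raise ValueError(
                    f"actuator disc at ({cx}, {cy}) mm extends beyond the surface"
                )
        for i, (cx, cy) in enumerate(centers):
            for cx2, cy2 in centers[i + 1 :]:
                if np.hypot(cx - cx2, cy - cy2) < 2 * r:
                    warnings.warn(
                        "overlapping actuator discs merge into one contact patch",
                        stacklevel=2,
                    )
                    break
        inside = np.zeros((nx, ny), dtype=bool)
        for cx, cy in centers:
            inside |= (x - cx) ** 2 + (y - cy) ** 2 < r**2
        codes[inside] = ACTUATOR

    return SurfaceAssignment(
        codes=codes,
        actuator_temperature_C=act_T,
        mat_temperature_C=mat_temperature_C,
    )
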