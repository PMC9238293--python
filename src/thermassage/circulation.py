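"""Temperature-dependent circulation transfer model.

Maps a local temperature elevation ``dT`` (degC above the unheated baseline)
to blood flow ``F`` (L/min), bounded by a baseline flow ``F_o`` and a maximal
flow ``F_max``. The default functional form is the logistic

    F(dT) = F_o + (F_max - F_o) / (1 + exp(a dT + b)),

which rises sigmoidally from F_o to F_max as dT grows (slope parameter
``a < 0``). Two alternative forms are kept for comparison: an unbounded
exponential ``F_o + (F_max - F_o) exp(-(a dT + b))`` and the same expression
clamped at F_max. Free parameters (a, b) are calibrated by least squares
against simultaneous deep-muscle temperature / femoral-artery flow
measurements taken in the leg during passive heat stress.

Flow values carry the units of the calibration measurements (whole-limb
arterial L/min); applied voxelwise they are model outputs indicating relative
perfusion state, and fold-changes over F_o are the robust summary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bioheat import TemperatureField

__all__ = [
    "FlowMeasurement",
    "FlowModelParams",
    "FlowField",
    "FORMS",
    "LEG_BASELINE_C",
    "CORE_TEMPERATURE_C",
    "calibration_measurements",
    "predict_flow",
    "fit_flow_model",
    "flow_field",
    "form_resolution_oracle",
]

FORMS = ("logistic", "printed_exp", "clamped_exp")

#: Lowest calibration temperature; the unheated reference for the leg data.
LEG_BASELINE_C = 34.9
#: Unheated reference for back predictions.
CORE_TEMPERATURE_C = 37.0


@dataclass(frozen=True)
class FlowMeasurement:
    """One simultaneous (deep-muscle temperature, arterial flow) observation."""

    temperature_C: float
    flow_L_min: float

    def __post_init__(self) -> None:
        if self.flow_L_min <= 0:
            raise ValueError("flow must be positive")


@dataclass(frozen=True)
class FlowModelParams:
    """Fitted transfer-model parameters."""

    F_o: float
    F_max: float
    a: float
    b: float
    form: str = "logistic"
    sse: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.F_max > self.F_o > 0):
            raise ValueError("require F_max > F_o > 0")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")


@dataclass
class FlowField:
    """Voxelwise predicted flow (L/min) and fold-change over baseline."""

    values: np.ndarray
    fold_change: np.ndarray
    spacing_mm: float
    params: FlowModelParams


def calibration_measurements() -> tuple[FlowMeasurement, ...]:
    """The packaged leg heat-stress calibration pairs."""
    ref = importlib.resources.files("thermassage.data") / "leg_heat_stress_calibration.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return tuple(
        FlowMeasurement(float(r.temperature_C), float(r.flow_L_min))
        for r in df.itertuples()
    )


def predict_flow(delta_T, params: FlowModelParams):
    """Evaluate the transfer model at a temperature elevation (degC).

    Total on any finite input; scalar in, scalar out; array in, array out.
    The logistic form is strictly increasing in ``delta_T`` for ``a < 0`` and
    bounded in (F_o, F_max).
    """
    dT = np.asarray(delta_T, dtype=float)
    z = np.clip(params.a * dT + params.b, -500.0, 500.0)
    span = params.F_max - params.F_o
    if params.form == "logistic":
        out = params.F_o + span / (1.0 + np.exp(z))
    elif params.form == "printed_exp":
        out = params.F_o + span * np.exp(-z)
    elif params.form == "clamped_exp":
        out = np.minimum(params.F_o + span * np.exp(-z), params.F_max)
    else:  # pragma: no cover - guarded by FlowModelParams
        raise ValueError(params.form)
    return out if out.ndim else float(out)


#: Fixed multistart grid for the (a, b) fit; first entry is the canonical
#: initialization, the rest guard against local minima. Deterministic.
_INIT_GRID: tuple[tuple[float, float], ...] = (
    (-1.0, 1.0),
    (-0.5, 0.5),
    (-2.0, 2.0),
    (-4.0, 4.0),
    (-8.0, 8.0),
)


def fit_flow_model(
    data: Sequence[FlowMeasurement],
    baseline_temperature_C: float = LEG_BASELINE_C,
    form: str = "logistic",
) -> FlowModelParams:
    """Least-squares fit of (a, b) to calibration measurements.

    ``F_o`` is assigned the minimum measured flow and ``F_max`` the flow at
    the highest measured temperature (not refit). Elevations are
    ``dT = T - baseline_temperature_C``. The optimizer runs from a fixed grid
    of initial points (tolerance 1e-10 on parameter change); lowest SSE wins,
    ties broken by grid order. Deterministic.
    """
    data = list(data)
    if len(data) < 3:
        raise ValueError("need at least 3 measurements to fit (a, b)")
    temps = np.array([m.temperature_C for m in data])
    flows = np.array([m.flow_L_min for m in data])
    if len(set(temps.tolist())) != len(temps):
        raise ValueError("measurement temperatures must be distinct")
    if np.allclose(flows, flows[0]):
        raise ValueError("degenerate data: all flows equal")

    F_o = float(flows.min())
    F_max = float(flows[int(np.argmax(temps))])
    if not F_max > F_o:
        raise ValueError("flow at the highest temperature must exceed the minimum flow")
    dT = temps - baseline_temperature_C

    def residuals(theta):
        p = FlowModelParams(F_o=F_o, F_max=F_max, a=theta[0], b=theta[1], form=form)
        return predict_flow(dT, p) - flows

    best = None
    for a0, b0 in _INIT_GRID:
        res = least_squares(residuals, x0=(a0, b0), xtol=1e-10, ftol=1e-14, gtol=1e-12)
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, res.x)
    sse, (a, b) = best
    if not np.isfinite(sse):
        raise RuntimeError("flow-model fit did not converge")
    return FlowModelParams(F_o=F_o, F_max=F_max, a=float(a), b=float(b), form=form, sse=sse)


def flow_field(
    temps: TemperatureField,
    baseline: TemperatureField,
    params: FlowModelParams,
) -> FlowField:
    """Apply the transfer model voxelwise: ``F(T - T_baseline)``."""
    if temps.dims != baseline.dims or temps.spacing_mm != baseline.spacing_mm:
        raise ValueError("temperature and baseline grids are not congruent")
    values = predict_flow(temps.values - baseline.values, params)
    return FlowField(
        values=values,
        fold_change=values / params.F_o,
        spacing_mm=temps.spacing_mm,
        params=params,
    )


def form_resolution_oracle(
    data: Sequence[FlowMeasurement] | None = None,
    baseline_temperature_C: float = LEG_BASELINE_C,
    printed_params: tuple[float, float] = (-2.67, 4.88),
) -> pd.DataFrame:
    """Compare candidate functional forms on the calibration data.

    Fits each form by least squares and additionally evaluates the unbounded
    exponential at the externally printed (a, b); reports SSE, the fitted
    parameters, the maximum prediction over the calibration range, and
    whether the form overshoots F_max. Documents why the logistic is the
    default resolution of the transfer model.
    """
    if data is None:
        data = calibration_measurements()
    temps = np.array([m.temperature_C for m in data])
    dT = temps - baseline_temperature_C
    rows = []
    for form in FORMS:
        p = fit_flow_model(data, baseline_temperature_C, form=form)
        pred = np.asarray(predict_flow(dT, p))
        rows.append({
            "form": form,
            "a": p.a,
            "b": p.b,
            "sse": p.sse,
            "max_prediction": float(pred.max()),
            "overshoots_Fmax": bool((pred > p.F_max + 1e-9).any()),
        })
    # the printed exponential evaluated at the printed parameter values
    a, b = printed_params
    flows = np.array([m.flow_L_min for m in data])
    p_printed = FlowModelParams(
        F_o=float(flows.min()),
        F_max=float(flows[int(np.argmax(temps))]),
        a=a, b=b, form="printed_exp",
    )
    pred = np.asarray(predict_flow(dT, p_printed))
    rows.append({
        "form": "printed_exp @ printed (a, b)",
        "a": a,
        "b": b,
        "sse": float(np.sum((pred - flows) ** 2)),
        "max_prediction": float(pred.max()),
        "overshoots_Fmax": bool((pred > p_printed.F_max + 1e-9).any()),
    })
    return pd.DataFrame(rows)
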