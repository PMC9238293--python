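import warnings

import numpy as np
import pytest

from thermassage.anatomy import (
    ActuatorLayout,
    build_layered_anatomy,
    property_table,
    surface_condition_masks,
)
from thermassage.bioheat import (
    SteadySolveOptions,
    ThermalBoundarySpec,
    assemble_steady_system,
    solve_steady,
)
from thermassage.circulation import calibration_measurements, fit_flow_model


@pytest.fixture(scope="session")
def props():
    return property_table()


@pytest.fixture(scope="session")
def fitted_params():
    """Logistic transfer model fitted to the packaged calibration pairs."""
    return fit_flow_model(calibration_measurements())


def build_default_scene(spacing_mm, actuator_temperature_C=45.0):
    """Default phantom + four-disc layout at the given spacing, assembled."""
    vol = build_layered_anatomy(spacing_mm=spacing_mm)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="overlapping actuator discs")
        surface = surface_condition_masks(
            vol, ActuatorLayout(temperature_C=actuator_temperature_C), 40.0
        )
    system = assemble_steady_system(vol, property_table(), ThermalBoundarySpec(surface=surface))
    return vol, system


@pytest.fixture(scope="session")
def coarse_scene():
    """Default scene at 4 mm spacing with 45 and 65 degC solutions."""
    vol, system = build_default_scene(4.0)
    opts = SteadySolveOptions()
    t45 = solve_steady(system, opts, rhs=system.rhs(actuator_temperature_C=45.0))
    t65 = solve_steady(system, opts, rhs=system.rhs(actuator_temperature_C=65.0),
                       x0=t45.values)
    return {"volume": vol, "system": system, "t45": t45, "t65": t65}
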