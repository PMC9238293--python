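#!/usr/bin/env python
"""Independent verification of the steady bio-heat solver.

Two oracles: the closed-form perfused-slab solution (1D column configured
through the 3D assembly path) and a manufactured trigonometric solution with
its implied source (grid-convergence order). Writes
results/solver_verification.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermassage.anatomy import (
    TissueLayerSpec,
    build_layered_anatomy,
    property_table,
    surface_condition_masks,
)
from thermassage.bioheat import (
    SteadySolveOptions,
    ThermalBoundarySpec,
    analytic_slab_1d,
    assemble_steady_system,
    manufactured_solution_check,
    solve_steady,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    props = property_table()

    s = 0.5
    vol = build_layered_anatomy([TissueLayerSpec("muscle", 50.0)], s, s, 50.0, s)
    surf = surface_condition_masks(vol, None, mat_temperature_C=45.0)
    system = assemble_steady_system(
        vol, props,
        ThermalBoundarySpec(surface=surf, cut_temperature_C=37.0,
                            lateral_mode="adiabatic"))
    field = solve_steady(system, SteadySolveOptions(rtol=1e-10))
    p = props["muscle"]
    exact = analytic_slab_1d(p.k, p.rho_b, p.c_b, p.w_b, p.T_b, p.Q_m,
                             50.0, 45.0, 37.0, vol.z_centers_mm)
    linf = float(np.max(np.abs(field.values.ravel() - exact)))
    lam = float(np.sqrt(p.k / (p.rho_b * p.c_b * p.w_b)) * 1000)
    print(f"perfused muscle slab (45 -> 37 degC, 0.5 mm): L_inf error {linf:.2e} degC")
    print(f"  thermal penetration length lambda = {lam:.1f} mm")

    mms = manufactured_solution_check()
    print(f"manufactured solution: L2 errors {['%.2e' % e for e in mms['l2_errors']]} "
          f"at {mms['spacings_mm']} mm -> order {mms['order']:.2f}")

    report = {"slab_linf_C": linf, "lambda_muscle_mm": lam, **mms}
    (OUT / "solver_verification.json").write_text(json.dumps(report, indent=2) + "\n")
    ok = linf < 0.05 and mms["order"] >= 1.8
    print("solver verification", "PASSED" if ok else "FAILED")
    if not ok:
        raise SystemExit(1)


if __name__ == "__main__":
    main()
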