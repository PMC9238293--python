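#!/usr/bin/env python
"""Solve the 45 and 65 degC heating scenes and report the standard probes.

Builds the default layered lumbar phantom, solves the steady bio-heat
problem for the two bracketing actuator settings, couples the fields to the
circulation model, and prints the depth probes under the actuator centroid
and at the midline. Writes per-scene profile tables under results/.

Defaults to a 2 mm grid (about half a minute); pass --spacing 1 for the
production grid used by scripts/acceptance.py.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermassage.bioheat import baseline_field, solve_steady
from thermassage.circulation import flow_field
from thermassage.config import default_config
from thermassage.profiles import depth_profile, standard_depths, standard_profiles
from thermassage.runner import build_scene, fit_from_config, solve_scene, _write_outputs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--spacing", type=float, default=2.0)
    args = parser.parse_args()

    cfg = default_config().model_copy(update={})
    cfg = cfg.model_copy(update={
        "anatomy": cfg.anatomy.model_copy(update={"spacing_mm": args.spacing}),
        "outputs": cfg.outputs.model_copy(update={"formats": ["csv"]})})
    params = fit_from_config(cfg)
    scene = build_scene(cfg)
    base = baseline_field(scene.volume, cfg.circulation.core_temperature_C)

    fields = {}
    fields[45.0] = solve_scene(scene, actuator_temperature_C=45.0)
    fields[65.0] = solve_steady(scene.system, scene.options,
                                rhs=scene.system.rhs(actuator_temperature_C=65.0),
                                x0=fields[45.0].values)
    ax, ay = scene.actuator_anchor_mm
    for setting, temp in fields.items():
        flow = flow_field(temp, base, params)
        print(f"\n=== actuators at {setting:g} degC "
              f"({temp.diagnostics['iterations']} CG iterations) ===")
        for label, (px, py) in (("actuator centroid", (ax, ay)), ("midline", (0.0, 0.0))):
            t = depth_profile(temp, px, py, [10.0, 20.0, 30.0, 40.0])
            f = depth_profile(flow, px, py, [10.0, 20.0, 30.0, 40.0])
            print(f"  {label} (x={px:g}, y={py:g} mm):")
            for d, tv, fv in zip(t.coordinate_mm, t.values, f.values):
                print(f"    depth {d:4.0f} mm: {tv:6.2f} degC   "
                      f"{fv:.3f} L/min ({fv / params.F_o:.2f}x baseline)")
        profs = standard_profiles(temp, flow, (ax, ay), standard_depths(scene.volume))
        _write_outputs(OUT / f"scene_{setting:g}C", cfg, scene.volume, temp, flow, profs)
    print(f"\nwrote per-scene profile tables under {OUT}/scene_45C and scene_65C")


if __name__ == "__main__":
    main()
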