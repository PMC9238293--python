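#!/usr/bin/env python
"""Calibrate the temperature-to-flow transfer model.

Fits the logistic transfer model to the five simultaneous deep-muscle
temperature / femoral-artery flow measurements taken in the leg during
passive heat stress, and compares the candidate functional forms (logistic,
unbounded exponential, clamped exponential) on the same data.

Writes results/circulation_fit.json and results/form_comparison.csv.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermassage.circulation import (
    LEG_BASELINE_C,
    calibration_measurements,
    fit_flow_model,
    form_resolution_oracle,
    predict_flow,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    data = calibration_measurements()
    params = fit_flow_model(data, LEG_BASELINE_C)
    dT = np.array([m.temperature_C for m in data]) - LEG_BASELINE_C
    fitted = np.asarray(predict_flow(dT, params))

    print("Calibration pairs (T degC -> F L/min) and the fitted logistic:")
    for m, f in zip(data, fitted):
        print(f"  {m.temperature_C:5.1f}  measured {m.flow_L_min:.2f}   fitted {f:.3f}")
    print(f"\nfit: a = {params.a:.4f} per degC, b = {params.b:.4f}, "
          f"SSE = {params.sse:.4f} (L/min)^2")
    print(f"resting flow F(0) = {float(predict_flow(0.0, params)):.3f} L/min; "
          f"saturation F_max/F_o = {params.F_max / params.F_o:.2f}x")

    report = form_resolution_oracle(data)
    print("\nFunctional-form comparison (the unbounded exponential printed")
    print("form overshoots F_max and is not sigmoidal; logistic is default):")
    print(report.to_string(index=False))

    (OUT / "circulation_fit.json").write_text(json.dumps({
        "F_o": params.F_o, "F_max": params.F_max,
        "a": params.a, "b": params.b, "form": params.form, "sse": params.sse,
    }, indent=2) + "\n")
    report.to_csv(OUT / "form_comparison.csv", index=False, float_format="%.6g")
    print(f"\nwrote {OUT / 'circulation_fit.json'} and {OUT / 'form_comparison.csv'}")


if __name__ == "__main__":
    main()
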