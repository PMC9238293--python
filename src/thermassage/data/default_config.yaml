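# Default thermal-massage scene: four 45 mm actuator discs at 45 degC
# (lateral positions +-60 mm, vertical separation 32 mm) over a 40 degC
# heating mat covering the posterior surface of a layered lumbar phantom;
# domain cuts held at 37 degC core temperature.
anatomy:
  layers:
    - {name: skin, thickness_mm: 1.1}
    - {name: subcutaneous fat, thickness_mm: 13.0}
    - {name: muscle, thickness_mm: 42.0}
    - {name: soft tissue, thickness_mm: 2.8}
  lateral_extent_mm: 300.0
  vertical_extent_mm: 200.0
  depth_extent_mm: 100.0
  spacing_mm: 1.0
  spine:
    enabled: false
sources:
  actuators:
    centers_mm: [[60.0, 16.0], [60.0, -16.0], [-60.0, 16.0], [-60.0, -16.0]]
    radius_mm: 22.5
    temperature_C: 45.0
  mat_temperature_C: 40.0
  h_W_m2K: 5.0
  ambient_C: 25.0
  cut_temperature_C: 37.0
solver:
  rtol: 1.0e-8
  maxiter: 20000
  coarse_init: true
circulation:
  form: logistic
  fit_baseline_C: 34.9
  core_temperature_C: 37.0
  calibration: builtin
outputs:
  directory: runs
  formats: [csv, npz]
sweep_temperatures_C: [45.0, 50.0, 55.0, 60.0, 65.0]
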