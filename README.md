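# emca

Simulation and analysis toolkit for **electrochemical melting-curve
analysis (éMCA)** SNP genotyping, plus the thermal-control stack that
drives it. The package models the full desk-scale experiment:

- **`emca.thermal`** — first-order-plus-dead-time (FOPDT) heating-plate
  simulation, two-point plant identification from step responses
  (28.3% / 63.2% rise times, τ = 1.5·Δt), a discrete PI controller with
  10-bit PWM-quantized actuation, anti-windup, staircase ramp protocols,
  step-response metrics (rise/settling/overshoot) and linear temperature
  calibration.
- **`emca.melt`** — two-state van't Hoff model of the hybridized fraction
  of a surface-tethered duplex, position-dependent single-mismatch Tm
  penalties (middle > top > bottom), a +10 °C surface→solution offset,
  and irreversible washing (running-minimum signal).
- **`emca.swv`** — square-wave voltammogram synthesis (Gaussian ferrocene
  oxidation peak on a linear baseline, 0–0.7 V window, 10 mV steps) and
  baseline-corrected peak-height extraction.
- **`emca.pipeline`** — melt-curve normalization to the pre-melt signal,
  first-derivative Tm calling (moving-average smoothing, central
  differences, optional parabolic refinement), replicate aggregation
  (mean ± sample SD) and ΔTm genotype calls.
- **`emca.simulate`** — end-to-end seeded experiment generator: a
  9-electrode array (4 alleles in duplicate + 1 ferrocene-thiol control)
  ramped 25→95 °C at 1 °C/step, emitting a voltammogram series and a
  ground-truth table; also matched fluorescence melt curves.
- **`emca.io` / `emca.config` / `emca.cli`** — CSV formats, strict
  YAML/JSON config resolution, run manifests and the `emca` CLI.

## CLI

```sh
# synthesize an experiment (voltammograms.csv, truth.csv, resolved config, manifest)
emca simulate --out run/ --seed 5

# analyze it: peak heights -> melt curves -> Tm calls -> genotype report
emca analyze --input run/voltammograms.csv --modality swv \
    --smooth 3 --interpolate --wt-electrodes e1,e2 --threshold 2.0 \
    --out report.csv --plot curves.png

# identify a heating plate from a recorded step response
emca identify --input trace.csv --step-magnitude 3.0 --noise-sd 0.1

# run the PI + PWM loop through a staircase ramp on the demo plate
emca tune --plant demo --kc 55.85 --ki 1.33 --ramp 25:90:1 --dwell 30

# print the fully resolved default configuration
emca config --show
```

Exit codes: `0` success, `2` validation/configuration error, `3` analysis
failure (no melting transition on any electrode).

Fluorescence melts use `--modality fluorescence` on both `simulate` and
`analyze`; `analyze` also accepts a pre-extracted peak-height table
(`electrode_id,temperature_C,height`).

## File formats

- Voltammogram series: `electrode_id,temperature_C,potential_V,current`
  (long format, one row per grid point).
- Closed-loop traces: `time_s,setpoint_C,plate_C,slide_C,actuation`.
- Fluorescence curves: `temperature_C,intensity` (optional `allele`).
- Tm report: `electrode_id,tm_C,mean,sd,n,call,delta_tm`.

All outputs are deterministic for a fixed seed; every CLI run writes a
JSON manifest with config, seed and SHA-256 digests of inputs/outputs.
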