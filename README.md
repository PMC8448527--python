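# sparklet

Quantal analysis of optical single-channel Ca²⁺ "sparklet" recordings,
plus the pressure-myography and luminal-flow metrics that usually
accompany them — with a stochastic gating simulator that produces
synthetic recordings with known ground truth, so every stage of the
analysis is verifiable without experimental data.

## What it does

- **`sparklet.gating_sim`** — continuous-time Markov simulation of N
  independent two-state (closed/open) channels per site; renders F/F₀
  traces (per-open-channel increment q = 0.29 ΔF/F₀ by default, additive
  Gaussian noise, optional bleaching) and whole-field movies with sites
  as 2-D Gaussian footprints. Exports per-frame open-channel counts and
  analytic stationary targets as ground truth.
- **`sparklet.trace_ops`** — per-pixel Kalman stack filtering (gain 0.8,
  acquisition noise variance 0.05 by default; fixed-gain mode available
  for closed-form testing), zero-phase Gaussian low-pass with a −3 dB
  corner at 4 Hz for display, 5×5-pixel ROI F/F₀ extraction, sparklet
  event detection (≥5 steady baseline points and ≥5 steady peak points),
  and trapezoidal area under the curve of (F − F₀)/F₀ over seconds.
- **`sparklet.quantal`** — all-points amplitude histograms, weighted
  least-squares multi-Gaussian mixture fitting (shared baseline, optional
  equal-spacing constraint μᵢ = μ₀ + i·q, component count by BIC),
  nearest-level idealization with half-amplitude hysteresis, dwell times,
  NP_O = (T₁ + 2T₂ + 3T₃ + 4T₄)/T_total, and sparklet sites per cell.
- **`sparklet.vessel`** — percent constriction, percent dilation
  (normalized to the passive Ca²⁺-free diameter), myogenic tone, and
  Poiseuille wall shear stress τ = 4μQ̇/(πr³) in dyn/cm² with explicit
  unit conversion (cP, µL/min, µm accepted; units are never guessed).
- **`sparklet.io` / `sparklet.config` / `sparklet.pipeline`** — CSV
  traces/events/results, ImageJ-compatible 16-bit TIFF movies,
  schema-validated run configuration (JSON or YAML), and a deterministic
  end-to-end pipeline whose result bundles carry full config provenance.

## CLI

```sh
sparklet simulate --seed 1 --out sim/            # synthetic traces + truth JSON
sparklet filter in.tif out.tif                   # Kalman stack filter
sparklet detect sim/site0_trace.csv --out events.csv
sparklet quantal sim/site0_trace.csv --out site.json   # NP_O, q̂, levels
sparklet vessel diameters.csv --out metrics.csv
sparklet run --seed 1 --out run/                 # full pipeline -> bundle.json
```

All randomness flows from a single seed via `numpy.random.SeedSequence`
splitting; identical config + seed reproduce byte-identical results.

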