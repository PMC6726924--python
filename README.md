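# pswarp

Phase-space-warping analysis of fatigue vibration time series.

A fatiguing structure driven by fast cyclic loading accumulates damage on a
much slower time scale; the damage feeds back on the fast dynamics as a
quasi-stationary parameter drift. `pswarp` tracks that drift from a single
scalar measurement channel:

1. **moonbeam** — a synthetic-data generator: a two-well (magnetoelastic-beam
   type) oscillator driven near its 9–10 Hz in-well resonance, whose stiffness
   degrades through one or two hidden slow damage variables (a slow "ductile"
   channel gated on small-amplitude motion and a fast "brittle" channel gated
   on extreme cross-well excursions), measured as noisy displacement and run
   until failure.
2. **embed** — delay-coordinate reconstruction with automatic delay selection
   (first minimum of average mutual information) and dimension selection
   (false nearest neighbors).
3. **track** — partitions the measurement into observation-interval records,
   summarizes each record's embedded trajectory by its mean distances to a
   fixed set of reference points chosen from the first (healthiest) record,
   and stacks the feature vectors into a tracking matrix `X` with temporal
   derivative `V`.
4. **sod** — smooth orthogonal decomposition: the generalized eigenproblem
   `Σ_X φ = λ Σ_V φ` whose eigenvalues (SOVs) sort feature-space directions
   by time scale (for a pure harmonic, SOV = 1/ω²), with proper orthogonal
   decomposition as the variance-ordered reference.
5. **assess** — counts damage modes as SOVs isolated from the continuum
   (log-gap rule), labels slow/fast groups as ductile-like/brittle-like,
   screens smooth coordinates against permutation surrogates, and detects the
   terminal amplitude surge that precedes failure.
6. **pipeline / cli** — reproducible end-to-end orchestration, fixture
   generation, and a validation mode that correlates recovered coordinates
   with the simulator's hidden damage trajectories.

## CLI

```bash
# simulate a two-mode accelerated fatigue run to CSV
pswarp simulate --preset two-mode --seed 1 --out run1.csv

# analyze a measurement file (or simulate-and-analyze a preset)
pswarp analyze --input run1.csv --seed 1 --out run1_results/
pswarp analyze --sim-preset run-to-failure --seed 1 --out rtf_results/

# deterministic test datasets
pswarp fixtures --kind harmonic --seed 0 --out fixtures/

# parameter-recovery report against the hidden damage trajectory
pswarp validate --run run1_results/ --damage run1_results/measurement.damage.csv
```

Simulator configs are flat YAML files mirroring `SimConfig` (or
`preset: two-mode` plus overrides); pipeline configs mirror `PipelineConfig`
and `EmbeddingOptions` fields. A run directory contains `sovs.csv`,
`socs.csv`, `tracking_X.csv`, `assessment.json` and a `manifest.json` keyed
by the config hash (re-running with the same config and seed is skipped
unless `--force`).

The hidden damage trajectory is always written to a separate file
(`*.damage.csv` or `/damage/<label>` in HDF) that the analysis pipeline never
reads; only `pswarp validate` / `pswarp.recovery` consume it.

## Reproducibility

Every source of randomness (initial conditions, measurement noise, reference
sampling, permutation surrogates) derives from a single seed through named,
independent streams; identical config + seed reproduces bitwise-identical
outputs. The integrator is fixed-step classical RK4 (sampling interval / 20
by default).
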