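# nablock

Low-dimensional modeling of state-dependent sodium-channel block.

The model has three variables: Hodgkin–Huxley gating (`m`, `h`, with
`f_open = m³h(1−b)` and rates of the form `c1·exp(V/c2)`) plus a drug-bound
fraction `b` that grows only from inactivated channels
(`db/dt = k_on[D](1−h)(1−b) − k_off·b`) and locks them inactivated until the
drug unbinds. On top of that core the package provides:

- **`nablock.gating`** — parameter/state types, steady states and time
  constants, current, equilibria, and stiff ODE integration of (m, h, b)
  under arbitrary voltage waveforms (`nablock.waveforms`).
- **`nablock.protocols`** — voltage-clamp protocols: steady-state
  availability and activation, time to half inactivation (decay and
  recovery branches), activation time constant, tonic block, use-dependent
  block (dose and frequency scans), recovery from use-dependent block, and
  the mean-squared-error metric. Drug-free protocols run on exact
  closed-form gate propagation, so they are fast enough for optimizer loops.
- **`nablock.fitting`** — bounded multistart least squares for the 8
  drug-free gating coefficients (drug kinetics are literature constants and
  are never fitted).
- **`nablock.ratedep`** — closed-form theory of rate-dependent block under
  periodic pacing: the square-wave action potential approximation, the
  piecewise-exponential solution for `b`, the upstroke fixed point `b*`, its
  derivative with respect to the pacing cycle length along a restitution
  curve, the critical restitution slope, sensitivity scans, and independent
  numerical oracles (iterated pacing map, ODE pacing).
- **`nablock.fixtures`** — synthetic ground-truth data: a gating parameter
  preset, noiseless/noisy clamp datasets, parametric restitution curves, and
  periodic AP waveforms. These emulate the *shapes* of published clamp
  curves; they are not digitized experimental data.
- **`nablock.io` / `nablock.cli`** — YAML parameter files, dataset/trajectory
  CSV with JSON sidecars, and the `nablock` command-line tool.

The packaged default parameter set (`nablock.fitted_default()`) is the
result of fitting the 8 coefficients to the packaged noiseless fixture; it
ships with its provenance in `src/nablock/data/default_fitted_params.json`
and can be regenerated with `python scripts/refit_default_params.py`.

## CLI

```sh
nablock generate-fixtures --out out/fixtures --seed 20210614
nablock fit --manifest out/fixtures/manifest.json --out out/fit
nablock simulate-clamp --protocol availability --drug-conc-um 20 --out out/clamp
nablock rate-dependence --drug-conc-um 20 --bcl-min 300 --bcl-max 1000 --out out/rd
nablock ap-clamp --kind trapezoid --ramp-ms 2 --cycles 20 --out out/ap
```

Every command echoes its resolved configuration to `run_config.json` in the
output directory. Concentrations on the CLI and in parameter files are
micromolar; internal units are mV / ms / molar throughout.

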