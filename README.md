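# molsynapse

Simulation and analysis toolkit for a peptide molecular-junction artificial
synapse: continuum ion/electron transport, hopping kinetics, synaptic
plasticity metrics, and physical reservoir computing.

## What is in the box

| Module | Purpose |
| --- | --- |
| `molsynapse.signals` | Voltage pulse/protocol data model, standard protocol builders (pulse trains, paired pulses, write/read endurance cycles), lossless CSV trace I/O with JSON metadata side-cars |
| `molsynapse.pnp` | 1-D coupled Poisson–Nernst–Planck solver (finite volumes, Scharfetter–Gummel fluxes, backward Euler, Gummel coupling) for cation/electron transport through a 4 nm molecular film; potentiation/depression simulation and potentiation-bias sweeps |
| `molsynapse.marcus` | Marcus hopping-rate evaluation, inverse-rate temperature curves, Arrhenius activation-energy fitting |
| `molsynapse.synapse` | Fast/slow two-timescale synapse surrogate (chemical gating ~150 ms, coordination ~80 s) with threshold-gated potentiation/depression, protocol driver, and an STDP spike-pair scheme |
| `molsynapse.plasticity` | Weight-change statistics (pulse-train Δwt, paired-pulse facilitation, pre/post-spike Δwt, current-change ratio) and multi-start single/double exponential relaxation fitting |
| `molsynapse.reservoir` | Sine/square waveform datasets, ±1 mask encoding, state collection from synapse nodes, least-squares readout, NRMSE/accuracy evaluation, fixed-size (M×N = 40) mask-length sweep |
| `molsynapse.cli` | `molsyn` command-line workbench |

## CLI

```bash
molsyn simulate-pnp --config cfg.yaml --out out/    # traces + decay fit (+ sweep)
molsyn simulate-pnp --no-injection                   # flat control device
molsyn plasticity trace.csv protocol.yaml --mode train|ppf|stdp|fit-decay
molsyn rc-run  --config rc.yaml --out rc_out/        # one RC evaluation
molsyn rc-sweep --config rc.yaml --out sweep_out/    # mask-length sweep
molsyn make-fixtures --out fixtures/                 # small example inputs
```

Configs are YAML; every command writes a `manifest.json` with config and
output digests. Identical configs and seeds reproduce identical outputs.

Example `cfg.yaml` for `simulate-pnp`:

```yaml
pnp: {n_grid: 128, dt: 1.0e-3}
schedule: {A: 1.0e-17, B: 3.0e-16, a: 6.8, b: -7.4, c: -3.4}
drive: {V_pot: -1.3, t_pot: 0.5, V_dep: 0.1, t_dep: 1.0}
sweep_voltages: [-0.6, -0.9, -1.2, -1.5]
```

## Notes on modelling choices

- The electron diffusion schedule models cation-enhanced hopping as a
  piecewise exponential in time; its dependence on the potentiation bias
  (growth rate up, fast depression rate down with over-threshold voltage) is
  an extension beyond the printed constants and is flagged in every trace's
  metadata.
- The synapse surrogate is a lumped two-state stand-in for speed (fitting
  fixtures, reservoir nodes); it claims no microscopic fidelity.
- Reservoir readout: ordinary least squares with a relative singular-value
  cutoff (`rcond`); repeated ±1 masks make the noise-free design exactly
  rank-deficient, and the cutoff keeps per-pulse read noise out of those
  null directions. Ridge regression is available behind a config flag.
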