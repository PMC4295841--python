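# multisyn

Models the interaction of synaptic plasticity (weight dynamics) and
stochastic, weight-dependent structural plasticity (synapse creation and
removal) on a single multi-synaptic connection between two rate-based
neurons.

A connection has `P` potential synaptic sites of which `S` are realised.
Every vacant site gains a synapse with probability `p_build` per step; every
realised synapse is removed with probability
`p_del(w) = p_build**rho * exp(-a**2 * w**q)` (default exponent `q = 4/3`),
so strong synapses survive longer. Between structural events the weights
relax to the fixed point of a configurable rate-based plasticity rule
(Hebb/BCM variants with hard bounds, sliding threshold, Oja, weight-dependent
synaptic scaling, or an empirically tabulated rule such as the
calcium-threshold spiking rule). The package provides:

- **`neuron_core`** — logistic/linear/empirical IO curves and the
  self-consistent `(v_i*, w*)` state per synapse count (grid scan +
  bisection, with multi-root detection).
- **`rate_rules`** — the rule library, closed-form fixed weights, and the
  two qualitative checkers: does the fixed weight grow with postsynaptic
  activity (necessary for a bimodal synapse-count distribution), and is the
  log-probability increment concave between its zero crossings (sufficient
  for the peak/valley order)?
- **`markov_structural`** — exact transition matrix and stationary
  distribution, the birth-death (one-change-per-step) closed form via
  detailed balance, `Δ_ln p` / `p_cf`–`p_d` analysis, the six-case shape
  classification, and continuous-`S` fixed-point (bifurcation) diagrams.
  All probability arithmetic is in log space.
- **`calcium_spiking`** — exact event-driven integration of the
  calcium-threshold plasticity rule (no time stepping), ensemble stationary
  weights under Poisson drive, and an AdEx forward-Euler f-I curve.
- **`stochastic_simulator`** — full time-stepped simulation (rates → RK4
  weights → delete → create) plus numba-accelerated pinned-weight fast paths
  for long occupancy runs and the triangular hysteresis protocol.
- **`fit_stats`** — Monte-Carlo goodness-of-fit p-values for sparse
  synapse-count histograms, activity confidence-region scans over
  `(v_j, v_i(S=0))` grids, mixtures over a prior on `P`, and equal-activity
  cline intersections.
- **`io_cli`** — TSV/JSON formats with provenance headers, YAML
  configuration, a synthetic experiment-fixture generator, and the CLI.

All chain results are *per structural time step*; the model deliberately
does not fix how long one step is in wall-clock time.
`StructuralParams.rate_scale` multiplies both creation and deletion
probabilities (clipped at 1) to compress simulated time without changing the
equilibrium distribution.

## CLI

Every subcommand is driven by one YAML config; see
`src/multisyn/io_cli/config.py` for the schema.

```bash
cat > model.yml <<'EOF'
structural: {ln_p_build: -16.0, rho: 0.125, a: 2.0, P: 12}
rule: {kind: bcm_scaling, mu: 0.2, theta: 0.08, kappa: 9.0, v_tss: 0.1}
neuron: {io: logistic}
point: {v_j: 0.656, v_i_S0: 0.2975}
rng: {seed: 0}
EOF

multisyn equilibrium --config model.yml --method first-step --out eq.tsv
multisyn classify    --config model.yml
multisyn bifurcation --config model.yml --varied post
multisyn simulate    --config model.yml --steps 100000 --out occ.tsv
multisyn hysteresis  --config model.yml --out hyst.tsv      # needs a protocol: section
multisyn make-fixture --zero-mass 0.9 --center 5 --out exp.tsv
multisyn confidence-region --config model.yml --experiment exp.tsv \
    --n-mc 1000 --grid-n 60 --out-grid grid.tsv --out-summary summary.json
multisyn ca-fixed-weight --rate-pre 8 --rate-post 10
multisyn fi-curve --i-min 600 --i-max 1450 --duration 2 --out fi.tsv
```

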