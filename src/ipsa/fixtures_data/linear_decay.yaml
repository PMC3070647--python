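# One-state exponential decay dx/dt = -k*x; closed-form solution e^{-k t}.
name: linear_decay
states: [x]
parameters: {k: 1.0}
reactions:
  - id: decay
    rate: k*x
    stoichiometry: {x: -1}
initial_conditions: {x: 1.0}
simulation: {t_start: 0.0, t_end: 5.0, n_points: 101}
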