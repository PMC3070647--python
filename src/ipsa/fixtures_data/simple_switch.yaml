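# 6-state, 4-reaction switch network.
# Rate constants are documented STAND-INS chosen for qualitative behaviour
# (switch-like x6 activation, direct pathway early / indirect pathway at the
# switch); they are not measured or published values.
name: simple_switch_network
states: [x1, x2, x3, x4, x5, x6]
parameters:
  kf1: 0.25    # r1: x1 -> x2, mass action
  kv2: 0.15    # r2 (direct): x4 -> x6 catalysed by x2, MM Vmax scale
  kk2: 1.0     # r2 Michaelis constant
  kv3: 0.3     # r3: x3 -> x5 catalysed by x2, MM Vmax scale
  kk3: 1.0     # r3 Michaelis constant
  kv4: 0.4     # r4 (indirect): x4 -> x6 catalysed by x5, MM Vmax scale
  kk4: 1.0     # r4 Michaelis constant
reactions:
  - id: r1
    rate: kf1*x1
    stoichiometry: {x1: -1, x2: 1}
  - id: r2
    rate: mm(kv2*x2, kk2, x4)
    stoichiometry: {x4: -1, x6: 1}
  - id: r3
    rate: mm(kv3*x2, kk3, x3)
    stoichiometry: {x3: -1, x5: 1}
  - id: r4
    rate: mm(kv4*x5, kk4, x4)
    stoichiometry: {x4: -1, x6: 1}
initial_conditions: {x1: 1.0, x3: 1.0, x4: 1.0}
simulation: {t_start: 0.0, t_end: 15.0, n_points: 301, rtol: 1.0e-8, atol: 1.0e-10}
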