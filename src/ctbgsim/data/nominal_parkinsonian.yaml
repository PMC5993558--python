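sigma_p: 3.3
alpha: 50.0
beta: 200.0
gamma_e: 116.0
r_e: 80.0
phi_n: 1.0
populations:
  e:
    Q_max: 300.0
    theta: 14.0
    is_excitatory: true
  r:
    Q_max: 300.0
    theta: 13.0
    is_excitatory: false
  s:
    Q_max: 300.0
    theta: 13.0
    is_excitatory: true
  d1:
    Q_max: 65.0
    theta: 19.0
    is_excitatory: false
  d2:
    Q_max: 65.0
    theta: 19.0
    is_excitatory: false
  p1:
    Q_max: 250.0
    theta: 10.0
    is_excitatory: false
  p2:
    Q_max: 300.0
    theta: 9.0
    is_excitatory: false
  z:
    Q_max: 500.0
    theta: 10.0
    is_excitatory: true
connections:
- target: e
  source: e
  nu: 1.2
  tau: 0.0
- target: e
  source: i
  nu: -1.5
  tau: 0.0
- target: e
  source: s
  nu: 1.1
  tau: 0.035
- target: r
  source: e
  nu: 0.1
  tau: 0.045
- target: r
  source: s
  nu: 0.1
  tau: 0.0
- target: s
  source: e
  nu: 1.5
  tau: 0.045
- target: s
  source: r
  nu: -0.1
  tau: 0.0
- target: s
  source: p1
  nu: -0.2
  tau: 0.0
- target: s
  source: n
  nu: 0.5
  tau: 0.0
- target: d1
  source: e
  nu: 0.1
  tau: 0.0
- target: d1
  source: s
  nu: 1.0
  tau: 0.0
- target: d1
  source: d1
  nu: -0.02
  tau: 0.0
- target: d2
  source: e
  nu: 0.1
  tau: 0.0
- target: d2
  source: s
  nu: 0.1
  tau: 0.0
- target: d2
  source: d2
  nu: -0.02
  tau: 0.0
- target: p1
  source: z
  nu: 1.0
  tau: 0.0
- target: p1
  source: d1
  nu: -0.2
  tau: 0.0
- target: p1
  source: p2
  nu: -0.02
  tau: 0.0
- target: p2
  source: z
  nu: 2.4
  tau: 0.0
- target: p2
  source: d2
  nu: -0.8
  tau: 0.0
- target: p2
  source: p2
  nu: -0.2
  tau: 0.0
- target: z
  source: e
  nu: 1.3
  tau: 0.0
- target: z
  source: p2
  nu: -0.2
  tau: 0.0
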