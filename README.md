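# ctbgsim

Mean-field simulation of the corticothalamic–basal-ganglia (CTBG) circuit,
built to study the parkinsonian beta rhythm and its suppression by deep
brain stimulation (DBS) of the subthalamic nucleus (STN). It is aimed at
computational neuroscientists and neural-engineering researchers who want a
population-level (neural field) account of why high-frequency STN
stimulation quenches pathological 13–30 Hz activity, and what low-frequency
stimulation does instead.

## The model

Nine neural populations are coupled: cortical pyramidal neurons *e* and
interneurons *i*; thalamic relay *s* and reticular *r* nuclei; striatal
D1/D2 populations *d₁*, *d₂*; internal and external pallidum *p₁*, *p₂*;
and the STN *ζ*. Each population maps its mean soma potential to a mean
firing rate through a sigmoid

&nbsp;&nbsp;&nbsp;&nbsp;Q_a = Q_a^max / (1 + exp(−(V_a − θ_a)/σ′)),

the soma potential integrates delayed afferent rate fields through a
second-order synaptodendritic filter with rise rate β and decay rate α,

&nbsp;&nbsp;&nbsp;&nbsp;(1/αβ) V̈_a + (1/α + 1/β) V̇_a + V_a = Σ_b ν_ab φ_b(t − τ_ab),

and the cortical pyramidal field obeys a damped-wave equation in its
spatially uniform mode, (1/γ_e²) φ̈_e + (2/γ_e) φ̇_e + φ_e = Q_e, while every
short-axon population is local (φ_b = Q_b). The interneuron population is
slaved to the pyramidal one by the random-connectivity identities
V_i = V_e, Q_i = Q_e and carries no independent state. DBS is an external
axonal pulse-rate channel φ_x(t) — a periodic train of top-hat pulses —
coupled with strength ν_ζx < 0 into the STN and ν_p1x, ν_p2x > 0 into both
pallidal segments.

The packaged nominal parameter set places the system in a parkinsonian
regime: a strong STN→GPe coupling (ν_p2ζ = 2.4 mV s) leaves the low-firing
fixed point with a nearly undamped 26 Hz mode (decay 0.77 s⁻¹) generated by
the GPe–STN–GPe loop and the hyperdirect cortex→STN pathway, plus a ~6 Hz
tremor-band mode. Driven by stochastic fluctuations of the external relay
input, the STN then exhibits large-amplitude 26 Hz beta oscillations with a
visible 52 Hz harmonic. Time-averaged DBS input acts as a constant shift of
the STN and pallidal operating points, which re-damps the resonance — the
package's account of beta suppression.

What the package computes:

* **Steady states** — all interior fixed points of the nine-population
  system by multi-start root finding on the reduced five-variable system,
  with the low-firing root selected as the operating state.
* **Trajectories** — fixed-step RK4 integration of the 18-variable delay
  system (history buffers for the 35/45 ms corticothalamic delays),
  with pulse-train stimulus, optional drive noise, and direct constant
  potential offsets.
* **Linearized gains** — sigmoid slopes ρ_a and connection gains
  G_ab = ρ_a ν_ab at any operating point; loop-gain products for the
  STN–GPe, hyperdirect, direct and indirect pathways.
* **Spectral observables** — Welch spectra of population rates; beta /
  tremor / harmonic peak readouts; suppression-versus-pulse-frequency
  curves; entrainment and intermodulation scans.

## Worked example

```python
from ctbgsim import (default_model, solve_steady_states,
                     select_operating_state, simulate, dominant_peak)
from ctbgsim.spectral import spectrum_of

model = default_model()                      # nominal parkinsonian set
states = solve_steady_states(model)
op = select_operating_state(states)
print(f"fixed points found: {len(states)}")
print(f"operating state: phi_e = {op.phi0['e']:.2f} s^-1, "
      f"phi_STN = {op.phi0['z']:.2f} s^-1 (residual {op.residual_norm:.1e} mV)")

run = simulate(model, duration=40.0, init=op, noise={"std": 30.0, "seed": 1})
spec = spectrum_of(run, "z", 10.0, 30.0)
f_beta, p_beta = dominant_peak(spec, 1.0, 60.0)
f_trem, p_trem = dominant_peak(spec, 1.0, 10.0)
print(f"dominant STN peak: {f_beta:.2f} Hz (density {p_beta:.2f})")
print(f"sub-10 Hz peak:    {f_trem:.2f} Hz (density {p_trem:.2f})")
```

prints

```
fixed points found: 2
operating state: phi_e = 8.15 s^-1, phi_STN = 8.12 s^-1 (residual 2.8e-17 mV)
dominant STN peak: 26.00 Hz (density 4.35)
sub-10 Hz peak:    6.25 Hz (density 0.19)
```

The two fixed points are the low-firing operating state and a coexisting
high-rate state; the simulation is initialized at the former. The 26 Hz
line is the parkinsonian beta rhythm of the STN; the 6.25 Hz line is the
tremor-band companion that projects more strongly to cortex.

The same pipelines are scripted as figure-level presets:

```bash
ctbgsim steady                         # fixed-point report
ctbgsim preset beta-generation-b       # 40 s run + STN spectrum
ctbgsim preset suppression-sweep       # beta power vs DBS pulse frequency
ctbgsim verify results/beta-generation-b   # re-run and diff artifacts
```

Every preset writes its artifacts next to a resolved-configuration snapshot
and content hash, and `ctbgsim verify` regenerates them and diffs.

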