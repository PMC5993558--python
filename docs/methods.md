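# Methods

This note records the model as implemented, the numerical choices, the
study conditions the package defaults encode, and the known limitations.

## Model equations and state

Eight populations carry explicit soma-potential state (cortical pyramidal
*e*, thalamic reticular *r* and relay *s*, striatal *d₁*/*d₂*, pallidal
*p₁*/*p₂*, subthalamic *ζ*, internally labelled `z`). Each obeys the
second-order synaptodendritic equation

    (1/αβ) V̈_a + (1/α + 1/β) V̇_a + V_a = P_a(t),
    P_a(t) = Σ_b ν_ab φ_b(t − τ_ab) [+ ν_ax φ_x(t)] [+ ΔV_a],

with shared rise/decay rates β = 200 s⁻¹, α = 50 s⁻¹. Because (α, β) are
connection-independent, the afferents are summed *before* the filter; this
is algebraically identical to filtering each connection separately and
summing postsynaptic potentials, and reduces the state to 18 variables
(V_a, V̇_a for eight populations plus the cortical field pair φ_e, φ̇_e).

The cortical pyramidal rate field propagates as a damped wave; in the
spatially uniform mode this is (1/γ_e²) φ̈_e + (2/γ_e) φ̇_e + φ_e = Q_e with
γ_e = 116 s⁻¹. All other axonal ranges are short, so φ_b = Q_b = S_b(V_b)
instantaneously (local-interaction approximation). Only the spatially
uniform mode is solved; there are no spatially resolved fields.

The cortical interneuron population is eliminated exactly: with
random-connectivity proportionality (ν_ee = ν_ie, ν_ei = ν_ii, ν_es = ν_is)
the interneuron potential obeys the same equation as the pyramidal one, so
V_i ≡ V_e and the interneuron afferent to cortex enters as ν_ei·S_e(V_e).
Note the distinction from φ_e: the interneuron leg is a *local* rate
(sigmoid of the instantaneous potential), while the pyramidal self-
connection passes through the wave filter. Treating both legs through the
wave filter instead introduces a spurious low-frequency instability and was
rejected.

Axonal delays: cortex→thalamus 45 ms (both relay and reticular targets) and
relay→cortex 35 ms, per the nominal table; all other edges are
delay-free. The integrator nevertheless supports an arbitrary delay on any
edge (zero, or at least one integration step).

The sigmoid spread σ′ = 3.3 mV enters the rate map directly as
Q = Q_max/(1 + exp(−(V − θ)/σ′)); the relation between σ′ and the threshold
standard deviation plays no computational role. Units are mV, s⁻¹ and mV s
throughout; no internal conversions.

## Steady states

Setting time derivatives to zero and substituting the reticular, internal-
pallidal and subthalamic rates leaves five simultaneous equations in
(φ_e, φ_s, φ_d1, φ_d2, φ_p2). Roots are found by a deterministic multi-start
search: a fixed ladder of physiological seed points (the decoupled-rate
point and low-rate fractions of Q_max) plus a scrambled Sobol sequence
(seed recorded in metadata), each refined by bounded trust-region least
squares and polished with damped Newton steps on a finite-difference
Jacobian. Bounds keep the search off the sigmoid-saturation corners, where
the residual vanishes to machine precision for rates pinned within the
exponential tails; such boundary artifacts (within 10⁻⁶·Q_max of 0 or
Q_max) are discarded as non-physical. Duplicates merge when reduced rates
agree to 10³ × tolerance in equivalent rate units.

The convergence criterion applies a 10⁻¹⁵ V tolerance in
potential-equivalent form: each rate residual is divided by the local
sigmoid slope (floored so that a rate residual below 10⁻⁹ s⁻¹ always
passes) and the maximum must fall below 10⁻¹² mV. Under the nominal
parameters two interior fixed points exist; simulations start from the
low-firing one (minimal φ_e, ties broken by φ_s).

## Integration

Classical fixed-step RK4 at dt = 10⁻⁴ s on the 18-variable system, with
per-population rate history buffers for the delayed fields. Delayed values
at the half-step stage times are linearly interpolated between buffer
samples; the O(dt²) interpolation error is far below the local truncation
error for these smooth fields. History before t = 0 is the steady state.
Delays must be integer step multiples to be sample-exact (450 and 350
steps at the default dt); non-integer multiples are supported via the same
interpolation with a logged warning.

The stimulus is sampled area-exactly: the value applied during a step is
the mean of the ideal top-hat train over that step, held constant within
it, so each pulse carries exactly φ_x^max·t_width spikes regardless of how
pulse edges fall on the grid. The integrator was verified three ways:
equilibrium preservation at a stable fixed point (drift < 10⁻⁹ mV over
5 s), closed-form linear responses of decoupled populations (relative
error < 10⁻⁶), and agreement of the simulated beta-mode decay rate with
the characteristic roots of the independently linearized delay system
(−0.772 vs −0.773 s⁻¹ at 26.0 Hz).

Integration aborts with a diagnostic (time, worst population) on any
non-finite state or a cortical field outside [0, Q_max] beyond numerical
tolerance. Identical configuration and seeds give bit-identical output;
dt, seeds, perturbations and the protocol are recorded in run metadata.

## Study conditions: the noise-driven near-critical regime

Linear analysis of the nominal parameter set places the beta mode at
λ = −0.77 s⁻¹ + 2πi·26.0 Hz: marginally *stable*, within half a percent of
its Hopf point (at ν_p2ζ ≈ 2.415, with a fold of the fixed point at
≈ 2.50). Two facts then fix the study conditions. First, the weak-coupling
variant (ν_p2ζ = 1.8) has its beta-band mode damped at −21 s⁻¹, yet is an
operating point whose spectrum is of scientific interest — a deterministic
noiseless run from the fixed point would produce no spectrum at all.
Second, the strong-coupling state's high-Q resonance (quality factor
≈ 100) converts broadband input fluctuations into narrowband
large-amplitude beta. The parkinsonian presets therefore drive the
external relay channel with white noise: φ_n fluctuates about its mean of
1 s⁻¹ with a per-step standard deviation of 30 s⁻¹ at dt = 10⁻⁴ s
(equivalently, an amplitude spectral density of ≈ 0.42 s⁻¹ Hz^−1/2; the
per-step value is redrawn each step and held constant within it, so the
effective density scales with √dt if dt is changed).

The amplitude was chosen once, against three qualitative anchors: STN beta
oscillations of large amplitude (RMS ≈ 2 s⁻¹, ≈ 30% of the mean STN rate,
with excursions spanning most of the low-rate range); a second-harmonic
52 Hz peak well above the spectral floor (i.e. visibly nonlinear
dynamics); and a negligible probability of escaping the low-firing basin
toward the coexisting high-rate attractor over 40 s (per-step std ≥ 50
escapes stochastically; 30 showed no escape in six 40 s realizations).
`simulate()` itself defaults to noise-free operation; the noise is a
property of the parkinsonian presets and analysis scripts.

A consequence of sitting on the stable side of the Hopf point is that the
beta rhythm is *not* self-sustaining: any constant shift of the
STN/pallidal operating points — including the time-averaged effect of the
calibrated stimulus — increases the mode's damping steeply (≈ −14 s⁻¹ per
mV of mean perturbation). Suppression of beta-band power by high-frequency
stimulation is therefore reproduced, and is monotone in pulse frequency
over 100–200 Hz, but the two-orders-of-magnitude suppression level is
already reached at 100 Hz rather than emerging sharply near 140 Hz; and in
the 24–28 Hz scans the stimulus line dominates the spectrum throughout the
band instead of locking only within a narrow range around the beta
frequency. Both discrepancies trace to the same marginal stability: a
system realized marginally on the *unstable* side (a limit cycle robust to
~1 mV operating-point shifts) would show the sharp threshold and the
bounded locking range. Within the two-significant-figure precision of the
nominal couplings we found no
faithful variant that is simultaneously at 26 Hz and robustly
supercritical (strengthening ν_p2ζ within rounding gives a fragile cycle
and moves the sub-10 Hz peak; adding pallidal–subthalamic conduction
delays destabilizes but detunes the rhythm to 16–22 Hz), so the package
keeps the nominal parameters and documents the regime rather than tuning
toward either behavior.

## Stimulus calibration

The pulse train defaults to clinical-style parameters: 0.7 ms pulse width
(an inter-pulse quiescent period of ≈ 7 ms at 130 Hz implies a
sub-millisecond pulse) and couplings ν_ζx = −1.2, ν_p1x = ν_p2x =
+1.2 mV s. The amplitude φ_x^max is calibrated so that the stimulus
carries a 6% share of the coupling-weighted activity arriving at the STN,

    share = |ν_ζx|⟨φ_x⟩ / (|ν_ζx|⟨φ_x⟩ + |ν_ζe|⟨φ_e⟩ + |ν_ζp2|⟨φ_p2⟩),

with the intrinsic averages taken over ≥ 1 s of a stimulated simulation
and the equation closed by fixed-point iteration (the share is monotone in
the amplitude). At 150 Hz under the study-condition noise this converges
to φ_x^max ≈ 9.6 s⁻¹, recorded in run metadata. The mean evoked potential
of the train is ν_ax·φ_x^max·t_width·f_stim by the unit DC gain of the
dendritic filter, which is the bridge between the oscillating-input and
constant-offset descriptions of stimulation; the two suppress beta-band
power identically to within a fraction of a percent.

## Spectral estimation

Welch averaged periodograms: mean removal, Hann taper, 4 s segments
(0.25 Hz bins) with 50% overlap, density scaling; integrated density
matches windowed variance within 1%. "Band peak power" is the maximum
density in the band, not the band integral. When beta-band power is
measured under stimulation, bins within ±0.5 Hz of the stimulus frequency
and its harmonics are masked inside the band so the stimulus line is not
mistaken for intrinsic beta. Entrainment scans use finer 10 s segments
(0.1 Hz bins) when resolving intermodulation lines spaced 0.2 Hz apart;
a predicted combination line counts as present when a local maximum within
one bin exceeds five times the local median density.

## Scaled-down defaults

Figure-level sweeps default to 20 s runs analyzed on their final 10 s
(the full-scale 40 s / 20 s-window settings are one override away); the
unstimulated spectrum uses the full 40 s run with the 10–30 s window.
These sizes keep a complete sweep in the low minutes on one CPU while
leaving peak-frequency readouts unchanged at 0.25 Hz resolution.

## What the synthetic drive does and does not emulate

The white-noise relay drive stands in for the aggregate of brainstem and
sensory fluctuations reaching the thalamus; it is stationary, Gaussian,
spatially uniform and white, where physiological input is none of these.
Passing tests therefore demonstrate the circuit's filtering and nonlinear
response under broadband stationary drive, not the statistics of real
LFP/EEG recordings: absolute power levels, peak widths and the
higher-order spectral structure depend on the assumed drive amplitude,
while peak *frequencies*, gain signs and the direction and equivalence
properties of stimulation effects are robust to it.

## Known limitations

* Spatially uniform mode only; no wavenumber spectra or traveling waves.
* No dopamine dynamics: parkinsonian severity enters only through the
  nominal coupling strengths.
* DBS is a rate drive on three populations; no antidromic cortical
  activation, fiber-pathway geometry, or charge-balanced waveform shape.
* The near-critical regime makes threshold-type observables (suppression
  onset frequency, locking range edges) sensitive to the side of the Hopf
  point on which the operating state sits, as discussed above; peak
  frequencies and qualitative suppression/entrainment behavior are robust.
* One (α, β) pair for all connections; per-receptor kinetics are out of
  scope.
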