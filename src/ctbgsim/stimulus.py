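"""Deep-brain-stimulation drive: pulse trains, evoked responses, calibration.

DBS is modeled as an external axonal pulse-rate channel ``phi_x(t)``: a
periodic train of top-hat pulses of amplitude ``phix_max`` (s^-1), width
``t_width`` (s) and repetition frequency ``f_stim`` (Hz).  The train couples
into the subthalamic nucleus with a negative strength ``nu_zx`` (net
inhibitory effect of high-frequency axonal activation) and into both pallidal
segments with positive strengths ``nu_p1x``, ``nu_p2x`` (excitatory terminal
activation), each filtered by the same second-order synaptodendritic response
as intrinsic afferents, with zero axonal delay.

The time-integral of one pulse, ``phix_max * t_width``, is the mean number of
additional spikes evoked per pulse in the target axons; the train's long-run
time average is ``phix_max * t_width * f_stim``, which multiplied by the
coupling gives the effective constant soma-potential perturbation that
underlies beta suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.signal import fftconvolve

from .model import ModelSpec, synaptic_kernel

__all__ = [
    "StimulusProtocol",
    "pulse_train",
    "pulse_train_zoh",
    "evoked_potential",
    "mean_perturbation",
    "calibrate_amplitude",
    "default_protocol",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """One DBS pulse-train configuration and its population couplings."""

    f_stim: float  # pulse frequency, Hz
    t_width: float  # pulse width, s
    phix_max: float  # pulse amplitude, s^-1
    onset: float = 0.0  # stimulation start, s
    nu_zx: float = -1.2  # STN coupling, mV s (<= 0)
    nu_p1x: float = 1.2  # GPi coupling, mV s (>= 0)
    nu_p2x: float = 1.2  # GPe coupling, mV s (>= 0)

    def __post_init__(self) -> None:
        if self.f_stim <= 0:
            raise ValueError("f_stim must be positive")
        if not (0 < self.t_width < 1.0 / self.f_stim):
            raise ValueError(
                f"pulse width {self.t_width} s must lie in (0, 1/f_stim); "
                f"pulses may not overlap"
            )
        if self.phix_max < 0:
            raise ValueError("phix_max must be non-negative")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.nu_zx > 0:
            raise ValueError("the STN-targeted channel is inhibitory: nu_zx <= 0")
        if self.nu_p1x < 0 or self.nu_p2x < 0:
            raise ValueError("the pallidal channels are excitatory: nu >= 0")

    @property
    def period(self) -> float:
        return 1.0 / self.f_stim

    def with_amplitude(self, phix_max: float) -> "StimulusProtocol":
        return replace(self, phix_max=phix_max)

    def with_frequency(self, f_stim: float) -> "StimulusProtocol":
        return replace(self, f_stim=f_stim)

    def to_dict(self) -> dict:
        return {
            "f_stim": self.f_stim,
            "t_width": self.t_width,
            "phix_max": self.phix_max,
            "onset": self.onset,
            "nu_zx": self.nu_zx,
            "nu_p1x": self.nu_p1x,
            "nu_p2x": self.nu_p2x,
        }


def default_protocol(
    f_stim: float = 150.0,
    phix_max: float = 0.0,
    onset: float = 0.0,
) -> StimulusProtocol:
    """Clinical-style protocol skeleton: 0.7 ms pulses, pallidum/STN couplings
    of +/-1.2 mV s.  The amplitude is left at zero; set it explicitly or via
    :func:`calibrate_amplitude`."""
    return StimulusProtocol(
        f_stim=f_stim, t_width=0.7e-3, phix_max=phix_max, onset=onset
    )


def pulse_train(p: StimulusProtocol, t_grid) -> np.ndarray:
    """Point-sampled pulse train on a uniform time grid (s^-1).

    The series equals ``phix_max`` inside each pulse window
    ``[t_j, t_j + t_width)`` with onsets ``t_j = onset + j / f_stim`` and is
    zero elsewhere and before onset.  The grid step must be at most
    ``t_width / 2`` so that every pulse is resolved.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-15):
            raise ValueError("t_grid must be uniform")
        if steps[0] > p.t_width / 2 + 1e-15:
            raise ValueError("grid step must be <= t_width / 2")
    s = t - p.onset
    phase = s - np.floor(s * p.f_stim) * p.period
    out = np.where((s >= 0) & (phase < p.t_width), p.phix_max, 0.0)
    return out


def _on_time(p: StimulusProtocol, t) -> np.ndarray:
    """Cumulative pulse-on time in [0, t) of the ideal train."""
    s = np.maximum(np.asarray(t, dtype=float) - p.onset, 0.0)
    n = np.floor(s * p.f_stim)
    rem = s - n * p.period
    return n * p.t_width + np.minimum(rem, p.t_width)


def pulse_train_zoh(p: StimulusProtocol, n_steps: int, dt: float) -> np.ndarray:
    """Area-exact per-step sampling of the pulse train.

    Entry ``k`` is the mean of the ideal top-hat train over
    ``[k dt, (k+1) dt)``, so the sampled series carries exactly the charge
    ``phix_max * t_width`` per pulse regardless of how pulse edges fall
    relative to the grid.  This is the drive the integrator applies,
    held constant within each step.
    """
    edges = np.arange(n_steps + 1) * dt
    cum = _on_time(p, edges)
    return p.phix_max * np.diff(cum) / dt


def _zoh_step_kernel(alpha: float, beta: float, dt: float, n: int) -> np.ndarray:
    """Discrete kernel of the dendritic filter for piecewise-constant input.

    ``g[k]`` is the integral of the impulse response over
    ``[k dt, (k+1) dt]``, i.e. the exact response contribution of one input
    step; truncated once the remaining tail is below 1e-15.
    """
    if abs(beta - alpha) < 1e-9 * alpha:
        H = lambda t: 1.0 - (1.0 + alpha * t) * np.exp(-alpha * t)
    else:
        H = lambda t: 1.0 - (
            beta * np.exp(-alpha * t) - alpha * np.exp(-beta * t)
        ) / (beta - alpha)
    n_tail = int(math.ceil(40.0 / (alpha * dt)))
    m = min(n, n_tail)
    edges = np.arange(m + 1) * dt
    return np.diff(H(edges))


def evoked_potential(
    series, alpha: float, beta: float, nu_ax: float, dt: float
) -> np.ndarray:
    """Postsynaptic potential evoked by an afferent rate series (mV).

    Convolves the series (interpreted as held constant over each step of
    length ``dt``) with the synaptodendritic impulse response and scales by
    the coupling strength.  Because the filter has unit DC gain, a constant
    input ``phi`` asymptotes to ``nu_ax * phi``.  Agrees with direct ODE
    integration of the dendritic filter driven by the same held series.
    """
    x = np.asarray(series, dtype=float)
    g = _zoh_step_kernel(alpha, beta, dt, x.size)
    return nu_ax * fftconvolve(x, g)[: x.size]


def mean_perturbation(p: StimulusProtocol, nu_ax: float) -> float:
    """Long-run effective constant potential perturbation (mV).

    The time average of the pulse train is ``phix_max * t_width * f_stim``;
    unit DC gain of the dendritic filter makes the steady evoked potential
    the coupling times that average.
    """
    return nu_ax * p.phix_max * p.t_width * p.f_stim


def calibrate_amplitude(
    model: ModelSpec,
    p: StimulusProtocol,
    target_share: float,
    init=None,
    duration: float = 3.0,
    window: tuple[float, float] = (1.5, 3.0),
    dt: float = 1e-4,
    noise=None,
    seed_kick: float = 1e-6,
    tol: float = 1e-3,
    max_iter: int = 8,
) -> float:
    """Pulse amplitude delivering a target share of STN afferent activity.

    The share is the coupling-weighted mean stimulus rate relative to all
    coupling-weighted activity arriving at the STN,

        share = |nu_zx| <phi_x> / (|nu_zx| <phi_x> + sum_b |nu_zb| <phi_b>),

    with the population averages ``<phi_b>`` (cortex and GPe, the intrinsic
    STN afferents) taken over the ``window`` of a stimulated simulation.
    Because the intrinsic averages depend only weakly on the stimulus, the
    share equation is closed by fixed-point iteration; the share is monotone
    increasing in the amplitude.

    Returns the calibrated ``phix_max`` (s^-1).  Raises ``RuntimeError`` on
    non-convergence.
    """
    if not (0 <= target_share < 1):
        raise ValueError("target_share must lie in [0, 1)")
    if target_share == 0:
        return 0.0
    from .integrate import simulate  # deferred: integrate imports this module
    from .steady import select_operating_state, solve_steady_states

    if init is None:
        init = select_operating_state(solve_steady_states(model))

    w_zx = abs(p.nu_zx)
    w_e = abs(model.nu("z", "e"))
    w_p2 = abs(model.nu("z", "p2"))

    # zeroth estimate from the fixed-point rates
    intr = w_e * init.phi0["e"] + w_p2 * init.phi0["p2"]
    duty = p.t_width * p.f_stim
    amp = target_share * intr / ((1.0 - target_share) * w_zx * duty)

    for _ in range(max_iter):
        proto = p.with_amplitude(amp)
        res = simulate(
            model, protocol=proto, duration=duration, dt=dt, init=init,
            noise=noise, seed_kick=seed_kick,
        )
        mask = (res.t >= window[0]) & (res.t <= window[1])
        phix_bar = float(np.mean(res.phi_x[mask]))
        intr = w_e * float(np.mean(res.rate("e")[mask])) + w_p2 * float(
            np.mean(res.rate("p2")[mask])
        )
        share = w_zx * phix_bar / (w_zx * phix_bar + intr)
        if abs(share - target_share) < tol:
            return amp
        amp = target_share * intr / ((1.0 - target_share) * w_zx * duty)
    raise RuntimeError(
        f"amplitude calibration did not converge after {max_iter} iterations "
        f"(last share {share:.4f}, target {target_share})"
    )
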