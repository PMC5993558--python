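"""Fixed-step RK4 integration of the spatially uniform delay system.

Each explicit population carries a second-order synaptodendritic equation

    (1/(alpha beta)) d2V_a/dt2 + (1/alpha + 1/beta) dV_a/dt + V_a = P_a(t),

where ``P_a`` sums the delayed afferent rate fields weighted by the coupling
strengths, plus any stimulus drive and constant potential offsets.  The
cortical pyramidal rate field additionally obeys the damped-wave equation in
its uniform mode,

    (1/gamma_e^2) d2phi_e/dt2 + (2/gamma_e) dphi_e/dt + phi_e = Q_e(t),

while every other population is local: ``phi_b = Q_b = S_b(V_b)``.  The only
non-zero axonal delays are cortex -> thalamus (45 ms, both relay and
reticular targets) and relay -> cortex (35 ms); delayed fields are read from
history ring buffers with linear interpolation at the RK4 half-steps.

State dimension is 18: ``(V_a, dV_a/dt)`` for the eight explicit populations
plus ``(phi_e, dphi_e/dt)``.  The hot loop is compiled with numba.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from numba import njit

from .model import POPULATIONS, ModelSpec, firing_rate
from .steady import SteadyState
from .stimulus import StimulusProtocol, pulse_train_zoh

__all__ = [
    "SimulationResult",
    "simulate",
    "rk4_step",
    "apply_direct_perturbation",
]

log = logging.getLogger(__name__)

_POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}

@njit(cache=True, inline="always")
def _sigmoid(v, qm, th, sigma):
    return qm / (1.0 + math.exp(-(v - th) / sigma))


@njit(cache=True)
def _stage_sources(y, hist, pos, edge_src, edge_m, qmax, theta, sigma, phin,
                   s_vals):
    """Source field value for every connection at one RK4 stage.

    ``pos`` is the fractional history index of the stage time.  Zero-delay
    edges read the stage state directly (wave field for the cortex, sigmoid
    image of the stage soma potential for local sources); delayed edges read
    the history buffer of the source's rate field with linear interpolation.
    Source codes 0-7 are the explicit populations, 8 the slaved interneuron
    population (rate ``S_e(V_e)``), 9 the external drive channel.
    """
    for j in range(edge_src.size):
        src = edge_src[j]
        m = edge_m[j]
        if src == 9:
            s_vals[j] = phin
        elif m == 0.0:
            if src == 0:
                s_vals[j] = y[16]
            elif src == 8:
                s_vals[j] = _sigmoid(y[0], qmax[0], theta[0], sigma)
            else:
                s_vals[j] = _sigmoid(y[src], qmax[src], theta[src], sigma)
        else:
            p = pos - m
            i0 = int(math.floor(p))
            w = p - i0
            row = 0 if src == 8 else src
            if w == 0.0:
                s_vals[j] = hist[row, i0]
            else:
                s_vals[j] = hist[row, i0] * (1.0 - w) + hist[row, i0 + 1] * w


@njit(cache=True)
def _deriv(y, s_vals, phix, edge_tgt, edge_nu, nux, dvc, qmax, theta, sigma,
           alpha, beta, gamma, dy):
    """Time derivative of the 18-dimensional state at one RK4 stage."""
    p = dvc.copy()
    for j in range(edge_tgt.size):
        p[edge_tgt[j]] += edge_nu[j] * s_vals[j]
    p[5] += nux[1] * phix
    p[6] += nux[2] * phix
    p[7] += nux[0] * phix
    ab = alpha * beta
    apb = alpha + beta
    for i in range(8):
        dy[i] = y[8 + i]
        dy[8 + i] = ab * (p[i] - y[i]) - apb * y[8 + i]
    qe = _sigmoid(y[0], qmax[0], theta[0], sigma)
    dy[16] = y[17]
    dy[17] = gamma * gamma * (qe - y[16]) - 2.0 * gamma * y[17]


@njit(cache=True)
def _run(n_steps, dt, edge_tgt, edge_src, edge_nu, edge_m, nux, dvc, qmax,
         theta, sigma, alpha, beta, gamma, phi_n, off, y0, phix, noise,
         out_y):
    """March the system ``n_steps`` RK4 steps; returns -1 or the failing step."""
    n_edges = edge_tgt.size
    hist = np.empty((8, n_steps + off + 2))
    for p in range(8):
        if p == 0:
            v0 = y0[16]
        else:
            v0 = _sigmoid(y0[p], qmax[p], theta[p], sigma)
        for i in range(off + 1):
            hist[p, i] = v0
    y = y0.copy()
    out_y[0] = y
    k1 = np.empty(18)
    k2 = np.empty(18)
    k3 = np.empty(18)
    k4 = np.empty(18)
    yt = np.empty(18)
    s_vals = np.empty(n_edges)
    for k in range(n_steps):
        px = phix[k]
        pn = phi_n + noise[k]
        base = float(k + off)
        # stage 1 at t
        _stage_sources(y, hist, base, edge_src, edge_m, qmax, theta, sigma,
                       pn, s_vals)
        _deriv(y, s_vals, px, edge_tgt, edge_nu, nux, dvc, qmax, theta,
               sigma, alpha, beta, gamma, k1)
        # stages 2 and 3 at t + dt/2
        for i in range(18):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _stage_sources(yt, hist, base + 0.5, edge_src, edge_m, qmax, theta,
                       sigma, pn, s_vals)
        _deriv(yt, s_vals, px, edge_tgt, edge_nu, nux, dvc, qmax, theta,
               sigma, alpha, beta, gamma, k2)
        for i in range(18):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _stage_sources(yt, hist, base + 0.5, edge_src, edge_m, qmax, theta,
                       sigma, pn, s_vals)
        _deriv(yt, s_vals, px, edge_tgt, edge_nu, nux, dvc, qmax, theta,
               sigma, alpha, beta, gamma, k3)
        # stage 4 at t + dt
        for i in range(18):
            yt[i] = y[i] + dt * k3[i]
        _stage_sources(yt, hist, base + 1.0, edge_src, edge_m, qmax, theta,
                       sigma, pn, s_vals)
        _deriv(yt, s_vals, px, edge_tgt, edge_nu, nux, dvc, qmax, theta,
               sigma, alpha, beta, gamma, k4)
        ok = True
        for i in range(18):
            y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not math.isfinite(y[i]):
                ok = False
        if not ok:
            return k
        if y[16] < -1e-6 * qmax[0] or y[16] > qmax[0] * (1.0 + 1e-6):
            return k
        hist[0, k + 1 + off] = y[16]
        for p in range(1, 8):
            hist[p, k + 1 + off] = _sigmoid(y[p], qmax[p], theta[p], sigma)
        out_y[k + 1] = y
    return -1


@dataclass
class SimulationResult:
    """Sampled trajectory of one run.

    ``V`` and ``phi`` are (8, n_samples) arrays in canonical population
    order; ``phi`` rows hold the axonal rate fields (the damped-wave field
    for the cortex, the sigmoid image of the soma potential for local
    populations).  ``phi_x`` is the stimulus drive actually applied per step
    (zero-padded to the sample grid).  ``meta`` records everything needed to
    reproduce the run.
    """

    t: np.ndarray
    V: np.ndarray
    phi: np.ndarray
    phi_x: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def rate(self, label: str) -> np.ndarray:
        return self.phi[_POP_INDEX[label]]

    def potential(self, label: str) -> np.ndarray:
        return self.V[_POP_INDEX[label]]

    @property
    def dt(self) -> float:
        return float(self.meta["dt"])

    def to_csv(self, path, decimate: int = 10) -> None:
        """Plain-text trajectory export (time + rate and potential columns)."""
        import pandas as pd

        sl = slice(None, None, max(1, int(decimate)))
        cols = {"t": self.t[sl]}
        for p in POPULATIONS:
            cols[f"phi_{p}"] = self.rate(p)[sl]
            cols[f"V_{p}"] = self.potential(p)[sl]
        cols["phi_x"] = self.phi_x[sl]
        pd.DataFrame(cols).to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        """Binary hierarchical export for long runs."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=self.t)
            fh.create_dataset("V", data=self.V)
            fh.create_dataset("phi", data=self.phi)
            fh.create_dataset("phi_x", data=self.phi_x)
            for key, val in self.meta.items():
                fh.attrs[key] = str(val)


_SRC_CODE = {**_POP_INDEX, "i": 8, "n": 9}


def _edge_arrays(model: ModelSpec, dt: float):
    """Flatten the connection list into kernel arrays.

    Returns ``(edge_tgt, edge_src, edge_nu, edge_m)`` with delays expressed
    in (possibly fractional) integration steps.  A delay must be either zero
    (the source is read at the stage time) or at least one step (read from
    the history buffer).
    """
    n = len(model.connections)
    edge_tgt = np.empty(n, dtype=np.int64)
    edge_src = np.empty(n, dtype=np.int64)
    edge_nu = np.empty(n)
    edge_m = np.empty(n)
    for j, c in enumerate(model.connections):
        edge_tgt[j] = _POP_INDEX[c.target]
        edge_src[j] = _SRC_CODE[c.source]
        edge_nu[j] = c.nu
        if c.tau == 0.0:
            edge_m[j] = 0.0
        else:
            m = c.tau / dt
            if m < 1.0:
                raise ValueError(
                    f"delay {c.tau} s on {c.target!r} <- {c.source!r} is "
                    f"shorter than one step dt={dt} s; use 0 or >= dt"
                )
            if abs(m - round(m)) > 1e-9:
                log.warning(
                    "delay %.6g s is not an integer multiple of dt=%.3g s; "
                    "using linear interpolation in the history buffer",
                    c.tau, dt,
                )
            else:
                m = float(round(m))
            edge_m[j] = m
    return edge_tgt, edge_src, edge_nu, edge_m


def simulate(
    model: ModelSpec,
    protocol: Optional[StimulusProtocol] = None,
    duration: float = 40.0,
    dt: float = 1e-4,
    init: SteadyState | None = None,
    perturbation: Optional[Mapping[str, float]] = None,
    noise: Optional[Mapping[str, float]] = None,
    seed_kick: float = 0.0,
) -> SimulationResult:
    """Integrate the CTBG system and return the full sampled trajectory.

    Parameters
    ----------
    model, protocol
        The parameter set and (optionally) a DBS pulse-train protocol.  The
        stimulus is sampled area-exactly per step (the value applied over a
        step equals the mean of the ideal top-hat train over that step) and
        held constant within the step.
    duration, dt
        Simulated span (s) and RK4 step (s).
    init
        Fixed point to start from.  When omitted the low-firing steady state
        of ``model`` is solved for on the fly.
    perturbation
        Constant soma-potential addends per population label (mV), applied
        to the summed drive of the second-order dendritic equation.
    noise
        ``{"std": rate s^-1, "seed": int}`` white perturbation on the
        external drive channel, redrawn each step and held constant within
        it.  Off when omitted.
    seed_kick
        One-off offset (mV) added to the cortical soma potential at t = 0 to
        break exact equilibrium when the fixed point is unstable; recorded
        in metadata.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if init is None:
        from .steady import select_operating_state, solve_steady_states

        init = select_operating_state(solve_steady_states(model))
    n_steps = int(round(duration / dt))
    edge_tgt, edge_src, edge_nu, edge_m = _edge_arrays(model, dt)
    qmax = np.array([model.populations[p].Q_max for p in POPULATIONS])
    theta = np.array([model.populations[p].theta for p in POPULATIONS])
    off = int(math.ceil(edge_m.max())) + 1 if edge_m.size else 1

    nux = np.zeros(3)
    phix = np.zeros(n_steps)
    if protocol is not None:
        nux[:] = (protocol.nu_zx, protocol.nu_p1x, protocol.nu_p2x)
        phix = pulse_train_zoh(protocol, n_steps, dt)

    dvc = np.zeros(8)
    if perturbation:
        for label, dv in perturbation.items():
            dvc[_POP_INDEX[label]] = dv

    noise_arr = np.zeros(n_steps)
    noise_meta: dict[str, object] = {}
    if noise:
        std = float(noise.get("std", 0.0))
        nseed = int(noise.get("seed", 0))
        if std > 0:
            rng = np.random.default_rng(nseed)
            noise_arr = std * rng.standard_normal(n_steps)
        noise_meta = {"noise_std": std, "noise_seed": nseed}

    y0 = np.zeros(18)
    for i, p in enumerate(POPULATIONS):
        y0[i] = init.V0[p]
    y0[0] += seed_kick
    y0[16] = init.phi0["e"]

    out_y = np.empty((n_steps + 1, 18))
    bad = _run(
        n_steps, dt, edge_tgt, edge_src, edge_nu, edge_m, nux, dvc, qmax,
        theta, model.sigma_p, model.alpha, model.beta, model.gamma_e,
        model.phi_n, off, y0, phix, noise_arr, out_y,
    )
    if bad >= 0:
        v_snap = out_y[max(bad - 1, 0), :8]
        worst = POPULATIONS[int(np.argmax(np.abs(v_snap)))]
        raise RuntimeError(
            f"integration failed at t={bad * dt:.4f} s (non-finite state or "
            f"cortical field out of range; largest |V| in population "
            f"{worst!r})"
        )

    t = np.arange(n_steps + 1) * dt
    V = out_y[:, :8].T.copy()
    phi = np.empty_like(V)
    for i, p in enumerate(POPULATIONS):
        if p == "e":
            phi[i] = out_y[:, 16]
        else:
            phi[i] = firing_rate(V[i], model.populations[p], model.sigma_p)
    phix_full = np.zeros(n_steps + 1)
    phix_full[:n_steps] = phix

    meta: dict[str, object] = {
        "dt": dt,
        "duration": duration,
        "seed_kick": seed_kick,
        "perturbation": dict(perturbation or {}),
        "protocol": None if protocol is None else protocol.to_dict(),
        **noise_meta,
    }
    return SimulationResult(t=t, V=V, phi=phi, phi_x=phix_full, meta=meta)


def rk4_step(y, t: float, dt: float, deriv: Callable):
    """One classical fourth-order Runge-Kutta step ``y(t) -> y(t + dt)``.

    ``deriv(t, y)`` evaluates the time derivative; delayed terms are the
    caller's responsibility (fold the history lookup into ``deriv``).  This
    reference stepper is the scheme the compiled production loop implements.
    """
    y = np.asarray(y, dtype=float)
    k1 = np.asarray(deriv(t, y))
    k2 = np.asarray(deriv(t + dt / 2, y + dt / 2 * k1))
    k3 = np.asarray(deriv(t + dt / 2, y + dt / 2 * k2))
    k4 = np.asarray(deriv(t + dt, y + dt * k3))
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def apply_direct_perturbation(
    model: ModelSpec,
    init: SteadyState,
    dV: float,
    duration: float = 40.0,
    dt: float = 1e-4,
    convention: str = "dbs",
    seed_kick: float = 0.0,
) -> SimulationResult:
    """Run with constant soma-potential offsets mimicking time-averaged DBS.

    ``convention="dbs"`` follows the stimulus coupling signs — the STN
    receives ``-|dV|`` (its DBS coupling is inhibitory) while GPi and GPe
    receive ``+|dV|`` (excitatory couplings).  ``convention="mirror"``
    applies the opposite sign pattern (STN ``+|dV|``, pallidum ``-|dV|``);
    both are available because the two conventions appear in different
    descriptions of the same experiment.
    """
    if dV < 0:
        raise ValueError("dV must be non-negative")
    if convention == "dbs":
        pert = {"z": -dV, "p1": +dV, "p2": +dV}
    elif convention == "mirror":
        pert = {"z": +dV, "p1": -dV, "p2": -dV}
    else:
        raise ValueError(f"unknown sign convention {convention!r}")
    return simulate(
        model,
        protocol=None,
        duration=duration,
        dt=dt,
        init=init,
        perturbation=pert,
        seed_kick=seed_kick,
    )
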