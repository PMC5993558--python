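"""Fixed points of the corticothalamic-basal-ganglia system.

Setting all time derivatives to zero collapses the delay-differential system
to algebraic relations between the steady rates.  Three populations can be
eliminated by direct substitution — the STN rate follows from the cortical
and GPe rates, the GPi rate from STN/striatal/GPe rates, and the reticular
rate from cortical/relay rates — leaving five simultaneous equations in
``(phi_e, phi_s, phi_d1, phi_d2, phi_p2)``.  Roots are found by a
deterministic multi-start quasi-Newton search and refined until the
potential-equivalent residual is below tolerance; simulations are
initialized at the low-firing root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .model import POPULATIONS, ModelSpec, firing_rate, rate_slope

__all__ = [
    "SteadyState",
    "reduced_residuals",
    "solve_steady_states",
    "select_operating_state",
]

#: Order of the reduced unknowns.
REDUCED_VARS: tuple[str, ...] = ("e", "s", "d1", "d2", "p2")

#: Rate-space residual cap (s^-1): a residual this small is accepted even
#: where the sigmoid slope vanishes and the potential-equivalent residual
#: is ill-conditioned.
RATE_RESIDUAL_CAP = 1e-9


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the full system.

    ``V0`` maps each explicit population to its steady soma potential (mV),
    ``phi0`` to its steady rate field (s^-1).  ``residual_norm`` is the
    maximum potential-equivalent residual (mV) of the five reduced
    equations, regularized by the rate-space cap.
    """

    V0: Mapping[str, float]
    phi0: Mapping[str, float]
    residual_norm: float
    meta: Mapping[str, object] = field(default_factory=dict)


def _substituted_rates(phi_e, phi_s, phi_d1, phi_d2, phi_p2, model: ModelSpec):
    """Rates of the eliminated populations (z, p1, r) by direct substitution."""
    pops, sp = model.populations, model.sigma_p
    nu = model.nu
    phi_z = firing_rate(nu("z", "e") * phi_e + nu("z", "p2") * phi_p2, pops["z"], sp)
    phi_p1 = firing_rate(
        nu("p1", "z") * phi_z + nu("p1", "d1") * phi_d1 + nu("p1", "p2") * phi_p2,
        pops["p1"],
        sp,
    )
    phi_r = firing_rate(nu("r", "e") * phi_e + nu("r", "s") * phi_s, pops["r"], sp)
    return phi_z, phi_p1, phi_r


def _residuals_unchecked(x, model: ModelSpec):
    """Residual 5-vector(s) without domain validation; x is (5,) or (5, N)."""
    x = np.asarray(x, dtype=float)
    phi_e, phi_s, phi_d1, phi_d2, phi_p2 = x
    pops, sp = model.populations, model.sigma_p
    nu = model.nu
    phi_z, phi_p1, phi_r = _substituted_rates(
        phi_e, phi_s, phi_d1, phi_d2, phi_p2, model
    )
    f_e = phi_e - firing_rate(
        (nu("e", "e") + nu("e", "i")) * phi_e + nu("e", "s") * phi_s, pops["e"], sp
    )
    f_s = phi_s - firing_rate(
        nu("s", "e") * phi_e
        + nu("s", "r") * phi_r
        + nu("s", "p1") * phi_p1
        + nu("s", "n") * model.phi_n,
        pops["s"],
        sp,
    )
    f_d1 = phi_d1 - firing_rate(
        nu("d1", "e") * phi_e + nu("d1", "s") * phi_s + nu("d1", "d1") * phi_d1,
        pops["d1"],
        sp,
    )
    f_d2 = phi_d2 - firing_rate(
        nu("d2", "e") * phi_e + nu("d2", "s") * phi_s + nu("d2", "d2") * phi_d2,
        pops["d2"],
        sp,
    )
    f_p2 = phi_p2 - firing_rate(
        nu("p2", "d2") * phi_d2 + nu("p2", "p2") * phi_p2 + nu("p2", "z") * phi_z,
        pops["p2"],
        sp,
    )
    return np.stack([f_e, f_s, f_d1, f_d2, f_p2])


def reduced_residuals(x, model: ModelSpec):
    """Residuals of the five reduced fixed-point equations.

    ``x`` holds candidate rates ``(phi_e, phi_s, phi_d1, phi_d2, phi_p2)``
    (s^-1), either a 5-vector or a (5, N) batch.  Each component must lie in
    ``[0, Q_max)`` of its population.  Zero residuals identify a fixed point.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != 5:
        raise ValueError("expected 5 reduced components")
    for i, label in enumerate(REDUCED_VARS):
        qmax = model.populations[label].Q_max
        if np.any(x[i] < 0) or np.any(x[i] >= qmax):
            raise ValueError(
                f"phi_{label} outside [0, {qmax}): offending values present"
            )
    return _residuals_unchecked(x, model)


def _forward_map(x, model: ModelSpec):
    """One sweep of the fixed-point map ``phi <- S(drive(phi))``."""
    return x - _residuals_unchecked(x, model)


def _potential_residual_norm(x, model: ModelSpec, tol: float) -> float:
    """Max potential-equivalent residual (mV), regularized by the rate cap.

    Dividing each rate residual by the local sigmoid slope converts it to mV;
    the slope is floored at ``RATE_RESIDUAL_CAP / tol`` so that a rate
    residual below the cap always passes regardless of how flat the sigmoid
    is there.
    """
    f = np.abs(_residuals_unchecked(x, model))
    rho = np.array(
        [
            rate_slope(
                np.clip(x[i], 0.0, model.populations[v].Q_max),
                model.populations[v],
                model.sigma_p,
            )
            for i, v in enumerate(REDUCED_VARS)
        ]
    )
    floor = RATE_RESIDUAL_CAP / tol
    return float(np.max(f / (rho + floor)))


def _full_state(x, model: ModelSpec, tol: float, meta: dict) -> SteadyState:
    """Reconstruct potentials and rates of all eight populations from a root."""
    phi_e, phi_s, phi_d1, phi_d2, phi_p2 = x
    phi_z, phi_p1, phi_r = _substituted_rates(
        phi_e, phi_s, phi_d1, phi_d2, phi_p2, model
    )
    nu = model.nu
    V0 = {
        "e": (nu("e", "e") + nu("e", "i")) * phi_e + nu("e", "s") * phi_s,
        "r": nu("r", "e") * phi_e + nu("r", "s") * phi_s,
        "s": nu("s", "e") * phi_e
        + nu("s", "r") * phi_r
        + nu("s", "p1") * phi_p1
        + nu("s", "n") * model.phi_n,
        "d1": nu("d1", "e") * phi_e + nu("d1", "s") * phi_s + nu("d1", "d1") * phi_d1,
        "d2": nu("d2", "e") * phi_e + nu("d2", "s") * phi_s + nu("d2", "d2") * phi_d2,
        "p1": nu("p1", "z") * phi_z
        + nu("p1", "d1") * phi_d1
        + nu("p1", "p2") * phi_p2,
        "p2": nu("p2", "z") * phi_z
        + nu("p2", "d2") * phi_d2
        + nu("p2", "p2") * phi_p2,
        "z": nu("z", "e") * phi_e + nu("z", "p2") * phi_p2,
    }
    phi0 = {
        a: float(firing_rate(V0[a], model.populations[a], model.sigma_p))
        for a in POPULATIONS
    }
    return SteadyState(
        V0={a: float(v) for a, v in V0.items()},
        phi0=phi0,
        residual_norm=_potential_residual_norm(np.asarray(x, float), model, tol),
        meta=meta,
    )


def solve_steady_states(
    model: ModelSpec,
    tol: float = 1e-12,
    n_starts: int = 64,
    seed: int = 0,
) -> list[SteadyState]:
    """Find all distinct fixed points reachable from a multi-start search.

    Starts are a scrambled Sobol sequence over the admissible rate box
    (deterministic for a given ``seed``).  Each start is first pulled toward
    an attracting basin by iterating the forward map ``phi <- S(drive(phi))``
    (whose fixed points are exactly the roots), then refined with a bounded
    least-squares solve — bounds keep the search off the sigmoid-saturation
    corners, where the residual vanishes spuriously — and finally polished
    by damped Newton steps on a finite-difference Jacobian.  Roots are kept
    when the potential-equivalent residual is below ``tol`` (mV) and every
    rate is strictly interior, and merged when their reduced rates coincide
    to within ``1e3 * tol`` in equivalent rate units.

    Raises ``RuntimeError`` when no root survives.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    qmax = np.array([model.populations[v].Q_max for v in REDUCED_VARS])
    sobol = qmc.Sobol(d=5, scramble=True, seed=seed)
    starts = sobol.random(n_starts) * (0.98 * qmax) + 0.01 * qmax

    fun = lambda x: _residuals_unchecked(x, model)
    roots: list[np.ndarray] = []
    merge_atol = max(1e3 * tol * (RATE_RESIDUAL_CAP / tol), 1e3 * tol * 40.0)
    lo, hi = 1e-9 * qmax, qmax * (1.0 - 1e-12)

    candidates: list[np.ndarray] = []
    # deterministic physiological seeds: the decoupled-rate point and a
    # ladder of low-rate fractions (the low-firing basin is small)
    s0 = np.array(
        [
            firing_rate(0.0, model.populations[v], model.sigma_p)
            for v in REDUCED_VARS
        ]
    )
    candidates.append(np.clip(s0, lo, hi))
    for frac in (0.02, 0.05, 0.1, 0.2, 0.3, 0.5):
        candidates.append(np.clip(frac * qmax, lo, hi))
    for x0 in starts:
        candidates.append(x0)
        xm = x0
        for _ in range(20):
            xm = np.clip(_forward_map(xm, model), lo, hi)
        candidates.append(xm)

    for x0 in candidates:
        sol = optimize.least_squares(
            fun, x0, bounds=(lo, hi), method="trf",
            xtol=3e-16, ftol=3e-16, gtol=1e-15,
        )
        x = sol.x
        if not np.all(np.isfinite(x)):
            continue
        # damped-Newton polish with a finite-difference Jacobian
        for _ in range(6):
            f = fun(x)
            if np.max(np.abs(f)) < 1e-13:
                break
            eps = 1e-7
            J = np.empty((5, 5))
            for j in range(5):
                dx = np.zeros(5)
                dx[j] = eps * max(1.0, abs(x[j]))
                J[:, j] = (fun(x + dx) - fun(x - dx)) / (2 * dx[j])
            try:
                step = np.linalg.solve(J, f)
            except np.linalg.LinAlgError:
                break
            x_new = x - step
            if np.max(np.abs(fun(x_new))) < np.max(np.abs(f)):
                x = x_new
            else:
                break
        # reject saturation-boundary artifacts: within the sigmoid's
        # exponential tails a pinned rate satisfies the equations to any
        # tolerance but is not a physically meaningful operating point
        if np.any(x <= 1e-6 * qmax) or np.any(x >= (1 - 1e-6) * qmax):
            continue
        if _potential_residual_norm(x, model, tol) >= tol:
            continue
        if any(np.max(np.abs(x - r)) < merge_atol for r in roots):
            continue
        roots.append(x)

    if not roots:
        raise RuntimeError(
            f"no steady state found (tol={tol} mV, n_starts={n_starts}, seed={seed})"
        )
    roots.sort(key=lambda r: (r[0], r[1]))
    meta = {"tol": tol, "n_starts": n_starts, "seed": seed}
    return [_full_state(x, model, tol, dict(meta)) for x in roots]


def select_operating_state(states: list[SteadyState]) -> SteadyState:
    """The low-firing root: minimal cortical rate, ties broken by relay rate."""
    if not states:
        raise ValueError("empty list of steady states")
    return min(states, key=lambda s: (s.phi0["e"], s.phi0["s"]))
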