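"""Core data types and pointwise maps of the corticothalamic-basal-ganglia model.

The model describes nine interacting neural populations — cortical excitatory
pyramidal cells (``e``) and inhibitory interneurons (``i``), thalamic specific
relay nuclei (``s``) and reticular nucleus (``r``), striatal D1/D2 populations
(``d1``, ``d2``), internal and external pallidum (``p1``, ``p2``) and the
subthalamic nucleus (``z``, STN) — at the mean-field level.  Each population
carries a mean soma potential ``V_a`` (mV, relative to rest) mapped to a mean
firing rate through a sigmoid, and projects a rate field ``phi_a`` to its
targets.  Only the cortical pyramidal field propagates as a damped wave; all
other axonal ranges are short enough that ``phi_b = Q_b`` (local-interaction
approximation).  The interneuron population is slaved to the pyramidal one by
the random-connectivity identities ``V_i = V_e``, ``Q_i = Q_e`` and never
carries independent state.

Units are fixed throughout the package: potentials in mV, rates in s^-1,
coupling strengths ``nu_ab`` in mV s, times in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "POPULATIONS",
    "EXCITATORY_SOURCES",
    "INHIBITORY_SOURCES",
    "PopulationParams",
    "Connection",
    "ModelSpec",
    "GainMatrix",
    "firing_rate",
    "rate_slope",
    "voltage_for_rate",
    "synaptic_kernel",
    "gains",
    "loop_gain",
    "default_model",
]

#: Populations carrying explicit soma-potential state, in canonical order.
#: The cortical interneuron population ``i`` is implicit (V_i = V_e).
POPULATIONS: tuple[str, ...] = ("e", "r", "s", "d1", "d2", "p1", "p2", "z")

#: Glutamatergic / cholinergic sources (positive coupling), including the
#: external drive channel ``n``.
EXCITATORY_SOURCES = frozenset({"e", "s", "z", "n"})
#: GABAergic sources (negative coupling).
INHIBITORY_SOURCES = frozenset({"i", "r", "d1", "d2", "p1", "p2"})


@dataclass(frozen=True)
class PopulationParams:
    """Sigmoid response parameters of one neural population."""

    label: str
    Q_max: float  # maximal firing rate, s^-1
    theta: float  # mean firing threshold, mV
    is_excitatory: bool

    def __post_init__(self) -> None:
        if not (self.Q_max > 0 and math.isfinite(self.Q_max)):
            raise ValueError(f"Q_max must be positive and finite, got {self.Q_max}")
        if not math.isfinite(self.theta):
            raise ValueError(f"theta must be finite, got {self.theta}")


@dataclass(frozen=True)
class Connection:
    """A directed coupling ``source -> target`` with strength ``nu`` (mV s).

    ``nu`` bundles the mean synapse count and per-spike response strength into
    a single parameter; its sign is dictated by the source's neurotransmitter
    class.  ``tau`` is the mean axonal conduction delay (s).
    """

    target: str
    source: str
    nu: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"axonal delay must be non-negative, got {self.tau}")
        if self.source in INHIBITORY_SOURCES and self.nu > 0:
            raise ValueError(
                f"inhibitory source {self.source!r} requires nu <= 0, got {self.nu}"
            )
        if self.source in EXCITATORY_SOURCES and self.nu < 0:
            raise ValueError(
                f"excitatory source {self.source!r} requires nu >= 0, got {self.nu}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.target, self.source)


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of the spatially uniform CTBG system.

    ``sigma_p`` is the sigmoid threshold spread sigma' (mV), shared by all
    populations.  ``alpha`` and ``beta`` are the synaptodendritic decay and
    rise rates (s^-1) of the second-order dendritic filter, also shared.
    ``gamma_e`` is the cortical damping rate (s^-1) and ``r_e`` the cortical
    axonal range (mm); only the pyramidal field obeys wave dynamics.
    ``phi_n`` is the constant external drive rate to the specific relay
    nuclei (s^-1).
    """

    populations: Mapping[str, PopulationParams]
    connections: tuple[Connection, ...]
    sigma_p: float
    alpha: float
    beta: float
    gamma_e: float
    r_e: float
    phi_n: float

    def __post_init__(self) -> None:
        if not (self.sigma_p > 0):
            raise ValueError("sigma_p must be positive")
        if not (0 < self.alpha < self.beta):
            raise ValueError("require 0 < alpha < beta")
        if not (self.gamma_e > 0):
            raise ValueError("gamma_e must be positive")
        missing = [p for p in POPULATIONS if p not in self.populations]
        if missing:
            raise ValueError(f"missing populations: {missing}")
        for c in self.connections:
            if c.target not in POPULATIONS:
                raise ValueError(f"unknown connection target {c.target!r}")
            if c.source not in POPULATIONS and c.source not in ("i", "n"):
                raise ValueError(f"unknown connection source {c.source!r}")

    # -- lookup helpers -----------------------------------------------------

    def connection(self, target: str, source: str) -> Connection:
        for c in self.connections:
            if c.target == target and c.source == source:
                return c
        raise KeyError(f"no connection {target!r} <- {source!r}")

    def nu(self, target: str, source: str, default: float | None = None) -> float:
        try:
            return self.connection(target, source).nu
        except KeyError:
            if default is None:
                raise
            return default

    def with_updates(self, **nu_overrides: float) -> "ModelSpec":
        """Return a copy with connection strengths replaced.

        Keys are ``"<target>_<source>"``, e.g. ``with_updates(p2_z=1.8)``
        weakens the STN -> GPe coupling.
        """
        conns = list(self.connections)
        for key, value in nu_overrides.items():
            target, _, source = key.partition("_")
            for idx, c in enumerate(conns):
                if c.target == target and c.source == source:
                    conns[idx] = replace(c, nu=value)
                    break
            else:
                raise KeyError(f"no connection {target!r} <- {source!r}")
        return replace(self, connections=tuple(conns))

    def scale_couplings(self, factor: float) -> "ModelSpec":
        """Return a copy with every nu (and phi_n for factor 0) scaled."""
        conns = tuple(replace(c, nu=c.nu * factor) for c in self.connections)
        return replace(self, connections=conns)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sigma_p": self.sigma_p,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma_e": self.gamma_e,
            "r_e": self.r_e,
            "phi_n": self.phi_n,
            "populations": {
                p.label: {
                    "Q_max": p.Q_max,
                    "theta": p.theta,
                    "is_excitatory": p.is_excitatory,
                }
                for p in self.populations.values()
            },
            "connections": [
                {"target": c.target, "source": c.source, "nu": c.nu, "tau": c.tau}
                for c in self.connections
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        known = {
            "sigma_p",
            "alpha",
            "beta",
            "gamma_e",
            "r_e",
            "phi_n",
            "populations",
            "connections",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        pops = {
            label: PopulationParams(label=label, **spec)
            for label, spec in d["populations"].items()
        }
        conns = tuple(Connection(**c) for c in d["connections"])
        return cls(
            populations=pops,
            connections=conns,
            sigma_p=d["sigma_p"],
            alpha=d["alpha"],
            beta=d["beta"],
            gamma_e=d["gamma_e"],
            r_e=d["r_e"],
            phi_n=d["phi_n"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Pointwise maps
# ---------------------------------------------------------------------------


def firing_rate(V, pop: PopulationParams, sigma_p: float):
    """Sigmoidal potential-to-rate map ``S_a``.

    ``Q = Q_max / (1 + exp(-(V - theta)/sigma'))``: strictly increasing in V,
    bounded in (0, Q_max).  Accepts scalars or arrays of soma potential (mV),
    returns rates (s^-1).
    """
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite soma potential")
    with np.errstate(over="ignore"):  # deep saturation underflows to 0
        out = pop.Q_max / (1.0 + np.exp(-(V - pop.theta) / sigma_p))
    return float(out) if out.ndim == 0 else out


def rate_slope(phi_ss, pop: PopulationParams, sigma_p: float):
    """Sigmoid slope ``rho_a = dQ_a/dV_a`` expressed through the rate.

    At a steady rate ``phi`` the analytic derivative of the sigmoid is
    ``phi (1 - phi/Q_max) / sigma'`` (s^-1 mV^-1); it vanishes only at the
    saturation boundaries phi = 0 and phi = Q_max.
    """
    phi_ss = np.asarray(phi_ss, dtype=float)
    if np.any(phi_ss < 0) or np.any(phi_ss > pop.Q_max):
        raise ValueError("steady rate outside [0, Q_max]")
    out = phi_ss * (1.0 - phi_ss / pop.Q_max) / sigma_p
    return float(out) if out.ndim == 0 else out


def voltage_for_rate(phi, pop: PopulationParams, sigma_p: float):
    """Inverse sigmoid: the soma potential at which ``S_a(V) = phi``."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi >= pop.Q_max):
        raise ValueError("rate must lie strictly inside (0, Q_max)")
    out = pop.theta - sigma_p * np.log(pop.Q_max / phi - 1.0)
    return float(out) if out.ndim == 0 else out


def synaptic_kernel(alpha: float, beta: float, t):
    """Impulse response of the synaptodendritic filter ``D_ab``.

    ``h(t) = alpha*beta/(beta-alpha) * (exp(-alpha t) - exp(-beta t))`` for
    ``alpha != beta`` and ``alpha^2 t exp(-alpha t)`` in the equal-rate limit;
    non-negative with unit time-integral (unit DC gain).  The near-degenerate
    regime |beta - alpha| < 1e-9*alpha switches to the limit form to stay
    numerically continuous.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is defined for t >= 0")
    if abs(beta - alpha) < 1e-9 * alpha:
        out = alpha**2 * t * np.exp(-alpha * t)
    else:
        out = alpha * beta / (beta - alpha) * (np.exp(-alpha * t) - np.exp(-beta * t))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GainMatrix:
    """Linearized connection gains at an operating point.

    ``rho[a]`` is the sigmoid slope of population ``a`` there (s^-1 mV^-1)
    and ``G[(a, b)] = rho_a * nu_ab`` is the dimensionless gain of the
    ``b -> a`` connection: the extra output activity of ``a`` per unit extra
    input from ``b``.
    """

    rho: Mapping[str, float]
    G: Mapping[tuple[str, str], float]


def gains(steady, model: ModelSpec) -> GainMatrix:
    """Connection gain matrix ``G_ab = rho_a nu_ab`` at a fixed point."""
    rho = {
        a: rate_slope(steady.phi0[a], model.populations[a], model.sigma_p)
        for a in POPULATIONS
    }
    G = {c.key: rho[c.target] * c.nu for c in model.connections}
    return GainMatrix(rho=rho, G=G)


def loop_gain(g: GainMatrix, path: Sequence[tuple[str, str]]) -> float:
    """Product of gains along an ordered list of ``(target, source)`` edges.

    An empty path returns 1 (empty product).  Edges absent from the gain
    matrix raise ``KeyError``.
    """
    out = 1.0
    for edge in path:
        if tuple(edge) not in g.G:
            raise KeyError(f"no connection {edge[0]!r} <- {edge[1]!r}")
        out *= g.G[tuple(edge)]
    return out


# ---------------------------------------------------------------------------
# Nominal parkinsonian parameter set
# ---------------------------------------------------------------------------

_DEFAULT_POPULATIONS = {
    "e": PopulationParams("e", Q_max=300.0, theta=14.0, is_excitatory=True),
    "r": PopulationParams("r", Q_max=300.0, theta=13.0, is_excitatory=False),
    "s": PopulationParams("s", Q_max=300.0, theta=13.0, is_excitatory=True),
    "d1": PopulationParams("d1", Q_max=65.0, theta=19.0, is_excitatory=False),
    "d2": PopulationParams("d2", Q_max=65.0, theta=19.0, is_excitatory=False),
    "p1": PopulationParams("p1", Q_max=250.0, theta=10.0, is_excitatory=False),
    "p2": PopulationParams("p2", Q_max=300.0, theta=9.0, is_excitatory=False),
    "z": PopulationParams("z", Q_max=500.0, theta=10.0, is_excitatory=True),
}

_DEFAULT_CONNECTIONS = (
    Connection("e", "e", 1.2),
    Connection("e", "i", -1.5),
    Connection("e", "s", 1.1, tau=0.035),
    Connection("r", "e", 0.1, tau=0.045),
    Connection("r", "s", 0.1),
    Connection("s", "e", 1.5, tau=0.045),
    Connection("s", "r", -0.1),
    Connection("s", "p1", -0.2),
    Connection("s", "n", 0.5),
    Connection("d1", "e", 0.1),
    Connection("d1", "s", 1.0),
    Connection("d1", "d1", -0.02),
    Connection("d2", "e", 0.1),
    Connection("d2", "s", 0.1),
    Connection("d2", "d2", -0.02),
    Connection("p1", "z", 1.0),
    Connection("p1", "d1", -0.2),
    Connection("p1", "p2", -0.02),
    Connection("p2", "z", 2.4),
    Connection("p2", "d2", -0.8),
    Connection("p2", "p2", -0.2),
    Connection("z", "e", 1.3),
    Connection("z", "p2", -0.2),
)


def nominal_parameter_file():
    """Path of the packaged nominal parkinsonian parameter file (YAML)."""
    from importlib import resources

    return resources.files("ctbgsim") / "data" / "nominal_parkinsonian.yaml"


def default_model() -> ModelSpec:
    """Nominal parkinsonian parameter set.

    The STN -> GPe coupling defaults to 2.4 mV s, the strongly parkinsonian
    value sustaining a dominant GPe-STN-GPe loop resonance; use
    ``default_model().with_updates(p2_z=1.8)`` for the weaker variant.
    """
    return ModelSpec(
        populations=dict(_DEFAULT_POPULATIONS),
        connections=_DEFAULT_CONNECTIONS,
        sigma_p=3.3,
        alpha=50.0,
        beta=200.0,
        gamma_e=116.0,
        r_e=80.0,
        phi_n=1.0,
    )
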