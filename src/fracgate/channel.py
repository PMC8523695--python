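"""Two-state voltage-gated ion-channel gating kinetics.

``n`` identical channels sit on a membrane; each is closed (energy ε₁,
carrying the gating charge z·e₀ across the membrane voltage V) or open
(energy ε₂). With open fraction ``x = n₂/n`` (the open probability P₀),
the Helmholtz free energy is

    F(x) = n[(1−x)ε₁ + x ε₂] + z e₀ n (1−x) V − β⁻¹ ln Ω(x),
    ln Ω(x) = −n[(1−x)ln(1−x) + x ln x],

whose minimum is the Boltzmann sigmoid of voltage

    P₀ = 1 / (1 + exp[−β z e₀ (V − V₀)]),    V₀ = −(ε₁ − ε₂)/(z e₀):

at the threshold voltage V₀ exactly half the channels are open. A channel
whose gating is deformed (e.g. by mutation) relaxes non-Markovianly; its
open probability obeys the time-fractional equation

    D^γ P₀ = (Γ/n) { β z e₀ (V − V₀) − ln[P₀/(1−P₀)] },

which is the fractional gradient flow of F in the open-channel *count*
``n₂ = n·P₀`` (so the composite rate seen by P₀ is Γ/n; equivalently the
drift equals −(Γ/n²)·β·∂F/∂x). Its fixed point is the equilibrium sigmoid
above for every γ; the exponent only shapes the relaxation, which for
γ < 1 is Mittag-Leffler-like and drastically slower than the Markovian
exponential.

Default units are reduced: ``e₀ = 1``, β in inverse energy, V in
energy/charge. :data:`PHYSIOLOGICAL_UNITS` offers a physical preset
(e₀ in coulombs, β = 1/k_BT at 310 K, V in volts) for realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from fracgate.errors import DomainError
from fracgate.fracops import UniformGrid
from fracgate.kinetics import Trajectory, solve_fractional_ivp
from fracgate.landscapes import FreeEnergyLandscape

__all__ = [
    "ChannelParams",
    "PHYSIOLOGICAL_UNITS",
    "config_entropy",
    "free_energy",
    "channel_landscape",
    "equilibrium_open_probability",
    "open_probability_drift",
    "simulate_channel",
    "step_voltage",
]


@dataclass(frozen=True)
class ChannelParams:
    """Thermodynamic and electrical parameters of the two-state channel.

    Parameters
    ----------
    n : int
        Total channel count.
    eps1, eps2 : float
        Closed- and open-state energies ε₁, ε₂ (energy units).
    z : int
        Gating-charge valence.
    beta : float
        Inverse temperature (energy⁻¹).
    V : float
        Membrane voltage (energy/charge units).
    e0 : float, default 1.0
        Elementary charge (reduced units by default).
    """

    n: int
    eps1: float
    eps2: float
    z: int
    beta: float
    V: float
    e0: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if self.beta <= 0:
            raise DomainError(f"beta must be positive, got {self.beta}")
        if not (isinstance(self.z, (int, np.integer)) and self.z >= 1):
            raise DomainError(f"z must be an integer >= 1, got {self.z!r}")
        if self.e0 <= 0:
            raise DomainError(f"e0 must be positive, got {self.e0}")
        if not np.isfinite(self.V0):
            raise DomainError("derived threshold voltage V0 is not finite")

    @property
    def V0(self) -> float:
        """Threshold voltage V₀ = −(ε₁ − ε₂)/(z e₀) at which P₀ = ½."""
        return -(self.eps1 - self.eps2) / (self.z * self.e0)

    @property
    def voltage_bias(self) -> float:
        """Dimensionless electrochemical driving force β z e₀ (V − V₀)."""
        return self.beta * self.z * self.e0 * (self.V - self.V0)

    def at_voltage(self, V: float) -> "ChannelParams":
        return replace(self, V=V)


#: Physical-units preset: elementary charge in coulombs, β = 1/k_BT at
#: body temperature (310 K, k_B in joules), voltages in volts.
PHYSIOLOGICAL_UNITS = {
    "e0": 1.602176634e-19,
    "beta": 1.0 / (1.380649e-23 * 310.0),
}


def config_entropy(x: float, n: int = 1) -> float:
    """Configurational entropy count ln Ω(x) = −n[(1−x)ln(1−x) + x ln x].

    The mixing entropy of ``n`` two-state channels at open fraction x;
    maximal (``n ln 2``) at x = ½, tending to 0 at either boundary.
    """
    x = float(x)
    if not (0 < x < 1):
        raise DomainError(f"open fraction must lie in (0, 1), got {x}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    return -n * ((1.0 - x) * math.log1p(-x) + x * math.log(x))


def free_energy(x: float, params: ChannelParams) -> float:
    """Helmholtz free energy F(x) of the channel ensemble at open fraction x.

    Sum of the state energies, the electrical work of the gating charge of
    the still-closed channels, and −β⁻¹ times the configurational entropy.
    """
    x = float(x)
    if not (0 < x < 1):
        raise DomainError(f"open fraction must lie in (0, 1), got {x}")
    p = params
    return (
        p.n * ((1.0 - x) * p.eps1 + x * p.eps2)
        + p.z * p.e0 * p.n * (1.0 - x) * p.V
        - config_entropy(x, p.n) / p.beta
    )


def _free_energy_gradient(x, params: ChannelParams):
    """∂F/∂x = n(ε₂−ε₁) − z e₀ n V + (n/β) ln[x/(1−x)] (vectorized)."""
    x = np.asarray(x, dtype=float)
    p = params
    return (
        p.n * (p.eps2 - p.eps1)
        - p.z * p.e0 * p.n * p.V
        + (p.n / p.beta) * (np.log(x) - np.log1p(-x))
    )


def channel_landscape(params: ChannelParams) -> FreeEnergyLandscape:
    """The channel free energy as a :class:`FreeEnergyLandscape` on (0, 1)."""
    f = np.vectorize(lambda x: free_energy(x, params), otypes=[float])
    return FreeEnergyLandscape(
        f=f,
        fprime=lambda x: _free_energy_gradient(x, params),
        domain=(0.0, 1.0),
        name=f"channel(bias={params.voltage_bias:g}, n={params.n})",
    )


def equilibrium_open_probability(params: ChannelParams) -> float:
    """Equilibrium open probability P₀ = 1/(1 + exp[−β z e₀ (V − V₀)]).

    The Boltzmann sigmoid minimizing F(x): strictly in (0, 1), strictly
    increasing in V, exactly ½ at the threshold voltage V₀.
    """
    from scipy.special import expit

    return float(expit(params.voltage_bias))


def open_probability_drift(
    p: float, params: ChannelParams, Gamma_coef: float
) -> float:
    """Right-hand side of the fractional gating equation at open fraction p.

    Returns ``(Γ/n) { β z e₀ (V − V₀) − ln[p/(1−p)] }`` (units time^{−γ}).
    Vanishes exactly at the equilibrium open probability.
    """
    p = float(p)
    if not (0 < p < 1):
        raise DomainError(f"open fraction must lie in (0, 1), got {p}")
    if Gamma_coef <= 0:
        raise DomainError(f"Gamma_coef must be positive, got {Gamma_coef}")
    bias = params.voltage_bias
    return (Gamma_coef / params.n) * (bias - (math.log(p) - math.log1p(-p)))


def simulate_channel(
    params: ChannelParams,
    gamma: float,
    Gamma_coef: float,
    p0: float,
    grid: UniformGrid,
    *,
    scheme: str = "abm",
    voltage_protocol: Callable[[float], float] | None = None,
) -> Trajectory:
    """Integrate the time-fractional gating equation D^γ P₀ = drift(P₀).

    Parameters
    ----------
    params : ChannelParams
        Channel parameters (constant voltage taken from ``params.V``).
    gamma : float
        Anomalous exponent, ``0 < gamma <= 1``.
    Gamma_coef : float
        Kinetic coefficient Γ; the rate seen by the open probability is Γ/n.
    p0 : float
        Initial open fraction in (0, 1); 0.1 (mostly closed) is the
        conventional starting point for a depolarization response.
    grid : UniformGrid
        Output grid starting at t0 = 0.
    voltage_protocol : callable, optional
        ``V(t)`` overriding the constant voltage — a convenience for step
        protocols; the memory integral always spans the full history.

    Returns
    -------
    Trajectory
        Open-probability trajectory; values stay in (0, 1). ``meta``
        records the equilibrium open probability for the run's parameters.
    """
    if not (0 < p0 < 1):
        raise DomainError(f"p0 must lie in (0, 1), got {p0}")
    if not (0 < gamma <= 1):
        raise DomainError(f"gamma must lie in (0, 1], got {gamma}")

    if voltage_protocol is None:
        def rhs(_t: float, p: float) -> float:
            return open_probability_drift(p, params, Gamma_coef)
    else:
        def rhs(t: float, p: float) -> float:
            return open_probability_drift(
                p, params.at_voltage(float(voltage_protocol(t))), Gamma_coef
            )

    states, clamps = solve_fractional_ivp(
        rhs, gamma, p0, grid, domain=(0.0, 1.0), scheme=scheme
    )
    meta = {
        "model": "two-state channel",
        "gamma": gamma,
        "Gamma_coef": Gamma_coef,
        "rate": Gamma_coef / params.n,
        "n": params.n,
        "voltage_bias": params.voltage_bias,
        "V0": params.V0,
        "p0": p0,
        "dt": grid.dt,
        "n_steps": grid.n_steps,
        "scheme": scheme,
        "clamp_count": int(clamps),
        "equilibrium_open_probability": equilibrium_open_probability(params),
    }
    return Trajectory(times=grid.times, states=states, meta=meta)


def step_voltage(V_before: float, V_after: float, t_switch: float):
    """Voltage step protocol V(t): ``V_before`` for t < t_switch, then
    ``V_after`` — a convenience for simulating depolarization steps."""
    def V(t: float) -> float:
        return V_before if t < t_switch else V_after

    return V
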