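"""Solver for the time-fractional kinetic equation on a free-energy landscape.

The governing equation is the fractional gradient flow

    D^γ x(t) = −Γ β ∂F/∂x(x(t)),      0 < γ ≤ 1,

with anomalous exponent γ, kinetic coefficient Γ, inverse temperature β and
Helmholtz free energy F. The fractional derivative is taken in the Caputo
sense, the standard well-posed reading for a physical initial condition
``x(0) = x0``: it coincides with the Riemann-Liouville operator whenever
``x0 = 0``, and :func:`fracgate.fracops.rl_derivative` is available for
verifying the Riemann-Liouville residual of a computed trajectory directly.

On a quadratic landscape ``F = ½κx²`` the equation is linear,
``D^γ x = −λ x`` with ``λ = Γβκ``, and the exact solution is the
Mittag-Leffler relaxation ``x0 E_γ(−λ t^γ)``; this is the solver's
principal analytic oracle. Time is dimensionless (``τ = 1`` convention), so
``Γβ`` is the single composite rate constant a user effectively controls.

Two schemes are provided:

* ``"abm"`` (default): the Adams-Bashforth-Moulton fractional
  predictor-corrector (fractional Adams method) with one corrector pass.
  At γ = 1 it reduces exactly to the classical Heun predictor-corrector.
* ``"implicit_gl"``: backward Grünwald-Letnikov stepping with a scalar
  nonlinear solve per step, for stiff landscapes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.optimize import brentq

from fracgate.errors import DomainError, RootNotFoundError, SolverError
from fracgate.fracops import UniformGrid, gl_weights
from fracgate.landscapes import FreeEnergyLandscape

__all__ = [
    "KineticConfig",
    "Trajectory",
    "gamma_from_delta",
    "solve_fractional_kinetic",
    "solve_fractional_ivp",
    "stationary_state",
]


@dataclass(frozen=True)
class KineticConfig:
    """Configuration of a fractional kinetic run.

    Parameters
    ----------
    gamma : float
        Anomalous exponent, ``0 < gamma <= 1`` (1 = Markovian limit).
    Gamma_coef : float
        Kinetic coefficient Γ (units state²·energy⁻¹·time^{−γ}). Distinct
        from the Gamma *function*; the two share a symbol in the field's
        notation but never in this package.
    beta : float
        Inverse temperature (energy⁻¹).
    x0 : float
        Initial state; must lie in the landscape domain interior.
    grid : UniformGrid
        Output time grid; must start at t0 = 0.
    scheme : str
        ``"abm"`` or ``"implicit_gl"``.
    corrector_passes : int
        Number of corrector sweeps per ABM step (>= 1).
    clamp_margin : float
        Distance from the domain boundary at which exiting states are
        clamped back inside (divergent landscapes such as the channel's
        entropy term make overshoot fatal otherwise).
    """

    gamma: float
    Gamma_coef: float
    beta: float
    x0: float
    grid: UniformGrid
    scheme: str = "abm"
    corrector_passes: int = 1
    clamp_margin: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1):
            raise DomainError(f"gamma must lie in (0, 1], got {self.gamma}")
        if self.Gamma_coef <= 0:
            raise DomainError(f"Gamma_coef must be positive, got {self.Gamma_coef}")
        if self.beta <= 0:
            raise DomainError(f"beta must be positive, got {self.beta}")
        if self.scheme not in ("abm", "implicit_gl"):
            raise DomainError(f"unknown scheme {self.scheme!r}")
        if self.corrector_passes < 1:
            raise DomainError("corrector_passes must be >= 1")
        if self.grid.t0 != 0.0:
            raise DomainError("fractional kinetics requires a grid with t0 = 0")


@dataclass
class Trajectory:
    """Solver output: states on a uniform time grid plus run metadata.

    ``meta`` echoes the configuration and records diagnostics, notably
    ``clamp_count`` (how often the state had to be pulled back into the
    landscape domain).
    """

    times: np.ndarray
    states: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise DomainError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")

    def to_frame(self, state_column: str = "x"):
        import pandas as pd

        return pd.DataFrame({"t": self.times, state_column: self.states})


def gamma_from_delta(Delta: float, m: int) -> float:
    """Kinetic coefficient from the spatial kernel width: Γ = (2πΔ)^{m/2} Δ.

    ``Delta`` is the Gaussian width of the jump kernel (state² units) and
    ``m`` the number of state dimensions collapsed into the coefficient.
    """
    if Delta <= 0:
        raise DomainError(f"Delta must be positive, got {Delta}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise DomainError(f"m must be an integer >= 1, got {m!r}")
    return (2.0 * math.pi * Delta) ** (m / 2.0) * Delta


def _clamped(x: float, lo: float, hi: float, margin: float) -> tuple[float, bool]:
    if x <= lo:
        return (lo + margin if np.isfinite(lo) else x), np.isfinite(lo)
    if x >= hi:
        return (hi - margin if np.isfinite(hi) else x), np.isfinite(hi)
    return x, False


def solve_fractional_ivp(
    rhs: Callable[[float, float], float],
    gamma: float,
    x0: float,
    grid: UniformGrid,
    *,
    domain: tuple[float, float] = (-np.inf, np.inf),
    scheme: str = "abm",
    corrector_passes: int = 1,
    clamp_margin: float = 1e-12,
) -> tuple[np.ndarray, int]:
    """Integrate the Caputo initial-value problem D^γ x = rhs(t, x).

    Returns ``(states, clamp_count)`` on the grid. This is the scheme core
    shared by :func:`solve_fractional_kinetic` and the channel simulator;
    ``rhs`` may depend on time (step-voltage protocols use this).

    The default scheme is the fractional Adams-Bashforth-Moulton
    predictor-corrector; ``"implicit_gl"`` selects backward
    Grünwald-Letnikov stepping (a Newton-free bracketed solve per step).
    """
    if not (0 < gamma <= 1):
        raise DomainError(f"gamma must lie in (0, 1], got {gamma}")
    lo, hi = domain
    n = grid.n_steps
    h = grid.dt
    t = grid.times
    x = np.empty(n + 1)
    x[0] = x0
    clamps = 0

    def eval_rhs(tj: float, xj: float, j: int) -> float:
        v = rhs(tj, xj)
        if not np.isfinite(v):
            raise SolverError(
                f"non-finite drift at step {j} (t={tj:g}, x={xj:g})", step=j
            )
        return v

    if scheme == "abm":
        g_hist = np.empty(n + 1)
        g_hist[0] = eval_rhs(t[0], x[0], 0)
        # corrector kernel: phi[m] multiplies g_{j-m}, m = 0..j-1
        phi = (np.arange(2, n + 3) ** (gamma + 1.0)
               + np.arange(0, n + 1) ** (gamma + 1.0)
               - 2.0 * np.arange(1, n + 2) ** (gamma + 1.0))
        # predictor kernel psi[m] = (m+1)^γ − m^γ multiplies g_{n-m}
        psi = np.arange(1, n + 2) ** gamma - np.arange(0, n + 1) ** gamma
        ch = h**gamma / math.gamma(gamma + 2.0)
        bh = h**gamma / math.gamma(gamma + 1.0)
        for j in range(n):
            gs = g_hist[: j + 1]
            # predictor: x0 + (h^γ/Γ(γ+1)) Σ ψ_m g_{j−m}
            xp = x0 + bh * np.dot(psi[: j + 1], gs[::-1])
            xp, was = _clamped(xp, lo, hi, clamp_margin)
            clamps += was
            # corrector weight for g_0 at step j+1: j^{γ+1} − (j−γ)(j+1)^γ
            a0 = j ** (gamma + 1.0) - (j - gamma) * (j + 1.0) ** gamma
            hist = np.dot(phi[:j], gs[1:][::-1]) + a0 * gs[0]
            xc = xp
            for _ in range(corrector_passes):
                gp = eval_rhs(t[j + 1], xc, j + 1)
                xc = x0 + ch * (gp + hist)
                xc, was = _clamped(xc, lo, hi, clamp_margin)
                clamps += was
            x[j + 1] = xc
            g_hist[j + 1] = eval_rhs(t[j + 1], xc, j + 1)
    else:  # implicit_gl
        w = gl_weights(gamma, n)
        hg = h**gamma
        y = x - x0  # work in the increment so Caputo == RL
        for j in range(1, n + 1):
            # w0 y_j + Σ_{k>=1} w_k y_{j-k} = h^γ rhs(t_j, x0 + y_j)
            tail = np.dot(w[1: j + 1], (x[j - 1:: -1] - x0)[: j])

            def resid(yj: float) -> float:
                return yj + tail - hg * rhs(t[j], x0 + yj)

            guess = x[j - 1] - x0
            step0 = max(abs(guess), 1.0) * 0.5 + hg
            a, b = guess - step0, guess + step0
            if np.isfinite(lo):
                a = max(a, lo - x0 + clamp_margin)
            if np.isfinite(hi):
                b = min(b, hi - x0 - clamp_margin)
            fa, fb = resid(a), resid(b)
            tries = 0
            while fa * fb > 0 and tries < 60:
                a2, b2 = a - (b - a), b + (b - a)
                if np.isfinite(lo):
                    a2 = max(a2, lo - x0 + clamp_margin)
                if np.isfinite(hi):
                    b2 = min(b2, hi - x0 - clamp_margin)
                if (a2, b2) == (a, b):
                    break
                a, b = a2, b2
                fa, fb = resid(a), resid(b)
                tries += 1
            if fa * fb > 0:
                raise SolverError(
                    f"implicit step {j} found no bracketing interval", step=j
                )
            yj = brentq(resid, a, b, xtol=1e-14, rtol=8.9e-16)
            xj, was = _clamped(x0 + yj, lo, hi, clamp_margin)
            clamps += was
            x[j] = xj
    return x, clamps


def solve_fractional_kinetic(
    landscape: FreeEnergyLandscape, config: KineticConfig
) -> Trajectory:
    """Integrate D^γ x = −Γβ F'(x) from x(0) = x0 on the configured grid.

    Returns a :class:`Trajectory`; ``meta`` carries the configuration, the
    scheme used and the clamp counter. States exiting the landscape domain
    are clamped to the interior (at ``clamp_margin`` from the boundary) with
    a warning, so that a single overshoot cannot poison the convolution
    history of the memory integral.
    """
    if not landscape.contains(config.x0):
        raise DomainError(
            f"x0={config.x0} is outside the landscape domain {landscape.domain}"
        )
    rate = config.Gamma_coef * config.beta

    def rhs(_t: float, x: float) -> float:
        return -rate * float(landscape.fprime(x))

    states, clamps = solve_fractional_ivp(
        rhs,
        config.gamma,
        config.x0,
        config.grid,
        domain=landscape.domain,
        scheme=config.scheme,
        corrector_passes=config.corrector_passes,
        clamp_margin=config.clamp_margin,
    )
    if clamps:
        warnings.warn(
            f"state clamped to the landscape domain {clamps} time(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    meta = {
        "landscape": landscape.name,
        "gamma": config.gamma,
        "Gamma_coef": config.Gamma_coef,
        "beta": config.beta,
        "x0": config.x0,
        "dt": config.grid.dt,
        "n_steps": config.grid.n_steps,
        "scheme": config.scheme,
        "clamp_count": int(clamps),
    }
    return Trajectory(times=config.grid.times, states=states, meta=meta)


def stationary_state(
    landscape: FreeEnergyLandscape, x_guess: float, *, max_expand: int = 60
) -> float:
    """Zero of the drift: the x* with F'(x*) = 0 nearest the guess.

    Brackets a sign change of ``fprime`` by symmetric expansion around the
    guess (truncated at the domain), then bisects with Brent's method.
    The result is independent of the anomalous exponent γ: memory changes
    how the stationary point is approached, never where it is.

    Raises
    ------
    RootNotFoundError
        If no sign change of ``fprime`` is found within the domain.
    """
    if not landscape.contains(x_guess):
        raise DomainError(f"x_guess={x_guess} outside domain {landscape.domain}")
    fp = lambda x: float(landscape.fprime(x))
    v0 = fp(x_guess)
    if abs(v0) < 1e-14:
        return x_guess
    lo, hi = landscape.domain
    margin = 1e-12
    step = 1e-3 * max(1.0, abs(x_guess))
    for _ in range(max_expand):
        a = x_guess - step if not np.isfinite(lo) else max(x_guess - step, lo + margin)
        b = x_guess + step if not np.isfinite(hi) else min(x_guess + step, hi - margin)
        fa, fb = fp(a), fp(b)
        if fa * fb <= 0:
            root = brentq(fp, a, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
            if abs(fp(root)) >= 1e-10:
                raise RootNotFoundError(
                    f"root refinement stalled: |fprime({root:g})| = {abs(fp(root)):.2e}"
                )
            return float(root)
        if fa * v0 <= 0:
            root = brentq(fp, a, x_guess, xtol=1e-15, rtol=8.9e-16, maxiter=200)
            return float(root)
        if fb * v0 <= 0:
            root = brentq(fp, x_guess, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
            return float(root)
        step *= 2.0
        if (not np.isfinite(lo) or a <= lo + 2 * margin) and (
            np.isfinite(hi) and b >= hi - 2 * margin
        ) and np.isfinite(lo):
            break
    raise RootNotFoundError(
        f"no sign change of fprime found around x_guess={x_guess} "
        f"within domain {landscape.domain}"
    )
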