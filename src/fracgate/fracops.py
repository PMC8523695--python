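"""Discrete fractional-calculus operators and the power-law memory kernel.

Non-Markovian kinetics with a long-tailed waiting-time distribution carries
the memory kernel ``Π(t) = (1/Γ(γ)) (t/τ)^{γ−1}`` with anomalous exponent
``0 < γ < 1``. The associated fractional derivatives are discretized on
uniform grids with the Grünwald-Letnikov (GL) convolution

    D^γ f(t_j) ≈ dt^{−γ} Σ_{k=0..j} w_k f(t_{j−k}),
    w_0 = 1,  w_k = w_{k−1} (1 − (γ+1)/k),

which is first-order accurate in ``dt`` and reduces to the backward first
difference at γ = 1. Two operator conventions are exposed:

* Riemann-Liouville (``rl_derivative``): GL applied to the samples as given;
  the RL derivative of a nonzero constant is ``c t^{−γ}/Γ(1−γ)``, not zero.
* Caputo (``caputo_derivative``): GL applied to the increment from the
  initial value. Caputo annihilates constants and is the convention used
  for all initial-value problems in this package; it coincides with
  Riemann-Liouville whenever ``f(0) = 0``.

The lower terminal of the fractional integral is always ``t = 0``, so grids
used with these operators start at ``t0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gammafn

from fracgate.errors import DomainError

__all__ = [
    "MemoryKernelParams",
    "UniformGrid",
    "memory_kernel",
    "gl_weights",
    "rl_derivative",
    "caputo_derivative",
]


@dataclass(frozen=True)
class MemoryKernelParams:
    """Power-law memory kernel parameters.

    Parameters
    ----------
    gamma : float
        Anomalous exponent, ``0 < gamma < 1`` (``gamma = 1`` is accepted as
        the memoryless Markovian degenerate case).
    tau : float, default 1.0
        Macroscopic relaxation parameter setting the time scale of the
        kernel. It enters only kernel evaluation; the solvers work in the
        dimensionless-time convention ``tau = 1``.
    """

    gamma: float
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1):
            raise DomainError(f"gamma must lie in (0, 1], got {self.gamma}")
        if not (self.tau > 0):
            raise DomainError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class UniformGrid:
    """Uniform time grid t_j = t0 + j·dt, j = 0..n_steps (n_steps+1 points)."""

    dt: float
    n_steps: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise DomainError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise DomainError(f"n_steps must be >= 1, got {self.n_steps}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * self.n_steps


def memory_kernel(t, params: MemoryKernelParams):
    """Power-law waiting-time memory kernel Π(t) = (t/τ)^{γ−1} / Γ(γ).

    Positive and strictly decreasing for ``0 < γ < 1``; identically 1 in
    the Markovian limit ``γ = 1``. Diverges as ``t → 0⁺``, hence ``t > 0``
    is required.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("memory_kernel requires t > 0 (kernel diverges at 0)")
    out = (t / params.tau) ** (params.gamma - 1.0) / _gammafn(params.gamma)
    return float(out) if out.ndim == 0 else out


def gl_weights(gamma: float, n: int) -> np.ndarray:
    """Grünwald-Letnikov convolution weights w_k = (−1)^k C(γ, k), k = 0..n.

    Computed by the stable recursion ``w_k = w_{k−1} (1 − (γ+1)/k)``.
    For ``0 < γ < 1``: ``w_0 = 1 > 0``, every later weight is negative, and
    the weights sum to zero over the full (infinite) sequence.
    """
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    k = np.arange(1, n + 1, dtype=float)
    factors = 1.0 - (gamma + 1.0) / k
    w = np.empty(n + 1)
    w[0] = 1.0
    if n:
        w[1:] = np.cumprod(factors)
    return w


def _gl_convolve(values: np.ndarray, order: float, dt: float) -> np.ndarray:
    n = len(values) - 1
    w = gl_weights(order, n)
    # full convolution, keep the causal part: out[j] = sum_k w[k] v[j-k]
    conv = np.convolve(w, values)[: n + 1]
    return conv * dt ** (-order)


def rl_derivative(values, order: float, grid: UniformGrid | None = None,
                  *, dt: float | None = None) -> np.ndarray:
    """Riemann-Liouville fractional derivative of sampled values (GL scheme).

    Parameters
    ----------
    values : array_like
        Samples on a uniform grid starting at t = 0.
    order : float
        Derivative order, ``0 < order < 1``.
    grid : UniformGrid, optional
        Grid the samples live on (its ``dt`` is used); alternatively pass
        ``dt`` directly.

    Returns
    -------
    numpy.ndarray
        The derivative at every grid point, first-order accurate in dt.
        Note the value at t = 0 is the degenerate single-term estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("rl_derivative requires a non-empty sample array")
    if not (0 < order < 1):
        raise DomainError(f"order must lie in (0, 1), got {order}")
    if grid is not None:
        if grid.t0 != 0.0:
            raise DomainError("fractional operators require grids with t0 = 0")
        dt = grid.dt
    if dt is None or dt <= 0:
        raise DomainError("a positive dt (or a grid) is required")
    return _gl_convolve(values, order, dt)


def caputo_derivative(values, order: float, grid: UniformGrid | None = None,
                      *, dt: float | None = None) -> np.ndarray:
    """Caputo fractional derivative: Riemann-Liouville of values − values[0].

    Annihilates constants, equals :func:`rl_derivative` when the initial
    sample is zero; this is the convention the initial-value solvers use.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("caputo_derivative requires a non-empty sample array")
    return rl_derivative(values - values[0], order, grid, dt=dt)
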