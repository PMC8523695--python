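"""Lattice time-fractional generalized master equation.

The probability field P(x, t) on a uniform state lattice evolves under

    ∂P/∂t = D^{1−γ} Σ_{x'} W(x, x') P(x', t),

where the Riemann-Liouville operator D^{1−γ} carries the power-law memory
of the waiting-time distribution and W is the free-energy transition
kernel (Langer/Glauber form)

    W(x, x') = exp[−(x − x')²/Δ] · exp[−(β/2)(F(x) − F(x'))],   x ≠ x',

with the diagonal fixed by conservation (columns sum to zero). The kernel
satisfies detailed balance exactly —
``W(x'→x)/W(x→x') = exp[−β(F(x) − F(x'))]`` — so the stationary state is
the Boltzmann distribution ∝ exp(−βF) for every γ: memory reshapes the
approach to equilibrium (Mittag-Leffler instead of exponential, variance
growing as t^γ on a flat landscape), never the target.

Convention: ``W[i, j]`` is the rate from lattice point j to i
(column-generator layout), so propagation is the matrix-vector product
``W @ P``. Time stepping uses the Grünwald-Letnikov discretization of
D^{1−γ} on the history of W·P, explicit by default with a stability guard,
or implicit (unconditionally stable in practice) for long horizons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from fracgate.errors import DomainError, StabilityError, StructureError
from fracgate.fracops import UniformGrid, gl_weights
from fracgate.landscapes import FreeEnergyLandscape

__all__ = [
    "LatticeGME",
    "ProbabilityField",
    "build_rate_matrix",
    "propagate_gme",
    "stationary_distribution",
    "field_variance",
]

#: off-diagonal entries below this (relative to the nearest-neighbor rate)
#: are dropped when choosing the default neighbor cutoff
_CUTOFF_FLOOR = 1e-12


@dataclass(frozen=True)
class LatticeGME:
    """Discretized state space with its transition-rate matrix.

    Attributes
    ----------
    xs : numpy.ndarray
        Uniformly spaced lattice points.
    W : numpy.ndarray
        Rate matrix (time^{−γ} units); ``W[i, j]`` is the j→i rate,
        columns sum to zero.
    Delta : float
        Spatial kernel width Δ (state² units).
    beta : float
        Inverse temperature.
    gamma : float
        Anomalous exponent used when propagating, ``0 < gamma <= 1``.
    """

    xs: np.ndarray
    W: np.ndarray
    Delta: float
    beta: float
    gamma: float = 1.0
    landscape_name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "xs", np.asarray(self.xs, dtype=float))
        object.__setattr__(self, "W", np.asarray(self.W, dtype=float))
        if self.W.shape != (len(self.xs), len(self.xs)):
            raise DomainError("W must be square with one row per lattice point")
        if not (0 < self.gamma <= 1):
            raise DomainError(f"gamma must lie in (0, 1], got {self.gamma}")

    @property
    def dx(self) -> float:
        return float(self.xs[1] - self.xs[0])

    def stable_dt(self, safety: float = 0.5) -> float:
        """Explicit-scheme step-size guide: dt with dt^γ·max|W_jj| = safety."""
        peak = float(np.max(np.abs(np.diag(self.W))))
        if peak == 0.0:
            return np.inf
        return (safety / peak) ** (1.0 / self.gamma)


@dataclass
class ProbabilityField:
    """Probability mass on the lattice at one time stamp."""

    values: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise DomainError("probability mass below the undershoot tolerance")
        if abs(self.values.sum() - 1.0) > 1e-10:
            raise DomainError(
                f"probabilities must sum to 1 (got {self.values.sum()!r})"
            )


def build_rate_matrix(
    landscape: FreeEnergyLandscape,
    xs,
    Delta: float,
    beta: float,
    cutoff: int | None = None,
    gamma: float = 1.0,
) -> LatticeGME:
    """Assemble the free-energy transition kernel on a uniform lattice.

    Off-diagonal entries ``W[i, j] = exp[−(x_i−x_j)²/Δ]·
    exp[−(β/2)(F(x_i)−F(x_j))]`` for ``|i−j| <= cutoff`` (zero beyond);
    diagonal entries are the negated column sums. The default cutoff keeps
    every neighbor whose Gaussian jump factor exceeds 1e-12; boundary
    columns simply have fewer neighbors (reflection by truncation).
    """
    xs = np.asarray(xs, dtype=float)
    if len(xs) < 3:
        raise DomainError("lattice needs at least 3 points")
    dxs = np.diff(xs)
    if not np.allclose(dxs, dxs[0], rtol=1e-10, atol=0.0):
        raise DomainError("lattice must be uniformly spaced")
    if Delta <= 0:
        raise DomainError(f"Delta must be positive, got {Delta}")
    if beta <= 0:
        raise DomainError(f"beta must be positive, got {beta}")
    dx = float(dxs[0])
    if cutoff is None:
        k = np.arange(1, len(xs))
        keep = np.exp(-((dx * k) ** 2) / Delta) >= _CUTOFF_FLOOR
        cutoff = int(max(1, keep.sum()))
    if cutoff < 1:
        raise DomainError(f"cutoff must be >= 1, got {cutoff}")

    F = np.asarray(landscape.f(xs), dtype=float)
    if not np.all(np.isfinite(F)):
        raise DomainError("free energy is non-finite on the lattice")
    dx2 = (xs[:, None] - xs[None, :]) ** 2
    W = np.exp(-dx2 / Delta) * np.exp(-0.5 * beta * (F[:, None] - F[None, :]))
    lag = np.abs(np.subtract.outer(np.arange(len(xs)), np.arange(len(xs))))
    W[(lag > cutoff) | (lag == 0)] = 0.0
    np.fill_diagonal(W, -W.sum(axis=0))
    return LatticeGME(
        xs=xs, W=W, Delta=Delta, beta=beta, gamma=gamma,
        landscape_name=landscape.name,
    )


def propagate_gme(
    gme: LatticeGME,
    p0: ProbabilityField,
    grid: UniformGrid,
    *,
    scheme: str = "explicit",
) -> list[ProbabilityField]:
    """Advance ∂P/∂t = D^{1−γ}[W P] on the grid; returns all time slices.

    The Grünwald-Letnikov discretization of the Riemann-Liouville operator
    acts on the full history of W·P:

        P^{m+1} = P^m + dt^γ Σ_{k=0..m} w_k^{(1−γ)} (W P)^{m−k}

    (explicit; the implicit variant moves the k = 0 term to the new time
    level and solves a pre-factorized linear system per step). Columns of W
    sum to zero, so total mass is conserved to round-off at every step.

    Raises
    ------
    StabilityError
        If the explicit iteration blows up (any |P| > 2); the error carries
        the maximal stable dt estimate.
    """
    if scheme not in ("explicit", "implicit"):
        raise DomainError(f"unknown scheme {scheme!r}")
    if len(p0.values) != len(gme.xs):
        raise DomainError("p0 length does not match the lattice")
    gamma = gme.gamma
    n = grid.n_steps
    dt = grid.dt
    dtg = dt**gamma
    w = gl_weights(1.0 - gamma, n + 1)
    W = gme.W
    times = grid.times

    if scheme == "explicit" and dtg * np.max(np.abs(np.diag(W))) > 0.5:
        warnings.warn(
            f"dt^gamma * max|W_jj| = {dtg * np.max(np.abs(np.diag(W))):.3g} "
            f"> 0.5; explicit propagation may be unstable "
            f"(stable dt estimate: {gme.stable_dt():.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    P = np.empty((n + 1, len(gme.xs)))
    P[0] = p0.values
    G = np.empty_like(P)  # history of W @ P
    G[0] = W @ P[0]
    if scheme == "explicit":
        markovian = gamma == 1.0  # w_k = 0 for k >= 1: no memory to carry
        for m in range(n):
            # Σ_{k=0..m} w_k G^{m−k} = w[:m+1] · G[m::-1]
            if markovian:
                P[m + 1] = P[m] + dtg * G[m]
            else:
                P[m + 1] = P[m] + dtg * (w[: m + 1] @ G[m::-1])
            if np.max(np.abs(P[m + 1])) > 2.0:
                raise StabilityError(
                    f"explicit propagation unstable at step {m + 1}; "
                    f"reduce dt below ~{gme.stable_dt():.3g}",
                    dt_max=gme.stable_dt(),
                )
            G[m + 1] = W @ P[m + 1]
    else:
        lu = lu_factor(np.eye(len(gme.xs)) - dtg * w[0] * W)
        for m in range(n):
            hist = w[1: m + 2] @ G[m::-1] if m >= 0 else 0.0
            P[m + 1] = lu_solve(lu, P[m] + dtg * hist)
            G[m + 1] = W @ P[m + 1]

    out = []
    for m in range(n + 1):
        vals = P[m]
        total = vals.sum()
        if abs(total - 1.0) > 1e-10:
            raise StabilityError(
                f"mass conservation violated at t={times[m]:g}: sum={total!r}"
            )
        out.append(ProbabilityField(values=np.clip(vals, -1e-12, None), t=times[m]))
    return out


def stationary_distribution(gme: LatticeGME) -> ProbabilityField:
    """Normalized null vector of W — the Boltzmann distribution on the lattice.

    Detailed balance of the kernel makes ``π_j ∝ exp(−βF(x_j))`` an exact
    null vector; this routine recovers it numerically from W alone (via the
    singular vector of the smallest singular value) so tests can compare
    the two routes independently.

    Raises
    ------
    StructureError
        If the null space of W is degenerate (disconnected lattice).
    """
    _, s, vt = np.linalg.svd(gme.W)
    scale = max(s[0], 1.0)
    if s[-1] > 1e-9 * scale:
        raise StructureError("W has no null vector: not a conservative generator")
    if len(s) > 1 and s[-2] < 1e-12 * scale:
        raise StructureError("degenerate null space: lattice is disconnected")
    v = vt[-1]
    v = v * np.sign(v.sum())
    if np.any(v < -1e-10 * np.max(np.abs(v))):
        raise StructureError("null vector is not sign-definite")
    v = np.clip(v, 0.0, None)
    return ProbabilityField(values=v / v.sum(), t=np.inf)


def field_variance(fields: Sequence[ProbabilityField], xs) -> np.ndarray:
    """Variance of the lattice position under each probability field."""
    xs = np.asarray(xs, dtype=float)
    out = np.empty(len(fields))
    for i, f in enumerate(fields):
        mean = float(f.values @ xs)
        out[i] = float(f.values @ (xs - mean) ** 2)
    return out
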