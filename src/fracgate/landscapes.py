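"""One-dimensional free-energy landscapes.

A landscape supplies the Helmholtz free energy ``F(x)`` and its derivative
``∂F/∂x`` over a stated domain; the kinetic equation relaxes the state down
this gradient. Built-in landscapes cover the shapes used throughout the
tests and CLI: quadratic wells, a symmetric double well, a flat landscape,
and the two-state ion-channel free energy (constructed in
:mod:`fracgate.channel`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from fracgate.errors import DomainError

__all__ = ["FreeEnergyLandscape", "quadratic", "double_well", "flat"]


@dataclass(frozen=True)
class FreeEnergyLandscape:
    """Free energy F(x) with analytic gradient on a closed interval domain.

    Attributes
    ----------
    f : callable
        Free energy; must accept scalars and numpy arrays.
    fprime : callable
        Derivative ∂F/∂x, consistent with ``f``.
    domain : tuple of float
        Closed interval ``(lo, hi)`` of valid states; ``lo < hi`` and
        infinite endpoints are allowed.
    name : str
        Short label used in output summaries.
    """

    f: Callable[[np.ndarray], np.ndarray]
    fprime: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float] = (-np.inf, np.inf)
    name: str = "custom"

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise DomainError(f"domain must satisfy lo < hi, got {self.domain}")

    def contains(self, x: float) -> bool:
        lo, hi = self.domain
        return lo < x < hi

    def validate_gradient(self, n_probe: int = 20, h: float = 1e-5,
                          atol: float = 1e-4) -> None:
        """Check fprime against a central difference of f at interior points.

        Raises
        ------
        DomainError
            If the analytic gradient disagrees with the central difference
            by more than ``atol`` at any probe point, or f is non-finite.
        """
        lo, hi = self.domain
        lo = max(lo, -1e3)
        hi = min(hi, 1e3)
        pad = 0.05 * (hi - lo)
        xs = np.linspace(lo + pad, hi - pad, n_probe)
        fx = np.asarray(self.f(xs), dtype=float)
        if not np.all(np.isfinite(fx)):
            raise DomainError("f is non-finite on the domain interior")
        num = (np.asarray(self.f(xs + h)) - np.asarray(self.f(xs - h))) / (2 * h)
        ana = np.asarray(self.fprime(xs), dtype=float)
        err = np.max(np.abs(num - ana))
        if err >= atol:
            raise DomainError(
                f"fprime disagrees with the central difference of f "
                f"(max abs error {err:.3e} >= {atol:.0e})"
            )


def quadratic(kappa: float = 1.0, center: float = 0.0) -> FreeEnergyLandscape:
    """Harmonic well F(x) = ½ κ (x − a)²; the linear-relaxation benchmark."""
    if kappa <= 0:
        raise DomainError(f"kappa must be positive, got {kappa}")
    return FreeEnergyLandscape(
        f=lambda x: 0.5 * kappa * (np.asarray(x, dtype=float) - center) ** 2,
        fprime=lambda x: kappa * (np.asarray(x, dtype=float) - center),
        name=f"quadratic(kappa={kappa:g}, center={center:g})",
    )


def double_well(barrier: float = 0.25) -> FreeEnergyLandscape:
    """Symmetric double well F(x) = b (x² − 1)², minima at x = ±1.

    The default ``barrier = 0.25`` gives F = (x²−1)²/4 with
    F'(x) = x³ − x.
    """
    if barrier <= 0:
        raise DomainError(f"barrier must be positive, got {barrier}")
    b = barrier
    return FreeEnergyLandscape(
        f=lambda x: b * (np.asarray(x, dtype=float) ** 2 - 1.0) ** 2,
        fprime=lambda x: 4.0 * b * np.asarray(x, dtype=float)
        * (np.asarray(x, dtype=float) ** 2 - 1.0),
        name=f"double_well(barrier={b:g})",
    )


def flat() -> FreeEnergyLandscape:
    """Flat landscape F ≡ 0 (free subdiffusion on the lattice)."""
    return FreeEnergyLandscape(
        f=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        fprime=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        name="flat",
    )


BUILTIN_LANDSCAPES: dict[str, Callable[..., FreeEnergyLandscape]] = {
    "quadratic": quadratic,
    "double-well": double_well,
    "flat": flat,
}
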