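"""Numerical evaluation of the Mittag-Leffler function.

The two-parameter Mittag-Leffler function

    E_{α,β}(z) = Σ_{k≥0} z^k / Γ(αk + β),        α > 0,

generalizes the exponential (``E_{1,1} = exp``) and is the relaxation law of
linear time-fractional kinetics: the linearized fractional kinetic equation
``D^γ x = −λ x`` (Caputo sense) has the solution ``x(t) = x(0) E_γ(−λ t^γ)``,
which interpolates between stretched-exponential decay at short times and
the power-law tail ``t^{−γ} / (λ Γ(1−γ))`` at long times.

Evaluation strategy (real arguments only — the kinetic equation needs real,
typically negative, arguments):

* small ``|z|`` and all ``z ≥ 0``: the defining Taylor series in float64
  (for negative arguments only while catastrophic cancellation is provably
  below tolerance);
* ``z < 0`` with ``0 < α < 1`` and ``β = 1``: the completely-monotone
  spectral representation, an absolutely convergent integral evaluated with
  adaptive quadrature — accurate uniformly in ``|z|``;
* large negative ``z`` otherwise: the algebraic asymptotic expansion
  ``−Σ_{k=1..K} z^{−k} / Γ(β − αk)``, accepted only when its smallest term
  meets the tolerance;
* everything else: arbitrary-precision summation of the Taylor series with
  mpmath at a working precision scaled to the cancellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as _gammafn

from fracgate.errors import DomainError, EvaluationError

__all__ = ["MLParams", "mittag_leffler", "ml_relaxation"]

_MAX_TERMS = 10_000


@dataclass(frozen=True)
class MLParams:
    """Parameters of the two-parameter Mittag-Leffler function E_{α,β}.

    Parameters
    ----------
    alpha : float
        Order parameter; ``0 < alpha <= 2`` is the supported range.
    beta : float, default 1.0
        Second parameter; ``beta = 1`` gives the one-parameter function.
    tol : float, default 1e-10
        Relative tolerance of the evaluation. Must lie in ``(0, 1e-6]``.
    z_switch : float, default 5.0
        Nominal size of the Taylor region (shrunk automatically where
        float64 cancellation would exceed ``tol``).
    n_asymptotic : int, default 10
        Number of terms attempted in the asymptotic expansion.
    """

    alpha: float
    beta: float = 1.0
    tol: float = 1e-10
    z_switch: float = 5.0
    n_asymptotic: int = 10

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise DomainError(f"alpha must be positive, got {self.alpha}")
        if not (0 < self.tol <= 1e-6):
            raise DomainError(f"tol must lie in (0, 1e-6], got {self.tol}")
        if self.z_switch <= 0 or self.n_asymptotic < 1:
            raise DomainError("z_switch must be > 0 and n_asymptotic >= 1")


def _taylor_float(z: float, alpha: float, beta: float, tol: float) -> float:
    """Float64 Taylor series; caller guarantees cancellation is benign."""
    total = 0.0
    term_scale = 0.0  # largest |term| seen, tracks cancellation
    for k in range(_MAX_TERMS):
        g = _gammafn(alpha * k + beta)
        if not np.isfinite(g):
            break  # Γ overflow: remaining terms are zero in float64
        term = z**k / g
        if not np.isfinite(term):
            raise EvaluationError(
                "Taylor term overflow", z=z, alpha=alpha, beta=beta
            )
        total += term
        term_scale = max(term_scale, abs(term))
        # 0.01 margin: the geometric tail of the series past the stopping
        # term must stay below tol, not just the term itself
        if abs(term) <= 0.01 * tol * max(abs(total), 1e-300) and k > alpha + beta:
            return total
    return total


def _taylor_cancellation_safe(z: float, alpha: float, tol: float) -> bool:
    """Largest series term is ~exp(|z|^{1/α}); accept only if the float64
    round-off it implies stays below tol relative to the ~1/|z| result."""
    if z >= 0:
        return True
    peak = abs(z) ** (1.0 / alpha)
    # eps * e^peak <= tol * |E| with |E| >= ~ 1/(3|z|) on the negative axis
    return peak <= math.log(tol / (3 * abs(z) * 2.3e-16) + 1.0)


def _spectral_negative(x: float, alpha: float) -> float:
    """E_α(−x) for x > 0, 0 < α < 1, via the complete-monotonicity integral.

    E_α(−x) = sin(απ)/(πα x) ∫_0^∞ e^{−v^{1/α}} /
              [(v/x)² + 2(v/x)cos(απ) + 1] dv
    """
    c = math.cos(alpha * math.pi)
    pref = math.sin(alpha * math.pi) / (math.pi * alpha * x)
    inv_alpha = 1.0 / alpha

    def integrand(v: float) -> float:
        w = v / x
        return math.exp(-(v**inv_alpha)) / (w * w + 2 * w * c + 1.0)

    v1, _ = quad(integrand, 0.0, 1.0, epsabs=1e-16, epsrel=1e-13, limit=300)
    v2, _ = quad(integrand, 1.0, np.inf, epsabs=1e-16, epsrel=1e-13, limit=300)
    return pref * (v1 + v2)


def _asymptotic_negative(
    z: float, alpha: float, beta: float, n_terms: int, tol: float
) -> tuple[float, bool]:
    """Algebraic expansion −Σ_{k≥1} z^{−k}/Γ(β−αk) for large negative z.

    Returns ``(value, ok)`` where ``ok`` reports whether the smallest
    retained term certifies the requested tolerance.
    """
    total = 0.0
    smallest = np.inf
    for k in range(1, n_terms + 1):
        g = _gammafn(beta - alpha * k)
        term = 0.0 if not np.isfinite(g) else z ** (-k) / g
        total -= term
        if term != 0.0:
            smallest = min(smallest, abs(term))
    ok = bool(smallest <= tol * max(abs(total), 1e-300)) and total != 0.0
    return total, ok


def _mpmath_series(z: float, alpha: float, beta: float) -> float:
    """Arbitrary-precision Taylor summation; the slow, always-correct path."""
    import mpmath as mp

    peak = abs(z) ** (1.0 / alpha) if z != 0 else 0.0
    dps = int(25 + 0.45 * peak)
    if dps > 4000:
        raise EvaluationError(
            "argument too large for the arbitrary-precision fallback",
            z=z, alpha=alpha, beta=beta,
        )
    # the largest series term sits near k ~ |z|^{1/α}/α; only terms past it
    # may trigger the stopping test
    k_peak = peak / alpha + 10
    with mp.workdps(dps):
        zz, aa, bb = mp.mpf(z), mp.mpf(alpha), mp.mpf(beta)
        total = mp.mpf(0)
        term_floor = mp.mpf(10) ** (-dps)
        k = 0
        while k < 40 * _MAX_TERMS:
            term = zz**k / mp.gamma(aa * k + bb)
            total += term
            if abs(term) < term_floor and k > k_peak:
                return float(total)
            k += 1
    raise EvaluationError(
        "arbitrary-precision series did not converge", z=z, alpha=alpha, beta=beta
    )


def mittag_leffler(
    z: float, params: MLParams | None = None, *, alpha: float | None = None,
    beta: float = 1.0, tol: float = 1e-10,
) -> float:
    """Evaluate the two-parameter Mittag-Leffler function E_{α,β}(z).

    Parameters may be supplied either as an :class:`MLParams` instance or as
    the keyword arguments ``alpha``/``beta``/``tol``.

    Parameters
    ----------
    z : float
        Real argument (complex arguments are outside the supported contract).
    params : MLParams, optional
        Evaluation parameters; overrides the keyword arguments.

    Returns
    -------
    float
        E_{α,β}(z) to within the requested relative tolerance.

    Raises
    ------
    DomainError
        If ``alpha <= 0`` or ``z`` is not finite.
    EvaluationError
        If no evaluation strategy converges within its iteration budget.
    """
    if params is None:
        if alpha is None:
            raise DomainError("either params or alpha must be given")
        params = MLParams(alpha=alpha, beta=beta, tol=tol)
    z = float(z)
    if not np.isfinite(z):
        raise DomainError(f"z must be finite, got {z}")
    a, b, tl = params.alpha, params.beta, params.tol

    if z == 0.0:
        return 1.0 / _gammafn(b)
    if a == 1.0 and b == 1.0:
        return math.exp(z)

    if abs(z) <= params.z_switch and _taylor_cancellation_safe(z, a, tl):
        return _taylor_float(z, a, b, tl)
    if z > 0:
        # positive terms, no cancellation: float series up to overflow
        try:
            return _taylor_float(z, a, b, tl)
        except EvaluationError:
            return _mpmath_series(z, a, b)

    # z < 0 beyond the safe Taylor region
    if 0 < a < 1 and b == 1.0:
        return _spectral_negative(-z, a)
    value, ok = _asymptotic_negative(z, a, b, params.n_asymptotic, tl)
    if ok:
        return value
    return _mpmath_series(z, a, b)


def ml_relaxation(t: float, lam: float, gamma: float) -> float:
    """Mittag-Leffler relaxation E_γ(−λ t^γ) of linear fractional kinetics.

    This is the solution of ``D^γ x = −λ x`` (Caputo) normalized to
    ``x(0) = 1``: monotonically non-increasing from 1, exponential for
    ``γ = 1``, heavy-tailed (``∝ t^{−γ}``) for ``0 < γ < 1``.

    Parameters
    ----------
    t : float
        Time, ``t >= 0``.
    lam : float
        Rate scale (units time^{−γ}), ``lam > 0``.
    gamma : float
        Anomalous exponent, ``0 < gamma <= 1``.
    """
    if not (0 < gamma <= 1):
        raise DomainError(f"gamma must lie in (0, 1], got {gamma}")
    if lam <= 0:
        raise DomainError(f"lam must be positive, got {lam}")
    if t < 0:
        raise DomainError(f"t must be non-negative, got {t}")
    if t == 0:
        return 1.0
    if gamma == 1.0:
        return math.exp(-lam * t)
    return mittag_leffler(-lam * t**gamma, MLParams(alpha=gamma))
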