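# Methods

This note records the models, numerical schemes, parameter choices and
known limitations behind `fracgate`.

## Model

A non-Markovian kinetic process with a long-tailed waiting-time
distribution carries the power-law memory kernel
`Π(t) = (1/Γ(γ)) (t/τ)^{γ−1}`, `0 < γ < 1`. At the trajectory level the
state variable obeys the time-fractional kinetic equation
`D^γ x = −Γβ ∂F/∂x`; at the distribution level the probability field on a
state lattice obeys `∂P/∂t = D^{1−γ}[W P]` with the Langer/Glauber
free-energy kernel `W(x,x') = exp[−(x−x')²/Δ] exp[−(β/2)(F(x)−F(x'))]`.
Both views share the same stationary physics: the kernel satisfies
detailed balance exactly, so the Boltzmann distribution `∝ exp(−βF)` is
the γ-independent target; γ only controls the relaxation law
(Mittag-Leffler instead of exponential).

**Operator convention.** The fractional operator is written in the
Riemann-Liouville form in the governing equations, but a Riemann-Liouville
initial-value problem with `x(0) ≠ 0` requires fractional-integral initial
data, which has no physical reading for an open probability. All
initial-value solvers therefore integrate in the **Caputo** sense — the
Riemann-Liouville operator applied to the increment `x(t) − x(0)` — which
coincides with Riemann-Liouville whenever `x(0) = 0` and is the standard
well-posed convention for physical initial conditions. `fracops` exposes
both operators so the Riemann-Liouville residual of a computed trajectory
can be verified directly.

**Units.** Time is dimensionless (`τ = 1` convention); the composite rate
`Γβκ` (or `Γ/n` for the channel) is the single rate constant a user
effectively controls. The fractional equation written without an explicit
`τ^γ` factor is dimensionally consistent only under this convention, which
is adopted throughout. The symbol Γ is used in the field both for the
Gamma function and for the kinetic coefficient; in code they are
`scipy.special.gamma`/`math.gamma` and `Gamma_coef`, never conflated.

**Channel n-scaling.** Applying the kinetic equation directly to the open
*fraction* `x = P₀` with the ensemble free energy would give a drift
`∝ Γ·n`; the gating equation instead carries `Γ/n`. The two readings are
reconciled by taking the kinetic variable to be the open-channel *count*
`n₂ = n·P₀`, whence `D^γ P₀ = (1/n) D^γ n₂` yields exactly the `Γ/n` form.
The package implements the `Γ/n` drift as printed and verifies (test
`test_is_free_energy_gradient_flow`) the equivalent identity
`drift(p) = −(Γ/n²)·β·∂F/∂x|_{x=p}`, which pins the scaling down.

## Mittag-Leffler evaluation

`E_{α,β}(z) = Σ z^k/Γ(αk+β)` is evaluated for real arguments by a region
switch:

* `α = 1, β = 1`: `exp(z)` (exact identity).
* `|z| ≤ z_switch` (default 5) **and** cancellation provably below
  tolerance (the largest series term is `~exp(|z|^{1/α})`; float64 is used
  only while `eps·exp(|z|^{1/α})` stays below `tol` relative to the
  `~1/|z|`-sized result): float64 Taylor series, stopping when a term
  falls below `0.01·tol` relative.
* `z > 0` beyond that: float64 Taylor (all terms positive, no
  cancellation), with an arbitrary-precision fallback on overflow.
* `z < 0`, `0 < α < 1`, `β = 1`: the complete-monotonicity spectral
  integral
  `E_α(−x) = sin(απ)/(παx) ∫₀^∞ e^{−v^{1/α}} / [(v/x)² + 2(v/x)cos(απ) + 1] dv`,
  evaluated with adaptive quadrature (`epsrel 1e-13`), accurate uniformly
  in `|z|` — this is the production path for relaxation laws.
* `z < 0` otherwise: the algebraic expansion
  `−Σ_{k=1..K} z^{−k}/Γ(β−αk)` (K = 10 by default), accepted only when its
  smallest term certifies the tolerance; else mpmath summation at
  `25 + 0.45·|z|^{1/α}` digits (the digit count matches the cancellation;
  the stopping index must pass the series peak at `k ≈ |z|^{1/α}/α`).

Default `tol = 1e-10`: solver oracles need 1e-6 and the headroom is cheap.
Only real arguments are supported; the kinetic equation needs real
negative ones. Both the one- and two-parameter functions are provided,
with `β = 1` the default since the relaxation law uses only `E_γ`.

## Fractional operators

Grünwald-Letnikov convolution on uniform grids with
`w_0 = 1, w_k = w_{k−1}(1 − (γ+1)/k)` (computed by vectorized cumulative
product — stable, and exactly the signed binomial coefficients). Full
memory is kept (no short-memory truncation): desk-scale grids make the
O(n²) cost irrelevant, and truncation would corrupt the heavy tail that is
the point of the model. Grids for fractional operators always start at
`t0 = 0`, the lower terminal of the memory integral. The scheme is first
order; the classical power-rule benchmarks converge at that rate once the
error is measured away from the `t^{μ−γ}` short-time layer at the origin
(the layer itself shrinks only like `dt^{1−γ}` in the sup norm, which is a
property of the exact solution's weak singularity, not of the scheme).

## Trajectory solvers

* **`abm`** (default): fractional Adams-Bashforth-Moulton
  predictor-corrector with one corrector pass (configurable). Reduces
  exactly to Heun's method at γ = 1. Observed order on smooth windows is
  `1 + γ`; the scheme is explicit and its stability region shrinks as
  `dt^γ·rate` grows.
* **`implicit_gl`**: backward Grünwald-Letnikov stepping, one scalar
  bracketed root solve (Brent) per step. Strictly first order,
  unconditionally stable in practice; the right choice for coarse grids on
  long horizons and stiff landscapes. The first-order convergence tests
  use this scheme.

States that overshoot the landscape domain are clamped to the interior at
`1e-12` from the boundary and counted (`Trajectory.meta["clamp_count"]`),
with a warning: logarithmic free energies (the channel's entropy term)
diverge at the boundary, and a single overshoot would otherwise poison the
entire convolution history. `stationary_state` brackets a sign change of
`F'` by symmetric expansion around the guess and bisects (Brent, xtol
1e-15); multiple minima need a user-supplied guess — no global search.

## Lattice propagation

`W[i,j]` is the j→i rate (column-generator layout) so propagation is
`W @ P`. The kernel defines only the jump rates; conservation fixes the
diagonal as the negated column sum. The written kernel form is read as
`exp{−(β/2)[F(x')−F(x)]}`, the Langer/Glauber choice that yields exact
detailed balance. The default neighbor cutoff keeps every lag with
Gaussian factor `exp(−(k·dx)²/Δ) ≥ 1e-12`; boundary columns simply have
fewer neighbors (reflection by truncation), which preserves exact
conservation and detailed balance on the finite lattice.

Time stepping discretizes `D^{1−γ}` by Grünwald-Letnikov on the history of
`W·P`. The explicit scheme warns when `dt^γ·max|W_jj| > 0.5` and aborts
with a stable-dt estimate if any `|P| > 2`; at γ = 1 it reduces to forward
Euler and skips the (identically zero) history. The implicit variant moves
the `k = 0` term to the new time level and reuses one LU factorization;
mass is then conserved identically because `1ᵀW = 0`. Long-horizon
stationarity runs use the implicit scheme: the Mittag-Leffler tail decays
only as `(λ t^γ Γ(1−γ))⁻¹`, so reaching total-variation 1e-3 at γ = 0.6
takes horizons of order 4·10⁴ — the γ = 0.6 acceptance run uses `dt = 1`
for 4·10⁴ steps on a 21-point lattice (≈1 minute), with the dt-halving
check confirming the discretization contributes ≲3·10⁻⁴ of the measured
distance. `stationary_distribution` recovers the null vector of `W` from
the SVD independently of the Boltzmann construction, so the two routes
cross-check each other in tests.

## Problem sizes in tests and the acceptance script

Chosen as the smallest sizes at which each property is cleanly exhibited:
dt = 1e-3 grids over t ∈ [0, 10] (10⁴ steps) for solver-vs-oracle
comparisons; a 21-point lattice on [−2, 2] with Δ = 1 for stationarity; a
151-point lattice with unit spacing, dt = 0.02, t ∈ [0.5, 50] (two decades)
for the variance-growth exponent; 10⁴-step ABM runs for the long-horizon
channel. The frozen Mittag-Leffler reference table in `tests/test_mlfunc.py`
was generated by mpmath summation at up to ~1100 digits (the α = 0.3,
|z| = 10 entries) and is stored rather than recomputed because that
summation takes minutes.

## Synthetic parameter sweeps

`fixture_sweep` draws γ ∈ [0.3, 1.0] (the physically reported anomalous
range), composite rates log-uniform over [0.1, 10], voltage biases
βze₀(V−V₀) ∈ [−5, 5] (spanning the sigmoid from ~0.007 to ~0.993) and
initial fractions in [0.05, 0.95]. The sweeps emulate parameter diversity,
not data: there is no measurement noise, no channel-count fluctuation and
no stochastic gating (single-channel trajectories are out of scope), so
passing tests certify the deterministic mean-field kinetics only.

## Known limitations

* One-dimensional state only; the multi-dimensional index survives solely
  in `gamma_from_delta` (`Γ = (2πΔ)^{m/2}Δ`).
* Real Mittag-Leffler arguments only; no matrix arguments, no derivatives
  with respect to order.
* Full-memory convolutions make cost quadratic in step count; horizons
  beyond ~10⁵ steps need the implicit schemes and patience.
* Constant-voltage theory; the step-voltage helper is a convenience, and
  time-dependent landscapes are unsupported.
* No fitting of γ to experimental recordings and no stochastic (Gillespie)
  single-channel simulation.
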