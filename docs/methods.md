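# Methods

This note records the models implemented in `crnflow`, the numerical choices
behind them, and what the test suite does and does not establish.

## Modeling hierarchy and assumptions

All models describe a well-stirred reactor of volume `V` containing `I`
species undergoing `R` reversible mass-action reactions with constant rate
coefficients.  Space, temperature and pressure dependence are out of scope.
The central assumption throughout is **detailed balance**: a positive
equilibrium `c*` at which every forward/backward pair balances individually,
`κ*^r = k_fw^r c*^α = k_bw^r c*^β`.  Under this assumption each level of
the hierarchy is a gradient flow of a relative entropy:

| level | state | entropy | mobility |
|---|---|---|---|
| RRE | `c ∈ [0,∞)^I` | `E(c) = Σ c*ᵢ λ_B(cᵢ/c*ᵢ)` | `K(c)` (logarithmic-mean) |
| CME | `u ∈ P(N₀^I)` | `E_V(u) = (1/V) Σ λ_B(u/w) w` | quadratic `K_V(u)` or cosh `Ψ*` |
| Liouville | `ϱ ∈ P(C)` | `∫ E dϱ` | transport `−div(ϱ K ∇·)` |
| FPE | density `ρ` | `(1/V)∫ ρ log(ρ/W_V)` | same `K`, plus `1/V` diffusion |

The identities connecting the levels — `K(c)DE(c) = R(c)`, the cosh force
identity, lattice detailed balance of the Poisson product, the exactness of
the Poisson reduction, and the energy-dissipation balance
`dE/dt = −2Ψ*(u, −DE)` — are algebraic consequences of detailed balance and
are tested as such (to 1e-10 … 1e-12 relative), not merely to solver
tolerance.

## Stoichiometric structure

Kernel bases of the Wegscheider matrix `W` (rows `γ^r = α^r − β^r`) and of
`Wᵀ` are computed in exact rational arithmetic (sympy null spaces, scaled to
primitive integer vectors).  Conservation laws `Q γ^r = 0` therefore hold
exactly and the count `n_W = R − I + m_W` is an invariant of the
construction, not a floating-point rank decision.  The Wegscheider residual
is the maximum of `|y · log(k_bw/k_fw)|` over the primitive basis vectors;
the detailed-balance tolerance on this log-space residual defaults to
`tol_db = 1e-9`.  When the equilibrium manifold is positive-dimensional
(`m_W > 0`) the solver returns the minimum-norm log-space representative
(numpy least squares), documented as one point of the manifold
`{c* ⊙ exp(Qᵀ s)}`.

Zero rate constants are allowed in a `ReactionNetwork` (irreversible
reactions appear in the examples contrasting microscopic and macroscopic
balance) but are rejected by every detailed-balance routine, since the
log-ratio is undefined there.

## Lattice truncation

The paper-level CME lives on the infinite lattice; the implementation
truncates to a box chosen per species as the smallest bound with
Poisson(`V cᵢ*`) tail mass below `trunc_tol` (default 1e-12; initial
conditions can widen the box).  Out-of-box transitions are removed
**pairwise** — a deleted jump takes its matching loss term with it.  This is
the finite-state-projection family of truncations, chosen so that

* generator column sums vanish identically (diagonal assembled as the exact
  negative of the off-diagonal column sums), hence no probability leak;
* the *conditioned* Poisson product is exactly stationary (detailed-balance
  pairs cancel within the box);
* all dissipation identities restrict exactly to in-box pairs, so the
  energy-dissipation balance holds on the truncated system too.

The prices are a conditioned rather than a true marginal equilibrium and a
boundary layer in which dissipation diagnostics are slightly distorted;
empirically, with tails at 1e-12 both effects sit below the 1e-6 tolerances
used in the checks.  Probability floors: log ratios clamp `u` at 1e-300;
dissipation sums skip pairs whose probabilities fall below 1e-12 of the
maximum, staying clear of the `G(·,0) = ∞` boundary.

Linear CME systems are propagated by the action of the matrix exponential
(Krylov/Taylor `expm_multiply`), which is exact up to rounding; an implicit
multistep (BDF, rtol 1e-8) path exists for comparison.

## Numerical evaluation of the special functions

* The logarithmic mean `Λ(a,b) = (a−b)/(log a − log b)` is evaluated through
  the log ratio with a symmetric series `Λ ≈ m(1 − s²/24)`, `m = (a+b)/2`,
  when `|log(a/b)| < 1e-6`; `Λ(a,a) = a`, `Λ(a,0) = 0` by continuity.  Its
  second-argument derivative uses the closed form with a series fallback
  `1/2 − (b−a)/(6m)` near the diagonal.
* The correction coefficient `Υ₁ = Λ(A+B−2Λ)/(2(A−B))` has a removable
  singularity at `A = B`; for `|A−B| < 1e-7 (A+B)` the limit `(A−B)/12` is
  used.
* The Stirling parameters `k_n` (in `n! = √(2πk_n)(n/e)^n`) and the
  correction `γ_n = (k_n − n − 1/6)(124/5 + 72n)` are computed at 40-digit
  precision (mpmath, shipped with sympy): the subtraction `k_n − n − 1/6`
  cancels ~`2 log₁₀ n` digits, which double precision cannot afford near
  `n = 10³`.  Direct evaluation gives `γ₁ = 0.9039…` and
  `γ_n ∈ [0.9039, 1)` for `n ≤ 1000`, confirming the stated `[0.9, 1]`
  range with the minimum at `n = 1`.

## Continuum solvers

The 1-D Fokker–Planck variants share a finite-volume frame on `[0, c_max]`
(`c_max` chosen so the equilibrium tail is below 1e-12, uniform cells,
no-flux ends, implicit Euler with one sparse LU reused across steps,
default `Δt = 0.01`):

* gradient variants (`simple`, and `simple_av` with the Stirling-refined
  equilibrium) use the flux `F = (K_f W_f / V) Δ(ρ/W)/Δc` with `W` at faces
  by geometric mean and the mobility at face midpoints; the discrete
  equilibrium `ρ = W` is then stationary to machine precision *by
  construction*, and the implicit-Euler map is a (sub)stochastic matrix, so
  relative entropy decays unconditionally;
* the chemical-Langevin variant is rewritten as drift-diffusion
  `F = D ρ' + (R + D')ρ`, `D = K_cle/V`, and discretised with the
  exponential-fitted Scharfetter–Gummel face flux.  This keeps local
  exponential equilibria exact and converges at second order; plain
  upwinding was found to be an order of magnitude too diffusive for the
  equilibrium-comparison checks at practical grids.  No entropy-decay claim
  is made for this variant: it is not a gradient flow, which is precisely
  the point of including it.

The corrected quasilinear gradient-flow coefficients
(`Υ₀…Υ₃`, `â₀^V…â₃^V`, `b̂₀`, `b̂₁`) are evaluated per reaction with the
coercivity pair defaulting to `θ₁ = 1/4`, `θ₂ = 3/4` (the theory only
constrains `0 < θ₁ < θ₂ < 1`; any larger `Υ₂`, `Υ₃` also work), and
parabolicity `â₁ + 2â₂q + 3â₃q² ≥ 0` is checked by sampling.  Time
integration of the corrected PDE itself is limited to the same 1-D
machinery.

Liouville transport of Dirac mixtures moves each atom along the stiff RRE
integrator (LSODA, rtol 1e-8/atol 1e-10 defaults, rtol 1e-10 for energy
audits) with weights frozen; the energy identity
`E(ϱ(0)) − E(ϱ(T)) = 2∫ Ψ*_Lio dt` is checked by trapezoidal quadrature and
is therefore quadrature-limited (~1e-4 at 200 time points).

## Hybrid couplings

* **CME ↔ rate equation** (one stochastic species exchanging with one
  macroscopic species via `X₁ ⇌ βX₂`): birth-death chain with reflecting
  truncation at `M_max` (same tail rule as the CME), coupled to
  `ċ₂ = β(mean/V − c₂^β)`.  The linear conservation law `β·mean/V + c₂` is
  exact up to the truncated tail and solver tolerance (LSODA rtol 1e-10).
* **Fokker–Planck ↔ rate equation** (mean-field): the stochastic density
  uses the Scharfetter–Gummel flux with `D = K_ss/V`, `v = R_s`; the
  macroscopic ODE integrates the *same* face fluxes (through the implied
  face density), so any linear conservation law of the network is inherited
  exactly by the discretisation.  The simplified hybrid energy (with the
  macroscopic relative entropy in place of the exact reduced marginal term)
  is the driving functional; the exact reduced term and the moment ratio
  `A(v) ≥ 1` are provided as inequality diagnostics.
* **Mixed CME/FP** (single species, `{0..N−1} ∪ [N/V, c_max]`): the
  generator acts on discrete probabilities plus continuous cell *masses*
  and has three blocks — the CME stencil, the gradient-form FV flux with
  the Stirling-refined equilibrium as weight, and an interface exchange
  with rate `V â` out of `u_{N−1}` and back-rate proportional to
  `U/W` at the first cell.  The exact printed coupling conditions involve
  point values at `c = N/V`; the implementation realises them with
  first-cell averages, which makes the hybrid equilibrium *exactly*
  stationary and total measure exactly conserved, at the cost of an `O(Δc)`
  displacement of the interface condition.  The large-V Robin form of the
  interface is exposed as a diagnostic (`robin_interface_mismatch`), whose
  gap decays as `V` grows.  The free interface parameter defaults to
  `â = a`, the natural choice.

## The fixture generator

`random_db_network` draws stoichiometric vectors with entries `≤ max_order`
(default 2, rejecting `α = β`), an equilibrium `c* ∈ [0.3, 2]^I` and fluxes
`κ* ∈ [0.5, 2]`, and *defines* the rate constants by inverting the
detailed-balance relations.  This emulates the regime the theory addresses —
moderate-order reversible networks near order-one concentrations — and makes
detailed balance true by construction, so Wegscheider residuals at rounding
level are a consistency check of the analysis pipeline, not a discovery.
What passing tests on these fixtures do **not** show: behaviour of networks
violating detailed balance (only the specific printed counterexamples are
exercised), stiff rate-constant ratios spanning many decades, high-order
reactions, or boundary-touching equilibria.

## Problem sizes

The default verification sizes are: volumes `V = 10–20` for lattice
computations (boxes of ~10²–10⁴ states), 400-cell grids for 1-D continuum
runs, 100-sample batches for identity checks, and `n ≤ 1000` for the
Stirling range.  These sizes keep every identity at or below its stated
tolerance while the full suite runs in well under a minute; the convergence
diagnostics (entropy and dissipation as `V → ∞`, Robin interface) report
trends over doubling sequences rather than asserting unknown constants.

## Known limitations

* Continuum solvers are one-dimensional in concentration space;
  multi-species densities are supported only through product/hybrid
  constructions.
* The truncated CME equilibrium is the conditioned Poisson product, which
  differs from the true stationary distribution of the truncated chain's
  infinite counterpart by the (controlled) tail mass.
* `solve_detailed_balance` returns one representative of a non-unique
  equilibrium; quantities that depend on the choice (entropies relative to
  `c*`) are always reported together with it.
* The general-φ (non-Boltzmann) gradient structures are deliberately
  restricted to unimolecular networks, where their mobilities are provably
  nonnegative.
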