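"""Chemical master equation on a truncated particle-number lattice.

The CME is the Kolmogorov forward equation ``du/dt = B_V u`` of the Markov
jump process on particle-number vectors ``n``, with volume-scaled
combinatorial jump intensities

.. math:: \\mathbb{B}_V^{\\alpha}(n) = \\frac{V (n+\\alpha)!}{V^{|\\alpha|}\\, n!}
          \\quad (0 \\text{ outside } \\mathbb{N}_0^I).

For a detailed-balance network the product-Poisson distribution
``w^V_n \\propto (V c_*)^n / n!`` is a reversible equilibrium:
``k_fw B_V^alpha(n) w_{n+alpha} = k_bw B_V^beta(n) w_{n+beta}
= kappa*^r V w_n``.

Truncation to a finite box removes out-of-box transitions *pairwise* (the
gain together with its matching loss term), so the generator keeps exactly
zero column sums and the conditioned Poisson product remains exactly
stationary.  All gradient-structure identities (quadratic and cosh
dissipation, energy-dissipation balance) then hold exactly on the truncated
state space as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply
from scipy.special import gammaln
from scipy.stats import poisson

from .network import DetailedBalanceData, ReactionNetwork
from .rre import boltzmann, logmean

__all__ = [
    "TruncatedLattice", "LatticeDistribution",
    "rate_coefficient", "build_generator",
    "poisson_equilibrium", "poisson_distribution",
    "verify_detailed_balance", "stationarity_residual", "poisson_weights_fn",
    "cme_entropy", "cme_entropy_gradient", "cme_dual_dissipation",
    "cme_dissipation_force", "energy_dissipation_residual",
    "integrate_cme", "lattice_moments",
]

#: probability floor used inside log ratios
U_FLOOR = 1e-300


@dataclass(frozen=True)
class TruncatedLattice:
    """Finite box ``prod_i {0..n_max_i}`` of particle-number states at volume V."""

    n_max: np.ndarray
    V: float

    def __post_init__(self):
        object.__setattr__(self, "n_max", np.asarray(self.n_max, dtype=int))
        if np.any(self.n_max < 0) or self.V <= 0:
            raise ValueError("need n_max >= 0 and V > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.n_max + 1)

    @property
    def n_species(self) -> int:
        return self.n_max.size

    @property
    def n_states(self) -> int:
        return int(np.prod(self.n_max + 1))

    @property
    def states(self) -> np.ndarray:
        """All box states as an ``(n_states, I)`` integer array (C order)."""
        grids = np.indices(self.shape).reshape(self.n_species, -1).T
        return grids

    def flat_index(self, n: np.ndarray) -> np.ndarray:
        """Flat indices of states ``n`` (shape ``(..., I)``)."""
        n = np.asarray(n, dtype=int)
        return np.ravel_multi_index(tuple(np.moveaxis(n, -1, 0)), self.shape)

    @classmethod
    def from_means(cls, means, V: float, tail_tol: float = 1e-12,
                   n_min: int = 8) -> "TruncatedLattice":
        """Box sized so each Poisson(``V * means_i``) tail mass is ``<= tail_tol``."""
        means = np.atleast_1d(np.asarray(means, dtype=float))
        n_max = np.maximum(poisson.isf(tail_tol, means * V).astype(int) + 2, n_min)
        return cls(n_max, V)

    @classmethod
    def from_detailed_balance(cls, db: DetailedBalanceData, V: float,
                              tail_tol: float = 1e-12,
                              extra_means=None) -> "TruncatedLattice":
        """Default box from the equilibrium ``c*`` (optionally also covering
        other concentration vectors, e.g. an initial condition)."""
        means = np.atleast_1d(db.c_star.copy())
        if extra_means is not None:
            means = np.maximum(means, np.atleast_1d(np.asarray(extra_means, float)))
        return cls.from_means(means, V, tail_tol)


@dataclass
class LatticeDistribution:
    """Probability vector over the states of a :class:`TruncatedLattice`."""

    u: np.ndarray
    lattice: TruncatedLattice

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (self.lattice.n_states,):
            raise ValueError("u length does not match lattice")
        if np.any(self.u < 0):
            raise ValueError("probabilities must be nonnegative")

    def normalized(self) -> "LatticeDistribution":
        return LatticeDistribution(self.u / self.u.sum(), self.lattice)


# ---------------------------------------------------------------------------
# rates and generator


def rate_coefficient(alpha, n, V: float):
    """Combinatorial jump intensity ``B_V^alpha(n)``.

    Computed as ``V^(1-|alpha|) * prod_i (n_i+1)...(n_i+alpha_i)`` via
    explicit products, so there is no factorial overflow.  Vectorised over a
    ``(..., I)`` array of states; 0 for states with a negative entry.
    """
    if V <= 0:
        raise ValueError("V must be positive")
    alpha = np.atleast_1d(np.asarray(alpha, dtype=int))
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    n = np.atleast_2d(n)
    out = np.full(n.shape[0], V ** (1 - int(alpha.sum())), dtype=float)
    for i, a_i in enumerate(alpha):
        for j in range(1, a_i + 1):
            out = out * (n[:, i] + j)
    out[np.any(n < 0, axis=1)] = 0.0
    return float(out[0]) if single else out


def _reaction_pairs(net: ReactionNetwork, lattice: TruncatedLattice, r: int):
    """In-box transition pairs of reaction ``r``.

    Returns ``(base, idx_a, idx_b)``: base states ``n >= 0`` such that both
    endpoints ``n+alpha^r`` and ``n+beta^r`` lie in the box, and the flat
    indices of those endpoints.
    """
    states = lattice.states
    a, b = net.alpha[r], net.beta[r]
    base = states - a[None, :]
    target = base + b[None, :]
    ok = np.all(base >= 0, axis=1) & np.all(target <= lattice.n_max[None, :], axis=1)
    base = base[ok]
    idx_a = lattice.flat_index(base + a[None, :])
    idx_b = lattice.flat_index(base + b[None, :])
    return base, idx_a, idx_b


def build_generator(net: ReactionNetwork, lattice: TruncatedLattice) -> sp.csc_matrix:
    """Assemble the truncated forward generator ``B_V`` (sparse, columns sum to 0).

    A forward jump ``n+alpha -> n+beta`` at rate ``k_fw B_V^alpha(n)`` and its
    backward partner are included only when *both* endpoints lie in the box;
    a deleted transition takes its loss term with it, which keeps every
    column sum exactly zero and preserves the conditioned product-Poisson
    equilibrium exactly.
    """
    V = lattice.V
    N = lattice.n_states
    rows, cols, vals = [], [], []
    for r in range(net.n_reactions):
        base, idx_a, idx_b = _reaction_pairs(net, lattice, r)
        fwd = net.k_fw[r] * rate_coefficient(net.alpha[r], base, V)
        bwd = net.k_bw[r] * rate_coefficient(net.beta[r], base, V)
        rows += [idx_b, idx_a]
        cols += [idx_a, idx_b]
        vals += [fwd, bwd]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    off = sp.csc_matrix((vals, (rows, cols)), shape=(N, N))
    # diagonal = exact negative of the off-diagonal column sums (no leak)
    colsum = np.asarray(off.sum(axis=0)).ravel()
    return (off - sp.diags(colsum, format="csc")).tocsc()


# ---------------------------------------------------------------------------
# equilibrium and detailed balance


def _log_poisson_weights(lattice: TruncatedLattice, means: np.ndarray) -> np.ndarray:
    """Un-normalised log Poisson-product weights at every box state."""
    states = lattice.states
    m = np.asarray(means, dtype=float) * lattice.V
    return np.sum(states * np.log(m)[None, :] - gammaln(states + 1.0)
                  - m[None, :], axis=1)


def poisson_distribution(lattice: TruncatedLattice, means) -> LatticeDistribution:
    """Product-Poisson distribution with concentration means, conditioned on the box."""
    logw = _log_poisson_weights(lattice, np.atleast_1d(np.asarray(means, float)))
    logw -= logw.max()
    w = np.exp(logw)
    return LatticeDistribution(w / w.sum(), lattice)


def poisson_equilibrium(db: DetailedBalanceData, lattice: TruncatedLattice
                        ) -> LatticeDistribution:
    """Equilibrium ``w^V_n \\propto (V c_*)^n / n!`` conditioned on the box."""
    return poisson_distribution(lattice, db.c_star)


def verify_detailed_balance(net: ReactionNetwork, db: DetailedBalanceData,
                            lattice: TruncatedLattice):
    """Check the lattice detailed-balance identity.

    Returns ``(max_violation, residual_field)`` where the violation at an
    in-box pair ``(n, r)`` is ``|k_fw B^alpha(n) w_{n+alpha} - kappa* V w_n| /
    (kappa* V w_n)`` and ``residual_field`` holds the per-state maximum.
    """
    w = poisson_equilibrium(db, lattice).u
    field = np.zeros(lattice.n_states)
    worst = 0.0
    for r in range(net.n_reactions):
        base, idx_a, idx_b = _reaction_pairs(net, lattice, r)
        if base.size == 0:
            continue
        lhs = net.k_fw[r] * rate_coefficient(net.alpha[r], base, lattice.V) * w[idx_a]
        # reference flux kappa* V w_n evaluated through w_{n+alpha} to stay in-box:
        # kappa* V w_n = k_bw B^beta(n) w_{n+beta}
        rhs = net.k_bw[r] * rate_coefficient(net.beta[r], base, lattice.V) * w[idx_b]
        rel = np.abs(lhs - rhs) / np.maximum(rhs, U_FLOOR)
        worst = max(worst, float(rel.max()))
        np.maximum.at(field, idx_a, rel)
    return worst, field


def poisson_weights_fn(means, V: float) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic Poisson-product ansatz ``n -> prod e^{-m_i} m_i^{n_i}/n_i!``.

    Defined for arbitrary integer vectors (0 outside the lattice); used to
    evaluate stationarity residuals without truncation artefacts.
    """
    m = np.atleast_1d(np.asarray(means, dtype=float)) * V

    def fn(n: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(np.asarray(n, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            logw = np.sum(n * np.log(m)[None, :] - gammaln(n + 1.0) - m[None, :],
                          axis=1)
        out = np.exp(logw)
        out[np.any(n < 0, axis=1)] = 0.0
        return out

    return fn


def stationarity_residual(net: ReactionNetwork, states, V: float,
                          weights_fn: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Exact CME right-hand side ``(B_V u)_n`` for an analytic ansatz ``u``.

    Evaluates the untruncated generator at the given states, pulling neighbour
    values from ``weights_fn`` (which must return 0 outside the lattice), so
    the result is free of truncation effects.
    """
    states = np.atleast_2d(np.asarray(states, dtype=int))
    res = np.zeros(states.shape[0])
    u_here = weights_fn(states)
    for r in range(net.n_reactions):
        a, b, g = net.alpha[r], net.beta[r], net.gamma[r]
        # forward reaction: gain at n from n+gamma, loss from n
        res += net.k_fw[r] * (rate_coefficient(a, states - b[None, :], V)
                              * weights_fn(states + g[None, :])
                              - rate_coefficient(a, states - a[None, :], V) * u_here)
        res += net.k_bw[r] * (rate_coefficient(b, states - a[None, :], V)
                              * weights_fn(states - g[None, :])
                              - rate_coefficient(b, states - b[None, :], V) * u_here)
    return res


# ---------------------------------------------------------------------------
# entropy and dissipation


def cme_entropy(u: np.ndarray, w: np.ndarray, V: float) -> float:
    """Volume-normalised relative entropy ``E_V(u) = (1/V) sum lambda_B(u/w) w``.

    States with ``u_n = 0`` contribute ``w_n / V`` exactly (``lambda_B(0)=1``).
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    pos = w > 0
    return float(np.sum(boltzmann(u[pos] / w[pos]) * w[pos]) / V)


def cme_entropy_gradient(u: np.ndarray, w: np.ndarray, V: float) -> np.ndarray:
    """Gradient ``DE_V(u) = (1/V) log(u_n/w_n)``, floor-clamped at ``u=0``."""
    u = np.maximum(np.asarray(u, dtype=float), U_FLOOR)
    return np.log(u / np.asarray(w, dtype=float)) / V


def cme_dual_dissipation(net: ReactionNetwork, lattice: TruncatedLattice,
                         u: np.ndarray, mu: np.ndarray,
                         kind: str = "quadratic",
                         w: np.ndarray | None = None,
                         active_tol: float = 1e-12) -> float:
    """Dual dissipation potential of the CME gradient structure.

    ``kind='quadratic'`` uses the flux form
    ``(V/2) sum_{n,r} Lambda(k_fw B^alpha(n) u_{n+alpha},
    k_bw B^beta(n) u_{n+beta}) (mu_{n+alpha}-mu_{n+beta})^2``
    which needs no detailed balance.  ``kind='cosh'`` needs the equilibrium
    ``w`` and evaluates
    ``(1/V) sum nu_hat sqrt(u_a u_b / (w_a w_b)) C*(V (mu_b - mu_a))`` with
    ``nu_hat = kappa* V w_n`` expressed through the in-box endpoint weights.

    Pairs whose probabilities fall below ``active_tol * max(u)`` are skipped
    to stay clear of the logarithmic singularity at the boundary of the
    probability simplex.
    """
    V = lattice.V
    u = np.asarray(u, dtype=float)
    mu = np.asarray(mu, dtype=float)
    total = 0.0
    thresh = active_tol * max(u.max(), U_FLOOR)
    for r in range(net.n_reactions):
        base, idx_a, idx_b = _reaction_pairs(net, lattice, r)
        if base.size == 0:
            continue
        dmu = mu[idx_a] - mu[idx_b]
        if kind == "quadratic":
            fa = net.k_fw[r] * rate_coefficient(net.alpha[r], base, V) * u[idx_a]
            fb = net.k_bw[r] * rate_coefficient(net.beta[r], base, V) * u[idx_b]
            act = (u[idx_a] >= thresh) & (u[idx_b] >= thresh)
            total += 0.5 * V * np.sum(logmean(fa[act], fb[act]) * dmu[act] ** 2)
        elif kind == "cosh":
            if w is None:
                raise ValueError("cosh dissipation requires the equilibrium w")
            nu = net.k_bw[r] * rate_coefficient(net.beta[r], base, V) * w[idx_b]
            act = (u[idx_a] >= thresh) & (u[idx_b] >= thresh)
            ratio = np.sqrt((u[idx_a][act] / w[idx_a][act])
                            * (u[idx_b][act] / w[idx_b][act]))
            total += np.sum(nu[act] * ratio
                            * (4.0 * np.cosh(0.5 * V * (-dmu[act])) - 4.0)) / V
        else:
            raise ValueError(f"unknown dissipation kind {kind!r}")
    return float(total)


def cme_dissipation_force(net: ReactionNetwork, lattice: TruncatedLattice,
                          u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Velocity ``d_mu Psi*_cosh,V(u, -DE_V(u))`` of the cosh structure.

    Coincides with ``B_V u`` wherever ``u > 0`` (the defining identity of the
    cosh gradient structure).
    """
    V = lattice.V
    u = np.maximum(np.asarray(u, dtype=float), U_FLOOR)
    out = np.zeros(lattice.n_states)
    for r in range(net.n_reactions):
        base, idx_a, idx_b = _reaction_pairs(net, lattice, r)
        if base.size == 0:
            continue
        nu = net.k_bw[r] * rate_coefficient(net.beta[r], base, V) * w[idx_b]
        ra = u[idx_a] / w[idx_a]
        rb = u[idx_b] / w[idx_b]
        flux = nu * (ra - rb)          # = sqrt(ra rb) C*'(log(ra/rb)) nu
        np.add.at(out, idx_b, flux)
        np.add.at(out, idx_a, -flux)
    return out


def energy_dissipation_residual(net: ReactionNetwork, lattice: TruncatedLattice,
                                B: sp.spmatrix, u: np.ndarray,
                                w: np.ndarray) -> float:
    """Residual of the energy-dissipation balance at state ``u``.

    Along solutions, ``d E_V/dt = <DE_V(u), B_V u> = -2 Psi*_V(u, -DE_V(u))``;
    the returned value is ``|dE/dt + 2 Psi*| / max(1, |dE/dt|)``.
    """
    mu = cme_entropy_gradient(u, w, lattice.V)
    dEdt = float(mu @ (B @ u))
    psi = cme_dual_dissipation(net, lattice, u, mu, "quadratic")
    return abs(dEdt + 2.0 * psi) / max(1.0, abs(dEdt))


# ---------------------------------------------------------------------------
# integration and moments


def integrate_cme(B: sp.spmatrix, u0: LatticeDistribution, t_grid,
                  method: str = "expm") -> list[LatticeDistribution]:
    """Propagate ``du/dt = B u`` on the time grid.

    ``method='expm'`` (default) uses Krylov/Taylor action of the matrix
    exponential (exact up to rounding for this linear system);
    ``method='bdf'`` uses an implicit multistep ODE solver (rtol 1e-8).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    lattice = u0.lattice
    if method == "expm":
        out = [u0]
        u = u0.u
        for dt in np.diff(t_grid):
            u = expm_multiply(B * dt, u)
            out.append(LatticeDistribution(np.maximum(u, 0.0), lattice))
        return out
    if method == "bdf":
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda _t, v: B @ v, (t_grid[0], t_grid[-1]), u0.u,
                        t_eval=t_grid, method="BDF", rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"CME integration failed: {sol.message}")
        return [LatticeDistribution(np.maximum(v, 0.0), lattice) for v in sol.y.T]
    raise ValueError(f"unknown method {method!r}")


def lattice_moments(dist: LatticeDistribution):
    """Rescaled mean ``e_hat = (1/V) E[n]`` and variance ``v_hat = Var[n]/V^2``."""
    states = dist.lattice.states.astype(float)
    V = dist.lattice.V
    mean = states.T @ dist.u
    second = (states ** 2).T @ dist.u
    e_hat = mean / V
    v_hat = (second - mean ** 2) / V ** 2
    return e_hat, v_hat
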