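"""Model reduction and hybrid discrete/continuous couplings.

Gradient structures can be coarse-grained through an embedding
``x = Phi(y)`` by restricting the energy, ``E_Y = E_X . Phi``, and reducing
the dual dissipation potential by constrained minimisation
(``Psi~*(eta) = inf { Psi*(xi) : A* xi = eta }`` for ``A = D Phi``).  Three
instances are implemented:

* the Poisson reduction of the CME onto concentration space, for which the
  reduction is *exact*: ``E_V(Phi_V(c)) = E(c)`` and the reduced quadratic
  potential is ``1/2 zeta . K(c) zeta`` (verified numerically);
* the finite-dimensional constrained-quadratic reduction itself
  (:func:`reduce_dual_potential`), cross-checkable against a brute-force
  Legendre transform;
* three hybrid dynamical systems: CME coupled to a macroscopic rate
  equation, a Fokker-Planck density coupled to a rate equation (mean-field),
  and a mixed discrete/continuous single-species model whose state lives on
  ``{0..N-1} u [N/V, inf)``.

All hybrid generators are assembled with exactly zero column sums (pairwise
transition bookkeeping), so the total measure is conserved to solver
precision and the constructed equilibria are exactly stationary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import quad, solve_ivp
from scipy.sparse.linalg import expm_multiply
from scipy.special import gammaln

from .cme import (TruncatedLattice, cme_dual_dissipation, cme_entropy,
                  poisson_distribution, poisson_equilibrium)
from .fpe import GridDensity1D, _what_refined
from .network import DetailedBalanceData
from .rre import boltzmann, logmean, onsager_matrix

__all__ = [
    "poisson_reduction_identities", "reduce_dual_potential",
    "HybridStateCMRR", "simulate_cme_rre", "cme_rre_stationarity_residual",
    "FPRRState", "simulate_fp_rre",
    "A_moment", "e_hat_V",
    "MixedState", "mixed_equilibrium", "build_mixed_generator",
    "simulate_mixed_cme_fp", "mixed_entropy", "robin_interface_mismatch",
]


# ---------------------------------------------------------------------------
# Poisson reduction of the CME (exactness diagnostics)


def poisson_reduction_identities(db: DetailedBalanceData, V: float,
                                 n_samples: int = 5, seed: int = 0,
                                 tail_tol: float = 1e-14) -> dict:
    """Numerically verify the exactness of the Poisson reduction.

    For sampled concentrations ``c`` and covectors ``zeta`` checks

    1. ``E_V(Phi_V(c)) = E(c)`` (energy identity),
    2. ``Psi*_V(Phi_V(c), M_V(c) zeta) = 1/2 zeta . K(c) zeta`` with the
       linear lift ``(M_V zeta)_n = zeta . n / V``,
    3. ``D Phi_V(c)* M_V(c) zeta = zeta`` (adjoint identity),

    each reported as a maximum absolute error (truncation-limited).
    """
    from .rre import entropy

    rng = np.random.default_rng(seed)
    I = db.c_star.size
    err_E = err_psi = err_adj = 0.0
    for _ in range(n_samples):
        c = db.c_star * rng.uniform(0.6, 1.6, size=I)
        zeta = rng.uniform(-1.0, 1.0, size=I)
        lattice = TruncatedLattice.from_detailed_balance(db, V, tail_tol,
                                                         extra_means=c)
        phi = poisson_distribution(lattice, c)
        w = poisson_equilibrium(db, lattice)
        err_E = max(err_E, abs(cme_entropy(phi.u, w.u, V) - entropy(db, c)))
        states = lattice.states.astype(float)
        mu = states @ zeta / V
        psi = cme_dual_dissipation(db.network, lattice, phi.u, mu, "quadratic")
        K = onsager_matrix(db, c)
        err_psi = max(err_psi, abs(psi - 0.5 * zeta @ K @ zeta))
        # D Phi_V(c)^*: mu -> ( sum_n phi_n (n_i/c_i - V) mu_n )_i
        factor = states / c[None, :] - V
        zeta_back = (phi.u * mu) @ factor
        err_adj = max(err_adj, float(np.max(np.abs(zeta_back - zeta))))
    return {"energy_identity_error": err_E, "psi_identity_error": err_psi,
            "adjoint_identity_error": err_adj}


def reduce_dual_potential(K_X: np.ndarray, A: np.ndarray, eta: np.ndarray,
                          range_tol: float = 1e-9):
    """Reduced dual dissipation ``inf { 1/2 xi.K_X xi : A^T xi = eta }``.

    ``A`` maps the reduced space Y into X (shape ``dim X x dim Y``); its
    adjoint is ``A^T``.  Returns ``(value, finite)`` where ``finite`` is
    False (value ``inf``) when ``eta`` has a component outside ``Ran(A^T)``,
    realising the convention ``inf over the empty set = inf``.
    """
    K_X = np.asarray(K_X, dtype=float)
    A = np.asarray(A, dtype=float)
    eta = np.asarray(eta, dtype=float)
    nX = K_X.shape[0]
    # feasibility: eta in Ran(A^T)
    xi_feas, *_ = np.linalg.lstsq(A.T, eta, rcond=None)
    if np.linalg.norm(A.T @ xi_feas - eta) > range_tol * max(1.0, np.linalg.norm(eta)):
        return float("inf"), False
    nY = A.shape[1]
    kkt = np.block([[K_X, A], [A.T, np.zeros((nY, nY))]])
    rhs = np.concatenate([np.zeros(nX), eta])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    xi = sol[:nX]
    return float(0.5 * xi @ K_X @ xi), True


# ---------------------------------------------------------------------------
# CME coupled to a rate equation (one stochastic species, X1 <-> beta X2)


@dataclass
class HybridStateCMRR:
    """State of the CME/rate-equation hybrid: count distribution + concentration."""

    v: np.ndarray
    c_m: float
    V: float
    beta_coeff: int

    def mean_count_concentration(self) -> float:
        return float(np.arange(self.v.size) @ self.v) / self.V


def _cmrr_rhs(y: np.ndarray, V: float, beta: int, M_max: int) -> np.ndarray:
    v, c2 = y[:-1], max(y[-1], 0.0)
    birth = V * c2 ** beta
    dv = np.zeros_like(v)
    dv[1:] += birth * v[:-1]            # gain from m-1
    dv[:-1] -= birth * v[:-1]           # matching loss (none out of M_max)
    m = np.arange(M_max + 1, dtype=float)
    dv[:-1] += (m[1:] * v[1:])          # gain from m+1 deaths
    dv -= m * v                         # death losses
    mean = float(m @ v) / V
    dc2 = beta * (mean - c2 ** beta)
    return np.append(dv, dc2)


def simulate_cme_rre(beta_coeff: int, V: float, M_max: int,
                     v0: np.ndarray, c2_0: float, t_grid: Sequence[float],
                     rtol: float = 1e-10, atol: float = 1e-13
                     ) -> list[HybridStateCMRR]:
    """Integrate the hybrid system for the reaction ``X1 <-> beta X2``.

    The stochastic species follows the birth-death chain
    ``v_m' = V c2^beta v_{m-1} - (m + V c2^beta) v_m + (m+1) v_{m+1}``
    (reflecting truncation at ``M_max``), coupled to
    ``c2' = beta ((1/V) sum m v_m - c2^beta)``, so the conserved quantity is
    ``beta * mean/V + c2``.  At ``(v, c2) = (Poisson(V), 1)`` the system is
    stationary.
    """
    v0 = np.asarray(v0, dtype=float)
    if v0.size != M_max + 1:
        raise ValueError("v0 must have M_max + 1 entries")
    t_grid = np.asarray(t_grid, dtype=float)
    y0 = np.append(v0, c2_0)
    sol = solve_ivp(lambda _t, y: _cmrr_rhs(y, V, beta_coeff, M_max),
                    (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"hybrid CME-RRE integration failed: {sol.message}")
    return [HybridStateCMRR(sol.y[:-1, k], float(sol.y[-1, k]), V, beta_coeff)
            for k in range(t_grid.size)]


def cme_rre_stationarity_residual(beta_coeff: int, V: float, M_max: int,
                                  v: np.ndarray, c2: float) -> tuple[float, float]:
    """Max |dv/dt| and |dc2/dt| at a candidate stationary state."""
    dy = _cmrr_rhs(np.append(np.asarray(v, float), c2), V, beta_coeff, M_max)
    return float(np.max(np.abs(dy[:-1]))), float(abs(dy[-1]))


def truncated_poisson(mean_count: float, M_max: int) -> np.ndarray:
    """Poisson(mean_count) conditioned on {0..M_max}."""
    m = np.arange(M_max + 1, dtype=float)
    logw = m * np.log(mean_count) - gammaln(m + 1.0) - mean_count
    w = np.exp(logw - logw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# Fokker-Planck density coupled to a rate equation (mean field, I = 2)


@dataclass
class FPRRState:
    """State of the FP/rate-equation hybrid: density in c_s, concentration c_m."""

    rho_s: GridDensity1D
    c_m_hat: float
    V: float


def _fp_rre_blocks(db: DetailedBalanceData, c_s: np.ndarray, c_m: float):
    """K blocks and reaction fluxes along a c_s array at fixed c_m."""
    net = db.network
    ca_s, cb_s = net.monomials(db.c_star)
    pts = np.stack([c_s, np.full_like(c_s, c_m)], axis=1)
    ca = np.prod(pts[:, None, :] ** net.alpha[None, :, :], axis=2)
    cb = np.prod(pts[:, None, :] ** net.beta[None, :, :], axis=2)
    lam = logmean(ca / ca_s[None, :], cb / cb_s[None, :]) * db.kappa_star[None, :]
    gam = net.gamma.astype(float)
    K_ss = lam @ (gam[:, 0] ** 2)
    K_sm = lam @ (gam[:, 0] * gam[:, 1])
    flux = (net.k_fw[None, :] * ca - net.k_bw[None, :] * cb)
    R_s = flux @ gam[:, 0]
    R_m = flux @ gam[:, 1]
    return K_ss, K_sm, R_s, R_m


def simulate_fp_rre(db: DetailedBalanceData, V: float, rho_s0: GridDensity1D,
                    c_m0: float, t_grid: Sequence[float],
                    rtol: float = 1e-8, atol: float = 1e-10) -> list[FPRRState]:
    """Integrate the mean-field hybrid (species 1 stochastic, species 2 macroscopic).

    .. math::

        \\dot\\rho = \\partial_s\\big(\\tfrac1V K_{ss}\\partial_s\\rho
                     + \\rho R_s(c_s,\\hat c_m)\\big), \\qquad
        \\dot{\\hat c}_m = -\\int \\big(\\tfrac1V K_{sm}\\partial_s\\rho
                     + \\rho R_m\\big)\\,dc_s .

    The same face fluxes are used in both equations, so any linear
    conservation law of the underlying network is inherited by the
    discretisation (up to solver tolerance).  No-flux ends preserve the mass
    of ``rho``.
    """
    if db.c_star.size != 2:
        raise ValueError("mean-field hybrid implemented for exactly two species")
    edges = rho_s0.edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    faces = edges[1:-1]
    dc = 0.5 * (widths[:-1] + widths[1:])
    M = centers.size

    def bernoulli(x):
        x = np.asarray(x, dtype=float)
        small = np.abs(x) < 1e-8
        return np.where(small, 1.0 - 0.5 * x,
                        x / np.expm1(np.where(small, 1.0, x)))

    def rhs(_t, y):
        rho, c_m = y[:-1], max(y[-1], 0.0)
        K_ss_f, K_sm_f, R_s_f, R_m_f = _fp_rre_blocks(db, faces, c_m)
        grad = (rho[1:] - rho[:-1]) / dc
        # exponential-fitted flux F_s = D grad + v rho with D = K_ss/V, v = R_s
        D = K_ss_f / V
        P = R_s_f * dc / D
        F_s = D / dc * (bernoulli(-P) * rho[1:] - bernoulli(P) * rho[:-1])
        # implied face density (consistent with F_s) drives the macroscopic flux
        safe = np.abs(R_s_f) > 1e-12
        rho_face = np.where(safe, (F_s - D * grad) / np.where(safe, R_s_f, 1.0),
                            0.5 * (rho[1:] + rho[:-1]))
        drho = np.zeros(M)
        drho[:-1] += F_s / widths[:-1]
        drho[1:] -= F_s / widths[1:]
        F_m = K_sm_f * grad / V + R_m_f * rho_face
        dc_m = -float(F_m @ dc)
        return np.append(drho, dc_m)

    t_grid = np.asarray(t_grid, dtype=float)
    y0 = np.append(rho_s0.rho, c_m0)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"hybrid FP-RRE integration failed: {sol.message}")
    return [FPRRState(GridDensity1D(edges, sol.y[:-1, k], V), float(sol.y[-1, k]), V)
            for k in range(t_grid.size)]


def fp_rre_energy(db: DetailedBalanceData, state: FPRRState) -> float:
    """Simplified hybrid energy ``int((1/V) rho log rho + rho E_s) + E_m(c_m)``."""
    rho = state.rho_s.rho
    widths = state.rho_s.widths
    centers = state.rho_s.centers
    pos = rho > 0
    ent = np.sum(rho[pos] * np.log(rho[pos]) * widths[pos]) / state.V
    E_s = db.c_star[0] * boltzmann(centers / db.c_star[0])
    pot = float((rho * E_s) @ widths)
    E_m = float(db.c_star[1] * boltzmann(state.c_m_hat / db.c_star[1]))
    return float(ent + pot + E_m)


def A_moment(v: float) -> float:
    """First moment ``A(v) = int z exp(-v lambda_B(z)) dz / Z(v)``; always >= 1."""
    Z, _ = quad(lambda z: np.exp(-v * boltzmann(z)), 0.0, np.inf, limit=200)
    M1, _ = quad(lambda z: z * np.exp(-v * boltzmann(z)), 0.0, np.inf, limit=200)
    return float(M1 / Z)


def e_hat_V(a_hat: float, a_star: float, V: float) -> float:
    """Exact reduced entropy of the macroscopic marginal,
    ``A(V a^) a^ log(a^/a*) - a^ + a* - log(a^ Z(V a^))/V``;
    bounded below by ``a* lambda_B(a^/a*)`` with equality as ``V -> inf``."""
    v = V * a_hat
    Z, _ = quad(lambda z: np.exp(-v * boltzmann(z)), 0.0, np.inf, limit=200)
    return float(A_moment(v) * a_hat * np.log(a_hat / a_star) - a_hat + a_star
                 - np.log(a_hat * Z) / V)


# ---------------------------------------------------------------------------
# mixed CME / Fokker-Planck model for 0 <-> X


@dataclass
class MixedState:
    """Mixed state: probabilities at counts ``0..N-1`` plus a density on ``[N/V, c_max]``."""

    u: np.ndarray
    U: GridDensity1D
    V: float
    N: int
    a_hat: float

    def total_measure(self) -> float:
        return float(self.u.sum() + self.U.mass())


def _mixed_weights(a: float, b: float, V: float, N: int, edges: np.ndarray):
    """Equilibrium pieces: Poisson weights w_0..w_{N-1} and continuous cell
    values of ``W_V / Z_{V,N}`` on the grid, normalised to total measure 1."""
    c_star = a / b
    n = np.arange(N, dtype=float)
    logw = n * np.log(V * c_star) - gammaln(n + 1.0) - V * c_star
    w = np.exp(logw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    Wraw = _what_refined(V, centers, c_star)
    Z = float(Wraw @ widths) / (1.0 - w.sum())
    return w, Wraw / Z


def mixed_equilibrium(a: float, b: float, V: float, N: int,
                      edges: np.ndarray, a_hat: float | None = None) -> MixedState:
    """The hybrid equilibrium measure (Poisson weights + scaled refined density)."""
    w, W = _mixed_weights(a, b, V, N, edges)
    return MixedState(w, GridDensity1D(edges, W, V), V, N,
                      a if a_hat is None else a_hat)


def build_mixed_generator(a: float, b: float, V: float, N: int,
                          edges: np.ndarray, a_hat: float | None = None
                          ) -> sp.csc_matrix:
    """Generator of the mixed model on ``y = (u_0..u_{N-1}, m_1..m_M)``.

    ``m_j`` are continuous cell *masses*, so every column sums to zero and
    the total measure is conserved exactly.  Three parts:

    * the CME birth-death stencil on ``{0..N-1}`` (birth ``Va``, death ``bn``);
    * the gradient-form finite-volume flux of the refined Fokker-Planck
      equation between continuous cells (weights ``W_V``, mobility
      ``Lambda(a, bc)`` at faces), whose discrete equilibrium is exactly the
      cell-averaged ``W_V``;
    * the interface exchange between ``u_{N-1}`` and the first cell realising
      the printed coupling conditions: rate ``V a^`` out of ``u_{N-1}`` and
      back-rate proportional to ``U(N/V)/W(N/V)``, so the exchange vanishes
      identically on the hybrid equilibrium.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    a_hat = a if a_hat is None else a_hat
    w, W = _mixed_weights(a, b, V, N, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    faces = edges[1:-1]
    dcf = 0.5 * (widths[:-1] + widths[1:])
    M = centers.size
    dim = N + M
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    def exchange(i, j, rate_ij, rate_ji):
        add(j, i, rate_ij)
        add(i, i, -rate_ij)
        add(i, j, rate_ji)
        add(j, j, -rate_ji)

    # CME part on {0..N-1}
    for n in range(N - 1):
        exchange(n, n + 1, V * a, b * (n + 1))
    # continuous FV part in mass coordinates:
    # dm_j/dt gains flux (Lam_f Wgeo_f / V) ((U/W)_{j+1} - (U/W)_j)/dcf
    lam_f = logmean(np.full(faces.size, a), b * faces)
    wgeo = np.sqrt(W[:-1] * W[1:])
    coef = lam_f * wgeo / (V * dcf)
    for f in range(M - 1):
        i, j = N + f, N + f + 1
        # per unit mass: U_j = m_j / width_j, ratio U_j / W_j
        exchange(i, j, coef[f] / (W[f] * widths[f]),
                 coef[f] / (W[f + 1] * widths[f + 1]))
    # interface between u_{N-1} and first continuous cell
    back = V * a_hat * w[N - 1] / (W[0] * widths[0])
    exchange(N - 1, N, V * a_hat, back)
    G = sp.csc_matrix((vals, (rows, cols)), shape=(dim, dim))
    return G


def simulate_mixed_cme_fp(a: float, b: float, V: float, N: int,
                          state0: MixedState, t_grid: Sequence[float],
                          a_hat: float | None = None) -> list[MixedState]:
    """Propagate the mixed model by the action of the matrix exponential."""
    edges = state0.U.edges
    G = build_mixed_generator(a, b, V, N, edges, a_hat)
    widths = np.diff(edges)
    y = np.concatenate([state0.u, state0.U.rho * widths])
    out = [state0]
    t_grid = np.asarray(t_grid, dtype=float)
    for dt in np.diff(t_grid):
        y = expm_multiply(G * dt, y)
        out.append(MixedState(y[:N].copy(),
                              GridDensity1D(edges, y[N:] / widths, V),
                              V, N, state0.a_hat))
    return out


def mixed_entropy(a: float, b: float, state: MixedState) -> float:
    """Relative entropy per volume of a mixed state against the hybrid equilibrium."""
    w, W = _mixed_weights(a, b, state.V, state.N, state.U.edges)
    widths = state.U.widths
    disc = float(np.sum(boltzmann(np.maximum(state.u, 0.0) / w) * w))
    cont = float(np.sum(boltzmann(np.maximum(state.U.rho, 0.0) / W) * W * widths))
    return (disc + cont) / state.V


def robin_interface_mismatch(a: float, b: float, V: float, N: int,
                             edges: np.ndarray) -> float:
    """Relative gap between the exact interface back-rate and its large-V
    Robin form: ``|V a w_{N-1} / W(N/V) - b N / V| / (b N / V)`` (-> 0 as V grows)."""
    w, W = _mixed_weights(a, b, V, N, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # recover the normalisation and evaluate W_V at the interface point N/V
    Z = _what_refined(V, centers[:1], a / b)[0] / W[0]
    W_interface = _what_refined(V, np.array([N / V]), a / b)[0] / Z
    exact = V * a * w[N - 1] / W_interface
    approx = b * N / V
    return abs(exact - approx) / approx
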