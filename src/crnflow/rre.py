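"""Macroscopic reaction-rate equations as entropy gradient flows.

For a detailed-balance network with equilibrium ``c*`` and fluxes
``kappa*^r``, the mass-action ODE ``c' = -R(c)`` is the gradient flow of the
relative Boltzmann entropy

.. math:: E(c) = \\sum_i c^*_i\\, \\lambda_B(c_i/c^*_i), \\qquad
          \\lambda_B(z) = z\\log z - z + 1,

with respect to the Onsager mobility built from the *logarithmic mean*
``Lambda(a,b) = (a-b)/(log a - log b)``:

.. math:: \\mathbb{K}(c) = \\sum_r \\kappa^r_*\\,
          \\Lambda\\Big(\\tfrac{c^{\\alpha^r}}{c_*^{\\alpha^r}},
                        \\tfrac{c^{\\beta^r}}{c_*^{\\beta^r}}\\Big)\\,
          \\gamma^r \\otimes \\gamma^r ,

so that ``K(c) DE(c) = R(c)`` holds identically.  Beyond the quadratic
dissipation ``Psi*(c, zeta) = 1/2 zeta.K(c) zeta`` the module provides the
tilt-invariant cosh-type dual dissipation potential and, for unimolecular
(Markov-chain) networks only, general-phi Onsager matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import DetailedBalanceData, ReactionNetwork

__all__ = [
    "logmean", "logmean_d2", "boltzmann",
    "reaction_rhs", "entropy", "entropy_gradient",
    "onsager_matrix", "ctmc_onsager_matrix", "general_phi_onsager_matrix",
    "dual_dissipation", "dissipation_force",
    "integrate_rre", "RRETrajectory",
]

DissipationKind = Literal["quadratic", "cosh"]


def boltzmann(z):
    """Boltzmann function ``lambda_B(z) = z log z - z + 1`` with ``0 log 0 = 0``."""
    z = np.asarray(z, dtype=float)
    out = np.ones_like(z)
    pos = z > 0
    zp = z[pos]
    out[pos] = zp * np.log(zp) - zp + 1.0
    if np.any(z < 0):
        raise ValueError("lambda_B requires z >= 0")
    return out if out.ndim else float(out)


def logmean(a, b):
    """Logarithmic mean ``Lambda(a,b) = (a-b)/(log a - log b)``.

    Continuously extended by ``Lambda(a,a) = a`` and ``Lambda(a,0) = 0``.
    Near ``a = b`` the symmetric series in ``s = log(a/b)`` is used,
    ``Lambda = m/cosh(s/2) * (sinh(s/2)/(s/2))``... evaluated as
    ``sqrt(ab) * (s/2)/sinh(s/2)`` inverse; concretely we use
    ``Lambda = sqrt(ab) * sinh(s/2)/(s/2)`` with a Taylor fallback, which is
    exact and avoids cancellation in ``a - b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    out = np.zeros(a.shape)
    both = (a > 0) & (b > 0)
    if np.any((a < 0) | (b < 0)):
        raise ValueError("logmean requires nonnegative arguments")
    ab, bb = a[both], b[both]
    s = np.log(ab) - np.log(bb)
    small = np.abs(s) < 1e-6
    res = np.empty_like(ab)
    # sqrt(ab)*sinh(s/2)/(s/2) == (a-b)/(log a - log b), stable for s not small
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(small, 0.0, (ab - bb) / np.where(small, 1.0, s))
    m = 0.5 * (ab + bb)
    # symmetric expansion around a=b: Lambda = m (1 - s^2/24 + ...)
    res[small] = m[small] * (1.0 - s[small] ** 2 / 24.0)
    out[both] = res
    return out if out.ndim else float(out)


def logmean_d2(a, b):
    """Partial derivative of the logarithmic mean in its second argument.

    ``d/db Lambda(a,b) = (Lambda/b) (b - Lambda)/(b - a)`` for ``a != b``
    and ``1/2`` at ``a = b`` (series fallback near the diagonal).
    """
    a = float(a)
    b = float(b)
    if a <= 0 or b <= 0:
        raise ValueError("logmean_d2 requires positive arguments")
    t = (b - a) / (0.5 * (a + b))
    if abs(t) < 1e-5:
        return 0.5 - t / 6.0
    lam = logmean(a, b)
    return (lam / b) * (b - lam) / (b - a)


# ---------------------------------------------------------------------------
# right-hand side, entropy, Onsager matrix


def reaction_rhs(net: ReactionNetwork, c) -> np.ndarray:
    """Time derivative ``dc/dt = -R(c)`` of the mass-action rate equations."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    ca, cb = net.monomials(c)
    return -((net.k_fw * ca - net.k_bw * cb) @ net.gamma)


def entropy(db: DetailedBalanceData, c) -> float:
    """Relative entropy ``E(c) = sum_i c*_i lambda_B(c_i/c*_i)``."""
    c = np.asarray(c, dtype=float)
    return float(np.sum(db.c_star * boltzmann(c / db.c_star)))


def entropy_gradient(db: DetailedBalanceData, c) -> np.ndarray:
    """Entropy gradient ``DE(c) = (log(c_i/c*_i))_i``; requires ``c > 0``."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("entropy gradient undefined on the boundary c_i = 0")
    return np.log(c / db.c_star)


def _relative_monomials(db: DetailedBalanceData, c):
    net = db.network
    ca, cb = net.monomials(np.asarray(c, dtype=float))
    ca_s, cb_s = net.monomials(db.c_star)
    return ca / ca_s, cb / cb_s


def onsager_matrix(db: DetailedBalanceData, c) -> np.ndarray:
    """Onsager mobility ``K(c)`` (symmetric positive semidefinite, I x I)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    a, b = _relative_monomials(db, c)
    lam = logmean(a, b)
    gam = db.network.gamma.astype(float)
    return np.einsum("r,ri,rj->ij", db.kappa_star * lam, gam, gam)


def ctmc_onsager_matrix(db: DetailedBalanceData, c) -> np.ndarray:
    """Markov-chain Onsager matrix built directly from exchange fluxes.

    For unimolecular networks (every reaction ``X_i <-> X_j``) this assembles
    ``K_M(c) = sum kappa*^{ij} Lambda(c_i/c*_i, c_j/c*_j) (e_i-e_j)(e_i-e_j)^T``
    independently of :func:`onsager_matrix`, with which it coincides.
    """
    return general_phi_onsager_matrix(db, c, phi=None)


def general_phi_onsager_matrix(db: DetailedBalanceData, c,
                               phi: tuple[Callable, Callable] | None = None) -> np.ndarray:
    """General-phi Onsager matrix for unimolecular (CTMC) networks.

    ``phi`` is a pair ``(phi_prime, phi_second)`` of the first and second
    derivative of a strictly convex entropy density; ``None`` selects the
    Boltzmann function, recovering the logarithmic-mean matrix.  For
    non-unimolecular networks the construction can produce indefinite
    mobilities, so it is refused there.
    """
    net = db.network
    if not net.is_unimolecular():
        raise ValueError("general-phi structures are restricted to unimolecular networks")
    c = np.asarray(c, dtype=float)
    I = net.n_species
    K = np.zeros((I, I))
    rel = c / db.c_star
    for r in range(net.n_reactions):
        i = int(np.argmax(net.alpha[r]))
        j = int(np.argmax(net.beta[r]))
        a, b = rel[i], rel[j]
        if phi is None:
            mob = logmean(a, b)
        else:
            dphi, d2phi = phi
            if abs(a - b) < 1e-9 * (abs(a) + abs(b) + 1):
                mob = 1.0 / d2phi(0.5 * (a + b))
            else:
                mob = (a - b) / (dphi(a) - dphi(b))
        e = np.zeros(I)
        e[i], e[j] = 1.0, -1.0
        K += db.kappa_star[r] * mob * np.outer(e, e)
    return K


# ---------------------------------------------------------------------------
# generalized dissipation potentials


def _cosh_Cstar(z):
    return 4.0 * np.cosh(0.5 * np.asarray(z, dtype=float)) - 4.0


def _cosh_Cstar_prime(z):
    return 2.0 * np.sinh(0.5 * np.asarray(z, dtype=float))


def dual_dissipation(db: DetailedBalanceData, c, zeta,
                     kind: DissipationKind = "quadratic") -> float:
    """Dual dissipation potential ``Psi*(c, zeta)``.

    ``kind='quadratic'`` gives ``1/2 zeta.K(c) zeta``; ``kind='cosh'`` gives
    the tilt-invariant potential
    ``sum_r kappa*^r sqrt(a_r b_r) (4 cosh(gamma^r.zeta / 2) - 4)``
    with ``a_r = c^alpha/c*^alpha``, ``b_r = c^beta/c*^beta``.
    """
    zeta = np.asarray(zeta, dtype=float)
    if kind == "quadratic":
        return float(0.5 * zeta @ onsager_matrix(db, c) @ zeta)
    if kind != "cosh":
        raise ValueError(f"unknown dissipation kind {kind!r}")
    a, b = _relative_monomials(db, c)
    g = db.network.gamma.astype(float) @ zeta
    return float(np.sum(db.kappa_star * np.sqrt(a * b) * _cosh_Cstar(g)))


def dissipation_force(db: DetailedBalanceData, c,
                      kind: DissipationKind = "quadratic") -> np.ndarray:
    """Velocity ``d_zeta Psi*(c, -DE(c))``, which equals ``-R(c)`` for both kinds."""
    c = np.asarray(c, dtype=float)
    if kind == "quadratic":
        return -(onsager_matrix(db, c) @ entropy_gradient(db, c))
    if kind != "cosh":
        raise ValueError(f"unknown dissipation kind {kind!r}")
    a, b = _relative_monomials(db, c)
    gam = db.network.gamma.astype(float)
    g = gam @ (-entropy_gradient(db, c))
    weights = db.kappa_star * np.sqrt(a * b) * _cosh_Cstar_prime(g)
    return weights @ gam


# ---------------------------------------------------------------------------
# integration


@dataclass
class RRETrajectory:
    """Concentration trajectory with entropy and dissipation records."""

    t: np.ndarray
    c: np.ndarray          # shape (len(t), I)
    energy: np.ndarray | None = None
    dissipation: np.ndarray | None = None

    def __iter__(self):
        return iter((self.t, self.c))


def integrate_rre(net: ReactionNetwork, c0, t_grid,
                  db: DetailedBalanceData | None = None,
                  rtol: float = 1e-8, atol: float = 1e-10,
                  clip_warn: float = -1e-8) -> RRETrajectory:
    """Integrate ``c' = -R(c)`` on the given time grid with a stiff solver.

    Negative excursions (possible at solver tolerance near the boundary) are
    clipped to 0; a warning is emitted if they exceed ``clip_warn`` in
    magnitude.  When ``db`` is given, the relative entropy and the quadratic
    dissipation ``Psi*(c, -DE)`` are recorded along the trajectory.
    """
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_t, c):
        return reaction_rhs(net, np.maximum(c, 0.0))

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), c0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"RRE integration failed at t={sol.t[-1]:g}: {sol.message}")
    c = sol.y.T
    if np.min(c) < clip_warn:
        import warnings
        warnings.warn(f"negative excursion {np.min(c):.3e} clipped to 0")
    c = np.maximum(c, 0.0)
    energy = dissipation = None
    if db is not None:
        energy = np.array([entropy(db, ck) for ck in c])
        dissipation = np.array([
            dual_dissipation(db, np.maximum(ck, 1e-300), -entropy_gradient(
                db, np.maximum(ck, 1e-300)), "quadratic") for ck in c])
    return RRETrajectory(t=t_grid, c=c, energy=energy, dissipation=dissipation)
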