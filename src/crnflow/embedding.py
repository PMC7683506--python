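"""Embeddings between lattice distributions and densities on concentration space.

The embedding ``iota_V`` spreads the mass of a lattice distribution ``u``
uniformly over the half-open cubes ``A_n^V = prod_i [n_i/V, (n_i+1)/V)``,
giving the piecewise-constant density ``rho(c) = V^I u_n`` on ``A_n^V``.
Its dual ``iota_V*`` averages a continuum function over cells, and
``kappa_V`` (cell masses) is a one-sided inverse: ``kappa_V . iota_V = id``.

These maps realise, at finite volume, the large-volume limit in which the
CME gradient system converges to the Liouville transport equation: the
discrete entropy potential ``E_V(c) = -I log(V)/V - (1/V) log w^V_n``
(for ``c in A_n^V``) converges pointwise to the macroscopic relative
entropy ``E(c)`` with rate ``(log V + E(c))/V``, quantified here through
Robbins' two-sided Stirling bounds ``n! = sqrt(2 pi k_n) (n/e)^n`` with
``k_n = n + 1/6 + gamma_n/(124/5 + 72 n)``, ``gamma_n in [0.9, 1]``.
The module exposes these as numerical *diagnostics* (tables and trends),
not as assertions with unknown constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

from .cme import LatticeDistribution, TruncatedLattice, cme_entropy, poisson_equilibrium
from .network import DetailedBalanceData
from .rre import entropy, logmean

__all__ = [
    "GridDensityND",
    "iota_V", "iota_V_star", "kappa_V",
    "discrete_potential_EV", "stirling_k", "stirling_gamma",
    "lemma_42_table", "psi_lio", "entropy_of_projection",
]

# 3-point Gauss-Legendre nodes/weights on [0, 1] (exact through degree 5)
_GAUSS_X = 0.5 * (1.0 + np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)]))
_GAUSS_W = 0.5 * np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


@dataclass
class GridDensityND:
    """Piecewise-constant density on the cubes ``A_n^V`` of a truncation box."""

    values: np.ndarray          # rho = V^I u_n, flat over lattice states
    lattice: TruncatedLattice

    @property
    def cell_volume(self) -> float:
        return float(self.lattice.V ** -self.lattice.n_species)

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_volume)

    def mean(self) -> np.ndarray:
        """Mean of the density (cell centres weight the uniform cube mass)."""
        centers = (self.lattice.states + 0.5) / self.lattice.V
        return (centers.T @ self.values) * self.cell_volume


def iota_V(u: LatticeDistribution) -> GridDensityND:
    """Embed ``u`` as the piecewise-constant density ``V^I u_n`` on ``A_n^V``."""
    V = u.lattice.V
    return GridDensityND(u.u * V ** u.lattice.n_species, u.lattice)


def _cell_quadrature_nodes(lattice: TruncatedLattice):
    """Tensor 3-point Gauss nodes/weights on every cell; cached per lattice shape."""
    I = lattice.n_species
    grids = np.meshgrid(*([_GAUSS_X] * I), indexing="ij")
    offsets = np.stack([g.ravel() for g in grids], axis=1)        # (3^I, I)
    wgrids = np.meshgrid(*([_GAUSS_W] * I), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    return offsets, weights


def iota_V_star(xi: Callable[[np.ndarray], np.ndarray],
                lattice: TruncatedLattice) -> np.ndarray:
    """Dual embedding: cell averages of ``xi`` by fixed 3-point tensor Gauss.

    ``xi`` must accept an ``(N, I)`` array of concentration points and return
    ``N`` values.  Exact for polynomials through degree 5 per axis.
    """
    offsets, weights = _cell_quadrature_nodes(lattice)
    states = lattice.states
    out = np.zeros(lattice.n_states)
    for off, wq in zip(offsets, weights):
        pts = (states + off[None, :]) / lattice.V
        out += wq * np.asarray(xi(pts), dtype=float)
    return out


def kappa_V(rho, lattice: TruncatedLattice | None = None) -> LatticeDistribution:
    """Cell masses ``kappa_V(rho)_n = rho(A_n^V)``; inverse of ``iota_V``.

    Accepts a :class:`GridDensityND` (exact) or a callable density on
    concentration space (cell averages by 3-point tensor Gauss, then
    multiplied by the cell volume).
    """
    if isinstance(rho, GridDensityND):
        lat = rho.lattice
        return LatticeDistribution(rho.values * lat.V ** -lat.n_species, lat)
    if lattice is None:
        raise ValueError("a lattice is required for a callable density")
    avg = iota_V_star(rho, lattice)
    u = avg * lattice.V ** -lattice.n_species
    return LatticeDistribution(np.maximum(u, 0.0), lattice)


# ---------------------------------------------------------------------------
# discrete entropy potential and Stirling diagnostics


def discrete_potential_EV(db: DetailedBalanceData, c, V: float) -> float:
    """Discrete entropy potential ``E_V(c) = -I log(V)/V - (1/V) log w^V_n``.

    ``n`` is the lattice cell containing ``c`` (``c in A_n^V``) and ``w^V``
    the un-normalised product-Poisson weight, evaluated in log space.
    """
    if V <= 0:
        raise ValueError("V must be positive")
    c = np.atleast_1d(np.asarray(c, dtype=float))
    n = np.floor(c * V)
    m = db.c_star * V
    logw = float(np.sum(n * np.log(m) - gammaln(n + 1.0) - m))
    I = c.size
    return -I * np.log(V) / V - logw / V


def stirling_k(n: int) -> float:
    """Stirling parameter ``k_n`` in ``n! = sqrt(2 pi k_n) (n/e)^n`` (``k_0 = 1/(2 pi)``)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return float(1.0 / (2.0 * np.pi))
    import mpmath

    with mpmath.workdps(40):
        logk = (2 * mpmath.loggamma(n + 1) + 2 * n * (1 - mpmath.log(n))
                - mpmath.log(2 * mpmath.pi))
        return float(mpmath.e ** logk)


def stirling_gamma(n: int) -> float:
    """Stirling correction ``gamma_n = (k_n - n - 1/6)(124/5 + 72 n)``.

    Lies in ``[0.9, 1]`` for every ``n >= 1`` (the minimum is at ``n = 1``).
    Evaluated through high-precision log-factorials: the subtraction
    ``k_n - n - 1/6`` loses ~``2 log10(n)`` digits to cancellation, which
    double precision cannot afford beyond ``n ~ 10^3``.
    """
    if n < 1:
        raise ValueError("gamma_n is defined for n >= 1")
    import mpmath

    with mpmath.workdps(40):
        logk = (2 * mpmath.loggamma(n + 1) + 2 * n * (1 - mpmath.log(n))
                - mpmath.log(2 * mpmath.pi))
        k = mpmath.e ** logk
        return float((k - n - mpmath.mpf(1) / 6) * (mpmath.mpf(124) / 5 + 72 * n))


def lemma_42_table(db: DetailedBalanceData, c_grid: np.ndarray,
                   V_list: Sequence[float]):
    """Pointwise convergence diagnostic of ``E_V`` towards ``E``.

    For each volume returns the supremum over the grid of ``|E_V - E|`` and
    of the normalised error ``V |E_V - E| / (log V + E)``; the latter is an
    empirical stand-in for the (existential) constant in the pointwise bound
    ``|E_V - E| <= K (log V + E)/V``.
    """
    c_grid = np.atleast_2d(np.asarray(c_grid, dtype=float))
    if c_grid.shape[0] == 1 and db.c_star.size == 1:
        c_grid = c_grid.T
    rows = []
    for V in V_list:
        errs, normed = [], []
        for c in c_grid:
            e = entropy(db, c)
            ev = discrete_potential_EV(db, c, V)
            errs.append(abs(ev - e))
            normed.append(abs(ev - e) * V / (np.log(V) + e))
        rows.append({"V": float(V), "sup_err": float(np.max(errs)),
                     "normalized_err": float(np.max(normed))})
    return rows


# ---------------------------------------------------------------------------
# Liouville dissipation


def _G(a, b):
    """Convex function ``G(a,b) = (a-b)(log a - log b)`` (continuation by 0 at a=b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) * (np.log(a) - np.log(b))
    return np.where(a == b, 0.0, out)


def psi_lio(db: DetailedBalanceData, measure, xi_gradient=None,
            form: str = "K") -> float:
    """Liouville dual dissipation ``Psi*_Lio(rho, xi) = 1/2 int grad xi . K grad xi d rho``.

    ``measure`` is either an atomic mixture (an object with ``weights`` and
    ``locations``) or a :class:`GridDensityND`.  When ``xi_gradient`` is
    omitted, ``xi = E`` is used; then ``form='G'`` evaluates the equivalent
    flux form ``1/2 int sum_r kappa*^r G(c^alpha/c*^alpha, c^beta/c*^beta)
    d rho`` and ``form='K'`` the quadratic form — the two must agree.
    """
    net = db.network
    gam = net.gamma.astype(float)
    ca_s, cb_s = net.monomials(db.c_star)

    def integrand(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        ca = np.prod(points[:, None, :] ** net.alpha[None, :, :], axis=2) / ca_s
        cb = np.prod(points[:, None, :] ** net.beta[None, :, :], axis=2) / cb_s
        if xi_gradient is None and form == "G":
            return 0.5 * np.sum(db.kappa_star[None, :] * _G(ca, cb), axis=1)
        if xi_gradient is None:
            with np.errstate(divide="ignore"):
                grads = np.log(points / db.c_star[None, :])
        else:
            grads = np.atleast_2d(xi_gradient(points))
        lam = logmean(ca, cb)
        gdot = grads @ gam.T
        return 0.5 * np.sum(db.kappa_star[None, :] * lam * gdot ** 2, axis=1)

    if hasattr(measure, "weights") and hasattr(measure, "locations"):
        pts = np.atleast_2d(np.asarray(measure.locations, dtype=float))
        w = np.asarray(measure.weights, dtype=float)
        return float(w @ integrand(pts))
    if isinstance(measure, GridDensityND):
        lat = measure.lattice
        avg = iota_V_star(integrand, lat)
        return float(avg @ measure.values) * measure.cell_volume
    raise TypeError("measure must be an atomic mixture or a GridDensityND")


def entropy_of_projection(db: DetailedBalanceData, rho_fn, V: float,
                          lattice: TruncatedLattice):
    """Pair ``(E_V(kappa_V(rho)), E(rho))`` for a smooth density ``rho_fn``.

    The first entry is the CME relative entropy of the projected distribution
    against the (conditioned) Poisson equilibrium, the second the limiting
    Liouville energy ``int E d rho`` by cell quadrature; their difference
    decays like ``log V / V`` for smooth densities.
    """
    u = kappa_V(rho_fn, lattice).normalized()
    w = poisson_equilibrium(db, lattice)
    ev = cme_entropy(u.u, w.u, V)

    def e_fn(points):
        points = np.atleast_2d(points)
        rel = points / db.c_star[None, :]
        lamb = np.where(rel > 0, rel * np.log(np.maximum(rel, 1e-300)) - rel + 1, 1.0)
        return np.sum(db.c_star[None, :] * lamb, axis=1)

    e_avg = iota_V_star(e_fn, lattice)
    rho_mass = kappa_V(rho_fn, lattice).u
    rho_mass = rho_mass / rho_mass.sum()
    e_limit = float(e_avg @ rho_mass)
    return ev, e_limit
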