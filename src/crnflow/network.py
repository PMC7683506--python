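"""Reaction networks, stoichiometry and detailed balance.

A mass-action network consists of ``R`` reversible reactions

.. math::

    \\alpha^r_1 X_1 + \\dots + \\alpha^r_I X_I
    \\;\\rightleftharpoons\\;
    \\beta^r_1 X_1 + \\dots + \\beta^r_I X_I

with forward/backward rate constants ``k_fw``, ``k_bw``.  The network
*satisfies detailed balance* if a positive concentration vector ``c*``
exists at which every reaction pair balances individually,

.. math:: \\kappa^r_* := k^r_{fw}\\, c_*^{\\alpha^r} = k^r_{bw}\\, c_*^{\\beta^r},

which after taking logarithms is the linear system
``W log c* = log(k_bw/k_fw)`` for the Wegscheider matrix ``W`` whose rows are
the stoichiometric difference vectors ``gamma^r = alpha^r - beta^r``.  By
Fredholm's alternative, solvability is equivalent to the *Wegscheider
conditions*: ``y . log(k_bw/k_fw) = 0`` for every ``y`` in ``ker W^T``.

Kernel bases are computed in exact rational arithmetic (sympy), so
conservation laws ``Q c = const`` hold exactly and the number of independent
Wegscheider conditions obeys ``n_W = R - I + m_W`` without floating-point
rank ambiguity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import sympy

__all__ = [
    "ReactionNetwork",
    "DetailedBalanceData",
    "ReactionFileError",
    "IrreversibleReactionError",
    "WegscheiderViolationError",
    "parse_reaction_file",
    "parse_reaction_text",
    "stoichiometric_analysis",
    "wegscheider_check",
    "solve_detailed_balance",
    "random_db_network",
    "example_two_pair_network",
    "TOL_DB",
]

#: default tolerance on log-space detailed-balance residuals
TOL_DB = 1e-9


class ReactionFileError(ValueError):
    """Raised on a malformed reaction file; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class IrreversibleReactionError(ValueError):
    """A zero rate constant makes detailed balance undefined."""


class WegscheiderViolationError(ValueError):
    """No detailed-balance equilibrium exists; carries the residual."""

    def __init__(self, residual: float):
        super().__init__(
            "no detailed-balance equilibrium: Wegscheider residual "
            f"{residual:.6g} exceeds tolerance"
        )
        self.residual = residual


@dataclass(frozen=True)
class ReactionNetwork:
    """A mass-action reaction network.

    Parameters
    ----------
    species_names
        Identifiers of the ``I`` species, in declaration order.
    alpha, beta
        ``R x I`` integer matrices of left/right stoichiometric coefficients.
    k_fw, k_bw
        Length-``R`` nonnegative rate constants (1/time, concentration
        normalised).  Zero rates are allowed here (irreversible reactions)
        but rejected by the detailed-balance routines.
    """

    species_names: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray
    k_fw: np.ndarray
    k_bw: np.ndarray

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=int)
        beta = np.asarray(self.beta, dtype=int)
        object.__setattr__(self, "alpha", np.atleast_2d(alpha))
        object.__setattr__(self, "beta", np.atleast_2d(beta))
        object.__setattr__(self, "k_fw", np.asarray(self.k_fw, dtype=float))
        object.__setattr__(self, "k_bw", np.asarray(self.k_bw, dtype=float))
        object.__setattr__(self, "species_names", tuple(self.species_names))
        R, I = self.alpha.shape
        if R < 1 or I < 1:
            raise ValueError("need at least one reaction and one species")
        if self.beta.shape != (R, I):
            raise ValueError("alpha and beta shapes differ")
        if len(self.species_names) != I:
            raise ValueError("species_names length does not match alpha columns")
        if self.k_fw.shape != (R,) or self.k_bw.shape != (R,):
            raise ValueError("rate vectors must have length R")
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("stoichiometric coefficients must be nonnegative")
        if np.any(self.k_fw < 0) or np.any(self.k_bw < 0):
            raise ValueError("negative rate constant")
        if np.any(self.k_fw + self.k_bw <= 0):
            raise ValueError("every reaction needs k_fw + k_bw > 0")
        if np.any(np.all(self.alpha == self.beta, axis=1)):
            raise ValueError("reaction with alpha^r == beta^r has no effect")

    @property
    def n_species(self) -> int:
        return self.alpha.shape[1]

    @property
    def n_reactions(self) -> int:
        return self.alpha.shape[0]

    @property
    def gamma(self) -> np.ndarray:
        """Stoichiometric difference vectors ``gamma^r = alpha^r - beta^r`` (R x I)."""
        return self.alpha - self.beta

    def monomials(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mass-action monomials ``(c^alpha^r, c^beta^r)`` for each reaction."""
        c = np.asarray(c, dtype=float)
        ca = np.prod(c[None, :] ** self.alpha, axis=1)
        cb = np.prod(c[None, :] ** self.beta, axis=1)
        return ca, cb

    def is_unimolecular(self) -> bool:
        """True when every reaction is a plain species exchange X_i <-> X_j.

        These networks are forward equations of continuous-time Markov chains,
        the only class for which non-Boltzmann (general-phi) gradient
        structures remain positive semidefinite.
        """
        for r in range(self.n_reactions):
            if self.alpha[r].sum() != 1 or self.beta[r].sum() != 1:
                return False
        return True


@dataclass(frozen=True)
class DetailedBalanceData:
    """Equilibrium data of a detailed-balance network.

    Attributes
    ----------
    network
        The underlying :class:`ReactionNetwork`.
    c_star
        Positive equilibrium concentrations (minimum-norm log-space
        representative when the equilibrium manifold has dimension > 0).
    kappa_star
        Equilibrium fluxes ``kappa^r_* = k_fw c*^alpha = k_bw c*^beta``.
    W
        ``R x I`` integer Wegscheider matrix with rows ``gamma^r``.
    Q
        ``m_W x I`` rational conservation matrix; rows span ``ker W``
        (exactly, as :class:`~fractions.Fraction` entries).
    wegscheider_basis
        ``n_W x R`` rational matrix; rows span ``ker W^T``.
    db_residual
        Infinity norm of the Wegscheider residual (log space).
    """

    network: ReactionNetwork
    c_star: np.ndarray
    kappa_star: np.ndarray
    W: np.ndarray
    Q: np.ndarray
    wegscheider_basis: np.ndarray
    m_W: int
    n_W: int
    db_residual: float

    @property
    def Q_float(self) -> np.ndarray:
        return np.asarray(self.Q, dtype=float).reshape(self.m_W, self.network.n_species)


# ---------------------------------------------------------------------------
# parsing

_RATE_RE = re.compile(r"kf\s*=\s*([^\s]+)\s+kb\s*=\s*([^\s]+)\s*$")
_TERM_RE = re.compile(r"^(\d+)?\s*\*?\s*([A-Za-z_]\w*)$")


def _parse_side(side: str, species_index: dict[str, int], lineno: int) -> np.ndarray:
    coeff = np.zeros(len(species_index), dtype=int)
    side = side.strip()
    if side in ("", "0", "∅"):
        return coeff
    for term in side.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ReactionFileError(f"cannot parse term {term!r}", lineno)
        stoich = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        if name not in species_index:
            raise ReactionFileError(f"unknown species {name!r}", lineno)
        coeff[species_index[name]] += stoich
    return coeff


def parse_reaction_text(text: str) -> ReactionNetwork:
    """Parse a reaction network from its textual description.

    Grammar (UTF-8, ``#`` comments)::

        species: X1 X2 X3
        2 X1 + X2 <-> 2 X3 ; kf=1.0 kb=1.0
        0 <-> X1 ; kf=2 kb=4       # empty side written as 0 (or left blank)
    """
    species: list[str] = []
    species_index: dict[str, int] = {}
    alphas, betas, kfs, kbs = [], [], [], []
    seen_species_line = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("species:"):
            if seen_species_line:
                raise ReactionFileError("duplicate species line", lineno)
            seen_species_line = True
            for name in line.split(":", 1)[1].split():
                if name in species_index:
                    raise ReactionFileError(f"duplicate species {name!r}", lineno)
                species_index[name] = len(species)
                species.append(name)
            continue
        if not seen_species_line:
            raise ReactionFileError("species line must come first", lineno)
        if ";" not in line:
            raise ReactionFileError("missing ';' before rate constants", lineno)
        lhs_rhs, rates = line.split(";", 1)
        if "<->" not in lhs_rhs:
            raise ReactionFileError("missing '<->'", lineno)
        lhs, rhs = lhs_rhs.split("<->", 1)
        m = _RATE_RE.match(rates.strip())
        if not m:
            raise ReactionFileError("rates must be given as 'kf=<float> kb=<float>'", lineno)
        try:
            kf, kb = float(m.group(1)), float(m.group(2))
        except ValueError as exc:
            raise ReactionFileError(str(exc), lineno) from None
        if kf < 0 or kb < 0:
            raise ReactionFileError("negative rate constant", lineno)
        a = _parse_side(lhs, species_index, lineno)
        b = _parse_side(rhs, species_index, lineno)
        if np.array_equal(a, b):
            raise ReactionFileError("reaction with alpha^r == beta^r", lineno)
        alphas.append(a)
        betas.append(b)
        kfs.append(kf)
        kbs.append(kb)
    if not species:
        raise ReactionFileError("no species declared")
    if not alphas:
        raise ReactionFileError("no reactions declared")
    return ReactionNetwork(tuple(species), np.array(alphas), np.array(betas),
                           np.array(kfs), np.array(kbs))


def parse_reaction_file(path) -> ReactionNetwork:
    """Read a reaction network from a text file (see :func:`parse_reaction_text`)."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_reaction_text(fh.read())


# ---------------------------------------------------------------------------
# stoichiometric structure


def _primitive_rows(vectors: Sequence[sympy.Matrix]) -> np.ndarray:
    """Scale rational basis vectors to primitive integer form (object array of Fractions)."""
    rows = []
    for v in vectors:
        fracs = [Fraction(sympy.nsimplify(x)) for x in v]
        denom_lcm = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
        ints = [int(f * denom_lcm) for f in fracs]
        g = math.gcd(*(abs(i) for i in ints)) or 1
        ints = [i // g for i in ints]
        lead = next((i for i in ints if i != 0), 1)
        if lead < 0:
            ints = [-i for i in ints]
        rows.append([Fraction(i) for i in ints])
    return np.array(rows, dtype=object)


def stoichiometric_analysis(net: ReactionNetwork):
    """Exact stoichiometric/conservation structure of a network.

    Returns ``(W, Q, m_W, n_W, wegscheider_basis)`` where ``W`` has rows
    ``gamma^r``, the rows of ``Q`` form a primitive integer basis of
    ``ker W`` (the conserved linear quantities ``Q c``), the rows of
    ``wegscheider_basis`` span ``ker W^T``, and ``n_W = R - I + m_W``.
    """
    W = net.gamma
    R, I = W.shape
    M = sympy.Matrix(W.tolist())
    Q = _primitive_rows(M.nullspace())
    y = _primitive_rows(M.T.nullspace())
    m_W = len(Q)
    n_W = len(y)
    Q = Q.reshape(m_W, I) if m_W else np.empty((0, I), dtype=object)
    y = y.reshape(n_W, R) if n_W else np.empty((0, R), dtype=object)
    assert n_W == R - I + m_W
    return W, Q, m_W, n_W, y


def wegscheider_check(net: ReactionNetwork, tol_db: float = TOL_DB):
    """Test the Wegscheider conditions ``y . log(k_bw/k_fw) = 0``.

    Returns ``(satisfied, residual)`` with ``residual`` the maximum of
    ``|y . log(k_bw/k_fw)|`` over the primitive basis vectors ``y`` of
    ``ker W^T`` (0 when there is no condition, i.e. ``n_W = 0``).
    """
    if np.any(net.k_fw <= 0) or np.any(net.k_bw <= 0):
        raise IrreversibleReactionError(
            "irreversible reaction: detailed balance undefined for zero rates")
    _, _, _, n_W, basis = stoichiometric_analysis(net)
    if n_W == 0:
        return True, 0.0
    logratio = np.log(net.k_bw / net.k_fw)
    residual = float(np.max(np.abs(np.asarray(basis, dtype=float) @ logratio)))
    return residual <= tol_db, residual


def solve_detailed_balance(net: ReactionNetwork, tol_db: float = TOL_DB) -> DetailedBalanceData:
    """Solve ``W log c* = log(k_bw/k_fw)`` for a detailed-balance equilibrium.

    The minimum-norm least-squares solution in log space is returned; when the
    kernel of ``W`` is nontrivial (``m_W > 0``) this is one representative of
    the equilibrium manifold ``{c* . exp(Q^T s)}``.

    Raises
    ------
    WegscheiderViolationError
        When the Wegscheider residual exceeds ``tol_db``.
    """
    satisfied, residual = wegscheider_check(net, tol_db)
    if not satisfied:
        raise WegscheiderViolationError(residual)
    W, Q, m_W, n_W, basis = stoichiometric_analysis(net)
    logratio = np.log(net.k_bw / net.k_fw)
    logc, *_ = np.linalg.lstsq(np.asarray(W, dtype=float), logratio, rcond=None)
    c_star = np.exp(logc)
    ca, cb = net.monomials(c_star)
    kappa = net.k_fw * ca
    rel = np.max(np.abs(kappa - net.k_bw * cb) / kappa)
    if rel > max(tol_db, 1e3 * np.finfo(float).eps * net.n_reactions):
        raise WegscheiderViolationError(float(rel))
    return DetailedBalanceData(
        network=net, c_star=c_star, kappa_star=kappa, W=W, Q=Q,
        wegscheider_basis=basis, m_W=m_W, n_W=n_W, db_residual=residual)


def random_db_network(I: int, R: int, max_order: int = 2, seed: int = 0,
                      c_star_range: tuple[float, float] = (0.3, 2.0),
                      kappa_range: tuple[float, float] = (0.5, 2.0),
                      ) -> tuple[ReactionNetwork, DetailedBalanceData]:
    """Draw a random network that satisfies detailed balance by construction.

    Stoichiometric vectors are drawn with entries ``<= max_order`` (rejecting
    ``alpha^r == beta^r``), a positive equilibrium ``c*`` and fluxes
    ``kappa*`` are drawn, and the rate constants are *defined* by inverting
    the detailed-balance relations::

        k_fw^r = kappa*^r / c*^{alpha^r},   k_bw^r = kappa*^r / c*^{beta^r}.

    The returned network therefore passes :func:`wegscheider_check` with
    residual at rounding level, and :func:`solve_detailed_balance` recovers an
    equilibrium with identical fluxes.
    """
    if I < 1 or R < 1:
        raise ValueError("need I, R >= 1")
    rng = np.random.default_rng(seed)
    alphas, betas = [], []
    while len(alphas) < R:
        a = rng.integers(0, max_order + 1, size=I)
        b = rng.integers(0, max_order + 1, size=I)
        if np.array_equal(a, b):
            continue
        alphas.append(a)
        betas.append(b)
    alpha = np.array(alphas)
    beta = np.array(betas)
    c_star = rng.uniform(*c_star_range, size=I)
    kappa = rng.uniform(*kappa_range, size=R)
    ca = np.prod(c_star[None, :] ** alpha, axis=1)
    cb = np.prod(c_star[None, :] ** beta, axis=1)
    names = tuple(f"X{i+1}" for i in range(I))
    net = ReactionNetwork(names, alpha, beta, kappa / ca, kappa / cb)
    return net, solve_detailed_balance(net)


def example_two_pair_network(a: float, b: float) -> ReactionNetwork:
    """The scalar two-reaction-pair network with RRE ``c' = 2a - 4bc + 2(1-c^2)``.

    Reaction pairs ``0 <-> X`` (kf=2a, kb=4b) and ``0 <-> 2X`` (kf=kb=1); the
    individual equilibria are ``a/(2b)`` and ``1``, the joint steady state is
    ``sqrt(1+a+b^2) - b``, and detailed balance holds iff ``a = 2b``.
    """
    return parse_reaction_text(
        "species: X\n"
        f"0 <-> X ; kf={2*a} kb={4*b}\n"
        "0 <-> 2 X ; kf=1 kb=1\n")
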