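"""Hawk-dove game calculus: payoffs, reaction dynamics, and the coexistence equilibrium.

The model couples frequency-dependent selection with logistic density
regulation.  Hawks (density ``u``) and doves (density ``v``) interact in a
well-mixed pool; each strategy's mean payoff depends only on the hawk
fraction ``s = u/(u+v)``.  Per-capita net growth is payoff minus a crowding
term ``kappa*(u+v)``, so the interior fixed point combines the replicator
fixed point for ``s`` with a logistic carrying level for the total density.

Everything downstream (the stochastic lattice, both PDE solvers, and the
linear-stability machinery) builds on the functions in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "PayoffMatrix",
    "GameEquilibrium",
    "ReactionJacobian",
    "build_cv_matrix",
    "payoffs",
    "reaction_rates",
    "frequency_transform",
    "coexistence_equilibrium",
    "reaction_jacobian",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """A 2x2 symmetric game between hawk and dove.

    ``T``: temptation (hawk vs dove), ``R``: reward (dove vs dove),
    ``S``: sucker payoff (dove vs hawk), ``P``: punishment (hawk vs hawk).
    ``V``/``C`` record the resource-contest provenance when the matrix was
    built from a resource of value V contested at fighting cost C.
    """

    T: float
    R: float
    S: float
    P: float
    V: float | None = None
    C: float | None = None

    def is_hawk_dove(self) -> bool:
        """True when the anti-coordination ranking T > R > S > P holds."""
        return self.T > self.R > self.S > self.P

    def require_hawk_dove(self) -> None:
        if not self.is_hawk_dove():
            raise ValueError(
                f"payoffs (T={self.T}, R={self.R}, S={self.S}, P={self.P}) "
                "do not satisfy the hawk-dove ranking T > R > S > P"
            )


def build_cv_matrix(V: float, C: float) -> PayoffMatrix:
    """Hawk-dove payoffs for a contest over a resource of value ``V`` with
    fighting cost ``C``: T=V, R=V/2, S=0, P=(V-C)/2.

    Requires C > V > 0, which guarantees the hawk-dove ranking.
    """
    if not V > 0:
        raise ValueError(f"resource value must be positive, got V={V}")
    if not C > V:
        raise ValueError(f"fighting cost must exceed the resource value, got C={C} <= V={V}")
    return PayoffMatrix(T=V, R=V / 2.0, S=0.0, P=(V - C) / 2.0, V=V, C=C)


def payoffs(u: ArrayLike, v: ArrayLike, matrix: PayoffMatrix) -> Tuple[ArrayLike, ArrayLike]:
    """Mean payoffs (p_H, p_D) in a pool with ``u`` hawks and ``v`` doves.

    p_H = P*u/(u+v) + T*v/(u+v) and p_D = S*u/(u+v) + R*v/(u+v); payoffs
    depend only on the hawk fraction.  An empty pool (u+v = 0) yields
    (0, 0): with nobody present there are no interactions and all
    payoff-driven event rates vanish.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("densities must be nonnegative")
    total = u + v
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, u / np.where(total > 0, total, 1.0), 0.0)
    occupied = total > 0
    p_h = np.where(occupied, matrix.P * s + matrix.T * (1.0 - s), 0.0)
    p_d = np.where(occupied, matrix.S * s + matrix.R * (1.0 - s), 0.0)
    if p_h.ndim == 0:
        return float(p_h), float(p_d)
    return p_h, p_d


def reaction_rates(
    u: ArrayLike, v: ArrayLike, matrix: PayoffMatrix, kappa: float
) -> Tuple[ArrayLike, ArrayLike]:
    """Net growth rates du/dt = u*(p_H - kappa*(u+v)), dv/dt = v*(p_D - kappa*(u+v))."""
    p_h, p_d = payoffs(u, v, matrix)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u * (p_h - kappa * (u + v))
    dv = v * (p_d - kappa * (u + v))
    if np.ndim(du) == 0:
        return float(du), float(dv)
    return du, dv


def frequency_transform(u: ArrayLike, v: ArrayLike) -> Tuple[ArrayLike, ArrayLike]:
    """Change of variables to hawk fraction s = u/(u+v) and total density q = u+v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    total = u + v
    if np.any(total <= 0):
        raise ValueError("frequency transform requires u + v > 0")
    s = u / total
    if np.ndim(s) == 0:
        return float(s), float(total)
    return s, total


@dataclass(frozen=True)
class GameEquilibrium:
    """Interior coexistence fixed point of the reaction dynamics."""

    u0: float
    v0: float
    s0: float
    q0: float
    kappa: float


def coexistence_equilibrium(matrix: PayoffMatrix, kappa: float) -> GameEquilibrium:
    """Coexistence equilibrium of the payoff-plus-logistic reaction dynamics.

    In general-matrix form::

        u0 = (T-R)(ST-RP) / (kappa*(S+T-R-P)^2)
        v0 = (S-P)(ST-RP) / (kappa*(S+T-R-P)^2)

    which for the resource-contest matrix reduces to
    u0 = (C-V)V^2/(2*kappa*C^2), v0 = V(C-V)^2/(2*kappa*C^2).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    matrix.require_hawk_dove()
    T, R, S, P = matrix.T, matrix.R, matrix.S, matrix.P
    denom = S + T - R - P
    u0 = (T - R) * (S * T - R * P) / (kappa * denom**2)
    v0 = (S - P) * (S * T - R * P) / (kappa * denom**2)
    if u0 <= 0 or v0 <= 0:
        raise ValueError("payoff matrix does not support a positive coexistence equilibrium")
    q0 = u0 + v0
    return GameEquilibrium(u0=u0, v0=v0, s0=u0 / q0, q0=q0, kappa=kappa)


@dataclass(frozen=True)
class ReactionJacobian:
    """Partial derivatives of the reaction terms at the coexistence equilibrium."""

    a1: float
    a2: float
    b1: float
    b2: float

    @property
    def trace(self) -> float:
        return self.a1 + self.b2

    @property
    def det(self) -> float:
        return self.a1 * self.b2 - self.a2 * self.b1

    def is_stable(self) -> bool:
        return self.trace < 0 and self.det > 0

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.a1, self.a2], [self.b1, self.b2]])


def payoff_partials(
    matrix: PayoffMatrix, u: float, v: float
) -> Tuple[float, float, float, float]:
    """(dp_H/du, dp_H/dv, dp_D/du, dp_D/dv) at the point (u, v).

    Payoffs depend on (u, v) only through the hawk fraction, so the
    partials carry a factor v/(u+v)^2 or u/(u+v)^2.
    """
    q = u + v
    if q <= 0:
        raise ValueError("payoff partials require u + v > 0")
    T, R, S, P = matrix.T, matrix.R, matrix.S, matrix.P
    dph_du = (P - T) * v / q**2
    dph_dv = (T - P) * u / q**2
    dpd_du = (S - R) * v / q**2
    dpd_dv = (R - S) * u / q**2
    return dph_du, dph_dv, dpd_du, dpd_dv


def reaction_jacobian(matrix: PayoffMatrix, kappa: float) -> ReactionJacobian:
    """Analytic Jacobian of the reaction dynamics at the coexistence equilibrium.

    Computed from the exact partial derivatives of u*(p_H - kappa*(u+v)) and
    v*(p_D - kappa*(u+v)); at the equilibrium the per-capita rates vanish
    (p = kappa*q0), leaving

        a1 = -kappa*u0 + u0 * dp_H/du,   a2 = u0 * (dp_H/dv - kappa),
        b1 = v0 * (dp_D/du - kappa),     b2 = -kappa*v0 + v0 * dp_D/dv.

    For the resource-contest game the entries are independent of kappa and
    the dove diagonal entry b2 is positive iff C < 2V (doves act as the
    activator, hawks as the inhibitor, only below that cost).
    """
    eq = coexistence_equilibrium(matrix, kappa)
    u0, v0 = eq.u0, eq.v0
    dph_du, dph_dv, dpd_du, dpd_dv = payoff_partials(matrix, u0, v0)
    a1 = -kappa * u0 + u0 * dph_du
    a2 = u0 * (dph_dv - kappa)
    b1 = v0 * (dpd_du - kappa)
    b2 = -kappa * v0 + v0 * dpd_dv
    return ReactionJacobian(a1=a1, a2=a2, b1=b1, b2=b2)
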