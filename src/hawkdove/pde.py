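"""Local cross-diffusion PDE for payoff-driven motion, and its
reaction-diffusion limit.

The continuum model advects each strategy up the gradient of its own payoff
in addition to plain diffusion::

    u_t = -(J_u)_x + u*(p_H - kappa*(u+v)),
    J_u  = -D_u u_x + 2 D_u w_u u g_u(w_u p_H) dp_H/dx,

with ``g = f'/f`` of the movement-weight family (identically 1 for the
exponential rule, ``1/(1+w p)`` for the affine rule), and analogously for
doves with (D_v, w_v, p_D).  Setting w_u = w_v = 0 recovers the plain
reaction-diffusion system.

Discretization is a conservative finite-volume scheme: densities live at
cell centers, fluxes at cell faces (central averages; optional upwinding of
the taxis term), zero flux imposed at the domain ends.  Time stepping is
scipy's BDF with an analytic Jacobian sparsity pattern, so stiff
diffusivity ratios are handled implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .game import PayoffMatrix, GameEquilibrium, payoffs

__all__ = [
    "Grid1D",
    "FieldPair",
    "LocalPDEParams",
    "payoff_fields",
    "flux_rhs",
    "perturbed_ic",
    "integrate",
    "PDEResult",
]


@dataclass(frozen=True)
class Grid1D:
    """Uniform finite-volume grid on [0, length] with cell-center coordinates."""

    length: float
    n: int
    boundary: str = "zero-flux"

    def __post_init__(self):
        if self.n < 16:
            raise ValueError("grid needs at least 16 cells")
        if self.length <= 0:
            raise ValueError("domain length must be positive")
        if self.boundary not in ("zero-flux", "periodic"):
            raise ValueError("boundary must be 'zero-flux' or 'periodic'")

    @property
    def dx(self) -> float:
        return self.length / self.n

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.dx


@dataclass
class FieldPair:
    """Hawk/dove density profiles at cell centers."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be 1-D arrays of equal length")


@dataclass(frozen=True)
class LocalPDEParams:
    matrix: PayoffMatrix
    kappa: float
    D_u: float
    D_v: float
    w_u: float = 0.0
    w_v: float = 0.0
    rule: str = "exponential"
    reaction: bool = True  # test hook: pure transport when False
    upwind: bool = False

    def __post_init__(self):
        if self.D_u < 0 or self.D_v < 0:
            raise ValueError("diffusivities must be nonnegative")
        if self.rule not in ("exponential", "affine"):
            raise ValueError("rule must be 'exponential' or 'affine'")


def payoff_fields(fields: FieldPair, matrix: PayoffMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise payoff profiles (p_H(x), p_D(x)) with the empty-point convention."""
    return payoffs(fields.u, fields.v, matrix)


def _log_weight_slope(rule: str, w: float, p: np.ndarray) -> np.ndarray:
    """g = f'/f evaluated at w*p (the chemotactic sensitivity factor)."""
    if rule == "exponential":
        return np.ones_like(p)
    denom = 1.0 + w * p
    if np.any(denom <= 0):
        raise ValueError("affine movement weight 1 + w*p is nonpositive somewhere on the profile")
    return 1.0 / denom


def _species_flux(dens, p, D, w, rule, dx, upwind):
    """Face fluxes (length n-1, interior faces) for one strategy on a
    zero-flux grid; boundary faces carry zero flux and are added by caller."""
    diff = -D * np.diff(dens) / dx
    if w == 0.0 or D == 0.0:
        return diff
    p_face = 0.5 * (p[:-1] + p[1:])
    g_face = _log_weight_slope(rule, w, p_face)
    vel = 2.0 * D * w * g_face * np.diff(p) / dx
    if upwind:
        dens_face = np.where(vel > 0, dens[:-1], dens[1:])
    else:
        dens_face = 0.5 * (dens[:-1] + dens[1:])
    return diff + vel * dens_face


def flux_rhs(
    fields: FieldPair, params: LocalPDEParams, grid: Grid1D
) -> Tuple[np.ndarray, np.ndarray]:
    """Semi-discrete time derivatives (du/dt, dv/dt) on the zero-flux grid."""
    if grid.boundary != "zero-flux":
        raise ValueError("the local model uses the zero-flux grid; see nonlocal_pde for periodic")
    u, v = fields.u, fields.v
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise FloatingPointError("non-finite density encountered (blowup)")
    m, dx = params.matrix, grid.dx
    p_h, p_d = payoffs(np.maximum(u, 0.0), np.maximum(v, 0.0), m)
    ju = np.zeros(grid.n + 1)
    jv = np.zeros(grid.n + 1)
    ju[1:-1] = _species_flux(u, p_h, params.D_u, params.w_u, params.rule, dx, params.upwind)
    jv[1:-1] = _species_flux(v, p_d, params.D_v, params.w_v, params.rule, dx, params.upwind)
    dudt = -np.diff(ju) / dx
    dvdt = -np.diff(jv) / dx
    if params.reaction:
        dudt = dudt + u * (p_h - params.kappa * (u + v))
        dvdt = dvdt + v * (p_d - params.kappa * (u + v))
    return dudt, dvdt


def perturbed_ic(
    eq: GameEquilibrium,
    grid: Grid1D,
    seed: Optional[int] = None,
    amplitudes: Tuple[float, float] = (2.0, 1.0),
) -> FieldPair:
    """Uniform coexistence state plus i.i.d. uniform noise per grid point:
    u = u0 + a_u * U(x_i), v = v0 + a_v * V(x_i) with U, V ~ Uniform(-1, 1)."""
    rng = np.random.default_rng(seed)
    a_u, a_v = amplitudes
    u = eq.u0 + a_u * rng.uniform(-1.0, 1.0, size=grid.n)
    v = eq.v0 + a_v * rng.uniform(-1.0, 1.0, size=grid.n)
    return FieldPair(u=u, v=v)


def cosine_mode_ic(
    eq: GameEquilibrium, grid: Grid1D, m: int, amplitude: Tuple[float, float]
) -> FieldPair:
    """Single cosine-mode perturbation cos(m*pi*x/l) (zero-flux basis); used
    for dispersion measurements against the linear theory."""
    profile = np.cos(m * np.pi * grid.x / grid.length)
    return FieldPair(u=eq.u0 + amplitude[0] * profile, v=eq.v0 + amplitude[1] * profile)


@dataclass
class PDEResult:
    times: np.ndarray
    u: np.ndarray  # (n_times, n_cells)
    v: np.ndarray
    status: str  # completed | steady | blowup | negative
    message: str
    grid: Grid1D

    @property
    def final(self) -> FieldPair:
        return FieldPair(u=self.u[-1], v=self.v[-1], t=float(self.times[-1]))


def _local_sparsity(n: int) -> sparse.csr_matrix:
    band = sparse.diags([np.ones(n - 1), np.ones(n), np.ones(n - 1)], [-1, 0, 1])
    return sparse.bmat([[band, band], [band, band]], format="csr")


def _run_solver(
    rhs_fun: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    t_end: float,
    sparsity,
    rtol: float,
    atol: float,
    n_snapshots: int,
    steady_tol: Optional[float],
    max_density: float,
    negativity_tol: float,
):
    """Shared driver for both PDE models: BDF stepping with terminal events
    for steady state, blowup, and negativity."""

    def steady(t, y):
        if t == 0.0:
            return 1.0
        return float(np.max(np.abs(rhs_fun(t, y)))) - steady_tol

    steady.terminal = True
    steady.direction = -1

    def blowup(t, y):
        return max_density - float(np.max(np.abs(y)))

    blowup.terminal = True
    blowup.direction = -1

    def negative(t, y):
        return float(np.min(y)) + negativity_tol

    negative.terminal = True
    negative.direction = -1

    events = [blowup, negative]
    if steady_tol is not None:
        events.append(steady)
    t_eval = np.linspace(0.0, t_end, n_snapshots)
    try:
        sol = solve_ivp(
            rhs_fun, (0.0, t_end), y0, method="BDF", t_eval=t_eval,
            jac_sparsity=sparsity, rtol=rtol, atol=atol, events=events,
        )
    except FloatingPointError as exc:
        raise FloatingPointError(f"PDE solution blew up: {exc}") from exc

    times = sol.t
    ys = sol.y.T
    status, message = "completed", sol.message
    if sol.status == 1:  # a terminal event fired
        fired = [k for k, te in enumerate(sol.t_events) if te.size > 0]
        k = fired[0]
        t_ev = sol.t_events[k][0]
        y_ev = sol.y_events[k][0]
        times = np.append(times, t_ev)
        ys = np.vstack([ys, y_ev])
        if events[k] is blowup:
            j = int(np.argmax(np.abs(y_ev)))
            status, message = "blowup", f"density magnitude exceeded {max_density:g} at t={t_ev:.6g} (dof {j})"
        elif events[k] is negative:
            j = int(np.argmin(y_ev))
            status, message = "negative", f"density fell below -{negativity_tol:g} at t={t_ev:.6g} (dof {j})"
        else:
            status, message = "steady", f"steady state (|rhs|_inf < {steady_tol:g}) at t={t_ev:.6g}"
    elif sol.status != 0:
        status, message = "blowup", f"integrator failed: {sol.message}"
    return times, ys, status, message


def integrate(
    ic: FieldPair,
    params: LocalPDEParams,
    grid: Grid1D,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_snapshots: int = 41,
    steady_tol: Optional[float] = 1e-9,
    max_density: float = 1e8,
) -> PDEResult:
    """Advance the local model to ``t_end`` (deterministic given ``ic``).

    Terminates early and reports status 'steady' once the right-hand side's
    sup norm drops below ``steady_tol``; 'blowup'/'negative' statuses surface
    the short-wave-unstable or under-resolved regimes instead of silently
    clipping (negativity threshold is 10*atol).
    """
    n = grid.n

    def rhs_fun(t, y):
        fields = FieldPair(u=y[:n], v=y[n:])
        du, dv = flux_rhs(fields, params, grid)
        return np.concatenate([du, dv])

    y0 = np.concatenate([ic.u, ic.v])
    times, ys, status, message = _run_solver(
        rhs_fun, y0, t_end, _local_sparsity(n), rtol, atol,
        n_snapshots, steady_tol, max_density, 10.0 * atol,
    )
    return PDEResult(
        times=times, u=ys[:, :n], v=ys[:, n:], status=status, message=message, grid=grid
    )
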