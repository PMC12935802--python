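"""Nonlocal payoff-gradient model on a periodic domain.

Instead of the local payoff slope, each strategy senses the centered
difference of its log movement weight across a sensing radius ``rho``::

    drift_u(x) = (1/2 rho) * [ log f_u(w_u p_H(x+rho)) - log f_u(w_u p_H(x-rho)) ],
    u_t = D_u u_xx - 2 D_u (u * drift_u)_x + u*(p_H - kappa*(u+v)),

with periodic wraparound (doves analogous).  For the exponential weight the
log collapses to ``w p`` itself.  The finite sampling interval caps the
growth of high wavenumbers, which is what restores a finite unstable band
where the local model is short-wave unstable.

``rho`` must be an integer number of grid cells so that x +/- rho are grid
points; the evaluation is then exact (no interpolation) and the discrete
dispersion matches the analytic B(m) factor sin(2 m pi rho / l)/rho.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import sparse

from .game import GameEquilibrium, payoffs
from .pde import FieldPair, Grid1D, LocalPDEParams, PDEResult, _run_solver

__all__ = ["NonlocalParams", "nonlocal_rhs", "integrate_periodic", "periodic_mode_ic"]


@dataclass(frozen=True)
class NonlocalParams(LocalPDEParams):
    rho: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        if self.rho <= 0:
            raise ValueError("sensing radius rho must be positive")


def _shift_cells(params: NonlocalParams, grid: Grid1D) -> int:
    s = params.rho / grid.dx
    s_int = int(round(s))
    if abs(s - s_int) > 1e-9 or s_int < 1:
        raise ValueError(
            f"rho={params.rho} is not a positive integer multiple of dx={grid.dx}; "
            "choose rho = k*dx so the shifted payoffs fall on grid points"
        )
    if params.rho >= grid.length / 2:
        raise ValueError("rho must be smaller than half the domain length")
    return s_int


def _log_weight(rule: str, w: float, p: np.ndarray) -> np.ndarray:
    if rule == "exponential":
        return w * p
    arg = 1.0 + w * p
    if np.any(arg <= 0):
        raise ValueError("affine movement weight 1 + w*p is nonpositive somewhere on the profile")
    return np.log(arg)


def nonlocal_rhs(
    fields: FieldPair, params: NonlocalParams, grid: Grid1D
) -> Tuple[np.ndarray, np.ndarray]:
    """Semi-discrete time derivatives for the nonlocal model (periodic grid).

    Conservative form: the taxis flux 2*D*u*drift is evaluated on cell faces
    from center averages, the sensing difference uses exact grid shifts.
    """
    if grid.boundary != "periodic":
        raise ValueError("the nonlocal model requires a periodic grid")
    s = _shift_cells(params, grid)
    u, v = fields.u, fields.v
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise FloatingPointError("non-finite density encountered (blowup)")
    m, dx = params.matrix, grid.dx
    p_h, p_d = payoffs(np.maximum(u, 0.0), np.maximum(v, 0.0), m)

    def species_rhs(dens, p, D, w):
        # face j sits between cells j-1 and j (cell 0's left face wraps)
        diff_flux = -D * (dens - np.roll(dens, 1)) / dx
        if w != 0.0 and D != 0.0:
            lw = _log_weight(params.rule, w, p)
            drift_c = (np.roll(lw, -s) - np.roll(lw, s)) / (2.0 * params.rho)
            drift_f = 0.5 * (drift_c + np.roll(drift_c, 1))
            dens_f = 0.5 * (dens + np.roll(dens, 1))
            flux = diff_flux + 2.0 * D * dens_f * drift_f
        else:
            flux = diff_flux
        return -(np.roll(flux, -1) - flux) / dx

    dudt = species_rhs(u, p_h, params.D_u, params.w_u)
    dvdt = species_rhs(v, p_d, params.D_v, params.w_v)
    if params.reaction:
        dudt = dudt + u * (p_h - params.kappa * (u + v))
        dvdt = dvdt + v * (p_d - params.kappa * (u + v))
    return dudt, dvdt


def periodic_mode_ic(
    eq: GameEquilibrium, grid: Grid1D, m: int, amplitude: Tuple[float, float]
) -> FieldPair:
    """Single periodic cosine mode cos(2*m*pi*x/l) around the equilibrium."""
    profile = np.cos(2.0 * m * np.pi * grid.x / grid.length)
    return FieldPair(u=eq.u0 + amplitude[0] * profile, v=eq.v0 + amplitude[1] * profile)


def _periodic_sparsity(n: int, s: int) -> sparse.csr_matrix:
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(dist, n - dist)
    block = sparse.csr_matrix(dist <= s + 1)
    return sparse.bmat([[block, block], [block, block]], format="csr")


def integrate_periodic(
    ic: FieldPair,
    params: NonlocalParams,
    grid: Grid1D,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_snapshots: int = 41,
    steady_tol: Optional[float] = 1e-9,
    max_density: float = 1e8,
) -> PDEResult:
    """Advance the nonlocal model to ``t_end``; same contract as
    :func:`hawkdove.pde.integrate` with periodic stencils throughout."""
    s = _shift_cells(params, grid)
    n = grid.n

    def rhs_fun(t, y):
        fields = FieldPair(u=y[:n], v=y[n:])
        du, dv = nonlocal_rhs(fields, params, grid)
        return np.concatenate([du, dv])

    y0 = np.concatenate([ic.u, ic.v])
    times, ys, status, message = _run_solver(
        rhs_fun, y0, t_end, _periodic_sparsity(n, s), rtol, atol,
        n_snapshots, steady_tol, max_density, 10.0 * atol,
    )
    return PDEResult(
        times=times, u=ys[:, :n], v=ys[:, n:], status=status, message=message, grid=grid
    )
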