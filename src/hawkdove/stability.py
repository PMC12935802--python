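"""Linear stability of the uniform coexistence state.

Perturbations about (u0, v0) with a cosine spatial profile evolve under a
2x2 linearization: ``A(m)`` for the local model on a zero-flux interval
(modes cos(m pi x / l)) and ``B(m)`` for the nonlocal model on a periodic
interval (modes cos(2 m pi x / l)).  The uniform state loses stability at
the smallest parameter where some mode has tr > 0 or det < 0.

Three mechanisms are distinguished:

* diffusion-driven (Turing) instability in the reaction-diffusion limit,
  requiring the dove (activator) self-activation b2 > 0 and a sufficient
  hawk/dove diffusivity ratio;
* payoff-driven instability in the local model, which opens either through
  the trace or through the determinant of A(m); when the quartic
  det(A) = alpha q^2 + beta q + gamma (q = (m pi / l)^2) has alpha < 0, or
  the trace's quadratic coefficient is positive, infinitely many wavenumbers
  destabilize at once (a biologically infeasible short-wave instability);
* the nonlocal model, whose sensing factor sin(2 m pi rho / l)/rho is
  bounded, so the unstable set is always finite.

Shortwave verdicts are certified from the asymptotic coefficient signs, not
from a finite mode scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .game import (
    PayoffMatrix,
    coexistence_equilibrium,
    payoff_partials,
    payoffs,
    reaction_jacobian,
)
from .pde import LocalPDEParams
from .nonlocal_pde import NonlocalParams

__all__ = [
    "SensitivityConstants",
    "DispersionPoint",
    "ThresholdSet",
    "InstabilityClass",
    "sensitivity_constants",
    "A_matrix",
    "A_rd_matrix",
    "dispersion_curve",
    "turing_cutoff_mc",
    "critical_Du",
    "critical_Du_min",
    "critical_diffusivity_ratio",
    "det_quadratic_coefficients",
    "payoff_thresholds",
    "integer_mode_det_onset",
    "classify_instability",
    "B_matrix",
    "nonlocal_band",
]


@dataclass(frozen=True)
class SensitivityConstants:
    """Log-weight payoff sensitivities at equilibrium:
    c = (f'/f)(w p*) * dp/d(u or v).  For the resource-contest game with the
    exponential rule: c1, c3 < 0 and c2, c4 > 0, independent of w."""

    c1: float
    c2: float
    c3: float
    c4: float


def sensitivity_constants(
    matrix: PayoffMatrix,
    kappa: float,
    rule: str = "exponential",
    w_u: float = 0.0,
    w_v: float = 0.0,
) -> SensitivityConstants:
    eq = coexistence_equilibrium(matrix, kappa)
    dph_du, dph_dv, dpd_du, dpd_dv = payoff_partials(matrix, eq.u0, eq.v0)
    if rule == "exponential":
        g_u = g_v = 1.0
    elif rule == "affine":
        p_h, p_d = payoffs(eq.u0, eq.v0, matrix)
        den_u = 1.0 + w_u * p_h
        den_v = 1.0 + w_v * p_d
        if den_u <= 0 or den_v <= 0:
            raise ValueError("affine weight 1 + w*p is nonpositive at the equilibrium payoffs")
        g_u, g_v = 1.0 / den_u, 1.0 / den_v
    else:
        raise ValueError("rule must be 'exponential' or 'affine'")
    return SensitivityConstants(
        c1=g_u * dph_du, c2=g_u * dph_dv, c3=g_v * dpd_du, c4=g_v * dpd_dv
    )


@dataclass(frozen=True)
class DispersionPoint:
    m: int
    q: float  # squared wavenumber entering the matrix
    matrix: np.ndarray
    trace: float
    det: float
    sigma: float  # max real part of the eigenvalues


def _dispersion_point(m: int, q: float, mat: np.ndarray) -> DispersionPoint:
    tr = mat[0, 0] + mat[1, 1]
    det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
    disc = tr * tr - 4.0 * det
    if disc >= 0:
        sigma = 0.5 * (tr + math.sqrt(disc))
    else:
        sigma = 0.5 * tr
    return DispersionPoint(m=m, q=q, matrix=mat, trace=tr, det=det, sigma=sigma)


def _linearization_pieces(params: LocalPDEParams):
    eq = coexistence_equilibrium(params.matrix, params.kappa)
    jac = reaction_jacobian(params.matrix, params.kappa)
    cs = sensitivity_constants(
        params.matrix, params.kappa, params.rule, params.w_u, params.w_v
    )
    return eq, jac, cs


def A_matrix(m: int, params: LocalPDEParams, length: float) -> DispersionPoint:
    """Linearization A(m) of the local model for the zero-flux cosine mode m:

        [a1 - D_u(1 - 2 w_u c1 u0) q,   a2 + 2 D_u w_u c2 u0 q]
        [b1 + 2 D_v w_v c3 v0 q,        b2 - D_v(1 - 2 w_v c4 v0) q]

    with q = (m pi / l)^2; at m = 0 this is the reaction Jacobian.
    """
    if m < 0:
        raise ValueError("mode index m must be nonnegative")
    eq, jac, cs = _linearization_pieces(params)
    q = (m * np.pi / length) ** 2
    mat = np.array(
        [
            [
                jac.a1 - params.D_u * (1.0 - 2.0 * params.w_u * cs.c1 * eq.u0) * q,
                jac.a2 + 2.0 * params.D_u * params.w_u * cs.c2 * eq.u0 * q,
            ],
            [
                jac.b1 + 2.0 * params.D_v * params.w_v * cs.c3 * eq.v0 * q,
                jac.b2 - params.D_v * (1.0 - 2.0 * params.w_v * cs.c4 * eq.v0) * q,
            ],
        ]
    )
    return _dispersion_point(m, q, mat)


def A_rd_matrix(m: int, params: LocalPDEParams, length: float) -> DispersionPoint:
    """Reaction-diffusion dispersion matrix (the w_u = w_v = 0 limit of A)."""
    return A_matrix(m, _strip_taxis(params), length)


def _strip_taxis(params: LocalPDEParams) -> LocalPDEParams:
    return LocalPDEParams(
        matrix=params.matrix, kappa=params.kappa, D_u=params.D_u, D_v=params.D_v,
        w_u=0.0, w_v=0.0, rule=params.rule,
    )


def dispersion_curve(
    params: LocalPDEParams, length: float, m_max: int
) -> List[DispersionPoint]:
    return [A_matrix(m, params, length) for m in range(m_max + 1)]


# ---------------------------------------------------------------------------
# Turing thresholds for the reaction-diffusion limit


def turing_cutoff_mc(
    params: LocalPDEParams, length: float
) -> Optional[float]:
    """Wavenumber cutoff m_c = (l/pi) sqrt(b2/D_v) below which Turing
    instability is feasible; None when b2 <= 0 (no Turing route) or D_v = 0."""
    jac = reaction_jacobian(params.matrix, params.kappa)
    if jac.b2 <= 0 or params.D_v <= 0:
        return None
    return (length / np.pi) * math.sqrt(jac.b2 / params.D_v)


def critical_Du(m: int, params: LocalPDEParams, length: float) -> float:
    """Per-mode critical hawk diffusivity: mode m destabilizes once D_u
    exceeds D_u*(m) = (a1 D_v q + b1 a2 - a1 b2) / (D_v q^2 - b2 q)."""
    mc = turing_cutoff_mc(params, length)
    if mc is None or not 0 < m < mc:
        raise ValueError(f"mode m={m} lies outside the feasible Turing range")
    jac = reaction_jacobian(params.matrix, params.kappa)
    q = (m * np.pi / length) ** 2
    num = jac.a1 * params.D_v * q + jac.b1 * jac.a2 - jac.a1 * jac.b2
    den = params.D_v * q**2 - jac.b2 * q
    return num / den


def critical_Du_min(
    params: LocalPDEParams, length: float
) -> Optional[Tuple[float, int]]:
    """(min over integer modes of D_u*(m), argmin m); None when no integer
    mode lies below the cutoff."""
    mc = turing_cutoff_mc(params, length)
    if mc is None or mc <= 1:
        return None
    ms = range(1, int(np.ceil(mc)))
    vals = [(critical_Du(m, params, length), m) for m in ms]
    best = min(vals)
    return best[0], best[1]


def critical_diffusivity_ratio(matrix: PayoffMatrix, kappa: float) -> Optional[float]:
    """Continuum marginal-stability ratio d* = D_u/D_v: the larger root of
    (a1 + d b2)^2 = 4 d (a1 b2 - a2 b1).  Above d* some continuum wavenumber
    has a negative determinant.  None when b2 <= 0 (no Turing route)."""
    jac = reaction_jacobian(matrix, kappa)
    if jac.b2 <= 0:
        return None
    # (b2 d + a1)^2 - 4 d det = b2^2 d^2 + (2 a1 b2 - 4 det) d + a1^2 = 0
    coeffs = [jac.b2**2, 2.0 * jac.a1 * jac.b2 - 4.0 * jac.det, jac.a1**2]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    if real.size == 0:
        return None
    return float(np.max(real))


# ---------------------------------------------------------------------------
# Payoff-driven thresholds (local model)


def det_quadratic_coefficients(
    params: LocalPDEParams,
) -> Tuple[float, float, float]:
    """Coefficients (alpha, beta, gamma) of det(A) = alpha q^2 + beta q + gamma
    as a polynomial in q = (m pi / l)^2."""
    eq, jac, cs = _linearization_pieces(params)
    e_u = params.D_u * (1.0 - 2.0 * params.w_u * cs.c1 * eq.u0)
    e_v = params.D_v * (1.0 - 2.0 * params.w_v * cs.c4 * eq.v0)
    f_u = 2.0 * params.D_u * params.w_u * cs.c2 * eq.u0
    f_v = 2.0 * params.D_v * params.w_v * cs.c3 * eq.v0
    alpha = e_u * e_v - f_u * f_v
    beta = -(jac.a1 * e_v + jac.b2 * e_u) - (jac.a2 * f_v + jac.b1 * f_u)
    gamma = jac.det
    return alpha, beta, gamma


def _trace_q_coefficient(params: LocalPDEParams) -> float:
    """Coefficient of q in tr(A(m)); a positive value opens the trace route
    at infinitely many wavenumbers."""
    eq, _, cs = _linearization_pieces(params)
    return (
        -(params.D_u + params.D_v)
        + 2.0 * params.D_u * params.w_u * cs.c1 * eq.u0
        + 2.0 * params.D_v * params.w_v * cs.c4 * eq.v0
    )


@dataclass(frozen=True)
class ThresholdSet:
    """Critical dove payoff sensitivities (and companions) for the local model.

    wv_I: trace route opens (shortwave); wv_II: alpha < 0, determinant
    negative at all large wavenumbers (shortwave); wv_IIIa: beta < 0;
    wv_IIIb: discriminant beta^2 - 4 alpha gamma >= 0 with beta < 0;
    wv_III = max(IIIa, IIIb): a finite unstable band requires
    wv_III < w_v < min(wv_I, wv_II).  wv_star is the onset: the smallest
    w_v at which any route opens, with its route label.
    Infinite thresholds mean the route never opens as w_v grows.
    """

    wv_I: float
    wv_II: float
    wv_IIIa: float
    wv_IIIb: float
    wv_III: float
    wv_star: float
    route: str  # 'trace_shortwave' | 'det_finite_band' | 'det_shortwave'


def _with_wv(params: LocalPDEParams, w_v: float) -> LocalPDEParams:
    return LocalPDEParams(
        matrix=params.matrix, kappa=params.kappa, D_u=params.D_u, D_v=params.D_v,
        w_u=params.w_u, w_v=w_v, rule=params.rule,
    )


def _affine_in_wv(fn, params) -> Tuple[float, float]:
    """(value at w_v=0, slope) of a quantity that is affine in w_v.

    Exact for the exponential rule, where the sensitivity constants do not
    depend on w_v (callers enforce that rule).
    """
    f0 = fn(_with_wv(params, 0.0))
    f1 = fn(_with_wv(params, 1.0))
    return f0, f1 - f0


def payoff_thresholds(params: LocalPDEParams) -> ThresholdSet:
    """Onset sensitivities of payoff-driven instability as w_v increases,
    holding (D_u, D_v, w_u) fixed (exponential movement rule).

    The determinant quartic's coefficients alpha and beta are affine in w_v
    and gamma is constant, so every threshold reduces to roots of linear or
    quadratic expressions: wv_I and wv_IIIa are linear roots, wv_II is the
    root of alpha(w_v) = 0, and wv_IIIb is the smallest w_v >= 0 where the
    discriminant beta^2 - 4 alpha gamma turns nonnegative while beta < 0.
    """
    if params.rule != "exponential":
        raise NotImplementedError(
            "threshold closed forms assume the exponential movement rule"
        )
    jac = reaction_jacobian(params.matrix, params.kappa)
    if not jac.is_stable():
        raise ValueError("reaction equilibrium is not ODE-stable; thresholds undefined")

    inf = float("inf")

    t0, t1 = _affine_in_wv(_trace_q_coefficient, params)
    wv_i = -t0 / t1 if t1 > 0 else inf

    def _alpha(p):
        return det_quadratic_coefficients(p)[0]

    def _beta(p):
        return det_quadratic_coefficients(p)[1]

    a0, a1_ = _affine_in_wv(_alpha, params)
    wv_ii = -a0 / a1_ if a1_ < 0 else inf

    b0, b1_ = _affine_in_wv(_beta, params)
    if b1_ < 0:
        wv_iiia = -b0 / b1_
    elif b0 < 0:
        wv_iiia = -inf  # beta < 0 for every w_v >= 0
    else:
        wv_iiia = inf
    gamma = jac.det

    # discriminant D(w) = (b0 + b1 w)^2 - 4 gamma (a0 + a1 w), quadratic in w
    dd = np.array([b1_**2, 2.0 * b0 * b1_ - 4.0 * gamma * a1_, b0**2 - 4.0 * gamma * a0])
    roots = np.roots(dd)
    real_roots = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-9)

    def disc(w):
        return (b0 + b1_ * w) ** 2 - 4.0 * gamma * (a0 + a1_ * w)

    def beta_at(w):
        return b0 + b1_ * w

    candidates = sorted({0.0, max(0.0, wv_iiia if np.isfinite(wv_iiia) else 0.0), *[r for r in real_roots if r >= 0]})
    wv_iiib = inf
    epsilon = 1e-12
    for w in candidates:
        probe = w + epsilon
        if beta_at(probe) < 0 and disc(probe) >= -1e-9 * max(1.0, abs(gamma)):
            wv_iiib = w
            break
    wv_iii = max(wv_iiia, wv_iiib)

    det_onset = wv_iii if wv_iii < wv_ii else wv_ii
    det_route = "det_finite_band" if wv_iii < wv_ii else "det_shortwave"
    if wv_i <= det_onset:
        wv_star, route = wv_i, "trace_shortwave"
    else:
        wv_star, route = det_onset, det_route
    return ThresholdSet(
        wv_I=wv_i, wv_II=wv_ii, wv_IIIa=wv_iiia, wv_IIIb=wv_iiib,
        wv_III=wv_iii, wv_star=wv_star, route=route,
    )


def integer_mode_det_onset(
    params: LocalPDEParams, length: float, m_max: int = 200
) -> Optional[Tuple[float, int]]:
    """(w_v, m) at which the first integer zero-flux mode's determinant
    crosses zero as w_v grows.

    The continuum onset (wv_IIIb in :func:`payoff_thresholds`) is the
    infimum over real wavenumbers; on a finite interval only integer modes
    exist, so the observable onset is this slightly larger value.  det(A(m))
    is affine in w_v at fixed m (exponential rule), giving a closed-form
    root per mode.  None when no mode destabilizes through the determinant.
    """
    if params.rule != "exponential":
        raise NotImplementedError("integer-mode onset assumes the exponential rule")
    a0, b0, gamma = det_quadratic_coefficients(_with_wv(params, 0.0))
    a1, b1, _ = det_quadratic_coefficients(_with_wv(params, 1.0))
    slope_a, slope_b = a1 - a0, b1 - b0
    best = None
    for m in range(1, m_max + 1):
        q = (m * np.pi / length) ** 2
        den = slope_a * q**2 + slope_b * q
        if den >= 0:
            continue  # this mode's determinant does not decrease with w_v
        w = -(a0 * q**2 + b0 * q + gamma) / den
        if w > 0 and (best is None or w < best[0]):
            best = (w, m)
    return best


# ---------------------------------------------------------------------------
# Mode classification


@dataclass(frozen=True)
class InstabilityClass:
    label: str  # 'stable' | 'finite_band' | 'shortwave_trace' | 'shortwave_det'
    unstable_modes: Tuple[int, ...]
    fastest_mode: Optional[int]
    unbounded: bool


def classify_instability(
    params: LocalPDEParams, length: float, m_scan: int = 400
) -> InstabilityClass:
    """Classify the unstable mode set of the local model.

    Shortwave verdicts come from the asymptotic coefficients (trace slope in
    q, quartic coefficient alpha), never from the scan alone; when both
    asymptotics are stabilizing, the scan range is extended to cover the
    analytic root bound of the determinant quadratic, so a reported finite
    band is complete.
    """
    alpha, beta, gamma = det_quadratic_coefficients(params)
    tq = _trace_q_coefficient(params)
    shortwave = None
    if tq > 0:
        shortwave = "shortwave_trace"
    elif alpha < 0:
        shortwave = "shortwave_det"

    m_hi = m_scan
    if shortwave is None and alpha > 0:
        disc = beta**2 - 4.0 * alpha * gamma
        if disc > 0:
            q_hi = (-beta + math.sqrt(disc)) / (2.0 * alpha)
            if q_hi > 0:
                m_hi = max(m_hi, int(np.ceil(length / np.pi * math.sqrt(q_hi))) + 2)

    pts = [A_matrix(m, params, length) for m in range(1, m_hi + 1)]
    unstable = [p.m for p in pts if p.trace > 0 or p.det < 0]
    fastest = max(pts, key=lambda p: p.sigma)
    fastest_mode = fastest.m if fastest.sigma > 0 else None
    if shortwave is not None:
        return InstabilityClass(
            label=shortwave, unstable_modes=tuple(unstable),
            fastest_mode=fastest_mode, unbounded=True,
        )
    if unstable:
        return InstabilityClass(
            label="finite_band", unstable_modes=tuple(unstable),
            fastest_mode=fastest_mode, unbounded=False,
        )
    return InstabilityClass(label="stable", unstable_modes=(), fastest_mode=None, unbounded=False)


# ---------------------------------------------------------------------------
# Nonlocal dispersion


def B_matrix(m: int, params: NonlocalParams, length: float) -> DispersionPoint:
    """Linearization B(m) of the nonlocal model for the periodic mode
    cos(2 m pi x / l); the sensing radius enters through the bounded factor
    sin(2 m pi rho / l)/rho, which caps high-wavenumber taxis."""
    if m < 0:
        raise ValueError("mode index m must be nonnegative")
    eq, jac, cs = _linearization_pieces(params)
    k = 2.0 * m * np.pi / length
    if k == 0.0:
        return _dispersion_point(m, 0.0, jac.as_matrix())
    h = math.sin(k * params.rho) / params.rho
    mat = np.array(
        [
            [
                jac.a1 - params.D_u * k**2 + 2.0 * k * params.D_u * params.w_u * eq.u0 * cs.c1 * h,
                jac.a2 + 2.0 * k * params.D_u * params.w_u * eq.u0 * cs.c2 * h,
            ],
            [
                jac.b1 + 2.0 * k * params.D_v * params.w_v * eq.v0 * cs.c3 * h,
                jac.b2 - params.D_v * k**2 + 2.0 * k * params.D_v * params.w_v * eq.v0 * cs.c4 * h,
            ],
        ]
    )
    return _dispersion_point(m, k**2, mat)


def _nonlocal_mode_bound(params: NonlocalParams, length: float) -> int:
    """Integer M beyond which tr(B) < 0 and det(B) > 0 are certified by the
    asymptotic coefficients: the quartic term D_u D_v k^4 dominates because
    |sin(k rho)/rho| <= 1/rho is bounded."""
    eq, jac, cs = _linearization_pieces(params)
    r = 1.0 / params.rho
    tu1 = abs(2.0 * params.D_u * params.w_u * eq.u0 * cs.c1)
    tu2 = abs(2.0 * params.D_u * params.w_u * eq.u0 * cs.c2)
    tv3 = abs(2.0 * params.D_v * params.w_v * eq.v0 * cs.c3)
    tv4 = abs(2.0 * params.D_v * params.w_v * eq.v0 * cs.c4)
    du, dv = params.D_u, params.D_v
    if du <= 0 or dv <= 0:
        raise ValueError("nonlocal band certification requires positive diffusivities")
    # trace <= -(du+dv) k^2 + (tu1+tv4) r k + |a1+b2| -> root bound
    k_tr = np.max(np.roots([du + dv, -(tu1 + tv4) * r, -abs(jac.a1 + jac.b2)]).real)
    # det >= du*dv k^4 - (du*tv4 + dv*tu1) r k^3
    #        - (|a1| dv + |b2| du + (tu1*tv4 + tu2*tv3) r^2) k^2
    #        - (|a1| tv4 + |b2| tu1 + |a2| tv3 + |b1| tu2) r k
    #        - (|a1 b2| + |a2 b1|)
    poly = [
        du * dv,
        -(du * tv4 + dv * tu1) * r,
        -(abs(jac.a1) * dv + abs(jac.b2) * du + (tu1 * tv4 + tu2 * tv3) * r**2),
        -(abs(jac.a1) * tv4 + abs(jac.b2) * tu1 + abs(jac.a2) * tv3 + abs(jac.b1) * tu2) * r,
        -(abs(jac.a1 * jac.b2) + abs(jac.a2 * jac.b1)),
    ]
    roots = np.roots(poly)
    k_det = max(float(rt.real) for rt in roots if abs(rt.imag) < 1e-9)
    k_star = max(k_tr, k_det, 0.0)
    return int(np.ceil(k_star * length / (2.0 * np.pi))) + 1


def nonlocal_band(
    params: NonlocalParams, length: float, m_max: Optional[int] = None
) -> InstabilityClass:
    """Scan integer periodic modes for instability; the scan range covers the
    certified bound, so the returned band is provably complete (never
    unbounded for positive diffusivities)."""
    bound = _nonlocal_mode_bound(params, length)
    m_hi = max(bound, m_max or 0)
    unstable = []
    fastest = (None, 0.0)
    for m in range(1, m_hi + 1):
        p = B_matrix(m, params, length)
        if p.trace > 0 or p.det < 0:
            unstable.append(m)
            if p.sigma > fastest[1]:
                fastest = (m, p.sigma)
    if unstable:
        return InstabilityClass(
            label="finite_band", unstable_modes=tuple(unstable),
            fastest_mode=fastest[0], unbounded=False,
        )
    return InstabilityClass(label="stable", unstable_modes=(), fastest_mode=None, unbounded=False)
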