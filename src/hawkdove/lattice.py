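"""Stochastic metapopulation lattice with payoff-driven demography and movement.

Hawks and doves live as integer counts on a 1-D chain of ``N`` patches with
nearest-neighbor coupling and no wraparound.  Within a patch, a positive mean
payoff acts as a per-capita birth rate and a negative one as a per-capita
death rate; a crowding death rate ``kappa * n_i * (u_i + v_i)`` regulates the
total patch density.  Individuals hop to a neighboring patch at total
per-capita rate ``mu``, choosing the destination with probability
proportional to an increasing weight ``f(w * p)`` of that strategy's payoff
there (affine ``1 + w p`` or exponential ``exp(w p)``).  Boundary patches
normalize over their single neighbor, which therefore receives the full
per-capita movement rate (zero-flux lattice).

Event timing is an exact continuous-time Gillespie direct method (see
``_kernel``); no tau-leaping or other approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _kernel
from .game import PayoffMatrix, GameEquilibrium, coexistence_equilibrium, payoffs

__all__ = [
    "MovementRule",
    "LatticeState",
    "StochasticConfig",
    "DemographicRates",
    "demographic_rates",
    "movement_rates",
    "gillespie_step",
    "initial_condition",
    "simulate",
    "ReplicateResult",
    "EnsembleSummary",
    "SimulationResult",
]

_RULE_CODES = {"exponential": _kernel.RULE_EXPONENTIAL, "affine": _kernel.RULE_AFFINE}


@dataclass(frozen=True)
class MovementRule:
    """Biased-random-walk movement: per-capita rates mu_u / mu_v, payoff
    sensitivities w_u / w_v, and the weight family ('exponential' or 'affine')."""

    kind: str = "exponential"
    mu_u: float = 0.0
    mu_v: float = 0.0
    w_u: float = 0.0
    w_v: float = 0.0

    def __post_init__(self):
        if self.kind not in _RULE_CODES:
            raise ValueError(f"unknown movement rule {self.kind!r}; use 'exponential' or 'affine'")
        if self.mu_u < 0 or self.mu_v < 0:
            raise ValueError("movement rates must be nonnegative")

    @property
    def code(self) -> int:
        return _RULE_CODES[self.kind]


@dataclass
class LatticeState:
    """Integer hawk/dove counts per patch plus the simulation clock."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.int64)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be 1-D arrays of equal length")
        if np.any(self.u < 0) or np.any(self.v < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_patches(self) -> int:
        return self.u.shape[0]


@dataclass(frozen=True)
class StochasticConfig:
    matrix: PayoffMatrix
    kappa: float
    movement: MovementRule
    n_patches: int = 100
    t_end: float = 100.0
    snapshot_dt: float = 0.5
    window_fraction: float = 0.05
    n_replicates: int = 1
    seed: int = 0
    ic_noise: int = 5

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class DemographicRates:
    birth_u: float
    payoff_death_u: float
    crowding_death_u: float
    birth_v: float
    payoff_death_v: float
    crowding_death_v: float


def demographic_rates(
    state: LatticeState, i: int, matrix: PayoffMatrix, kappa: float
) -> DemographicRates:
    """Birth/death propensities at patch ``i``.

    The sign of the patch payoff decides birth versus death: rate
    ``u_i * max(p_H, 0)`` for hawk births, ``u_i * max(-p_H, 0)`` for hawk
    payoff deaths, plus the crowding death rate ``kappa*u_i*(u_i+v_i)``;
    doves analogous.
    """
    out = np.empty(_kernel.N_SLOTS)
    _kernel.patch_rates(
        state.u, state.v, i, matrix.T, matrix.R, matrix.S, matrix.P,
        kappa, 0.0, 0.0, 0.0, 0.0, _kernel.RULE_EXPONENTIAL, out,
    )
    return DemographicRates(*out[:6])


def movement_rates(
    state: LatticeState, i: int, rule: MovementRule, matrix: PayoffMatrix
) -> dict:
    """Total movement rates out of patch ``i`` keyed by
    ('u'|'v', neighbor index).  Weights normalize over the patch's existing
    neighbors, so the per-patch totals are always ``u_i*mu_u`` and ``v_i*mu_v``.
    """
    out = np.empty(_kernel.N_SLOTS)
    ok = _kernel.patch_rates(
        state.u, state.v, i, matrix.T, matrix.R, matrix.S, matrix.P,
        0.0, rule.mu_u, rule.mu_v, rule.w_u, rule.w_v, rule.code, out,
    )
    if not ok:
        raise ValueError(
            f"affine movement weight is nonpositive in the neighborhood of patch {i}; "
            "reduce |w| or use the exponential rule"
        )
    rates = {}
    if i > 0:
        rates[("u", i - 1)] = out[6]
        rates[("v", i - 1)] = out[8]
    if i < state.n_patches - 1:
        rates[("u", i + 1)] = out[7]
        rates[("v", i + 1)] = out[9]
    return rates


_SLOT_NAMES = (
    "birth_u", "payoff_death_u", "crowding_death_u",
    "birth_v", "payoff_death_v", "crowding_death_v",
    "move_u_left", "move_u_right", "move_v_left", "move_v_right",
)


def _all_rates(state, matrix, kappa, rule) -> np.ndarray:
    n = state.n_patches
    rates = np.zeros((n, _kernel.N_SLOTS))
    for i in range(n):
        ok = _kernel.patch_rates(
            state.u, state.v, i, matrix.T, matrix.R, matrix.S, matrix.P,
            kappa, rule.mu_u, rule.mu_v, rule.w_u, rule.w_v, rule.code, rates[i],
        )
        if not ok:
            raise ValueError(f"affine movement weight nonpositive near patch {i}")
    return rates


def gillespie_step(
    state: LatticeState,
    matrix: PayoffMatrix,
    kappa: float,
    rule: MovementRule,
    rng: np.random.Generator,
) -> Optional[Tuple[str, int, float]]:
    """Advance the state by one exact event (in place).

    Returns (event name, patch index, dt), or None when the total rate is
    zero (absorbing, fully extinct state).  This reference stepper shares its
    propensity code with the compiled production loop.
    """
    rates = _all_rates(state, matrix, kappa, rule)
    lam = rates.sum()
    if lam <= 0:
        return None
    dt = rng.exponential(1.0 / lam)
    flat = rates.ravel()
    idx = rng.choice(flat.size, p=flat / lam)
    i, slot = divmod(idx, _kernel.N_SLOTS)
    if slot == 0:
        state.u[i] += 1
    elif slot in (1, 2):
        state.u[i] -= 1
    elif slot == 3:
        state.v[i] += 1
    elif slot in (4, 5):
        state.v[i] -= 1
    elif slot == 6:
        state.u[i] -= 1
        state.u[i - 1] += 1
    elif slot == 7:
        state.u[i] -= 1
        state.u[i + 1] += 1
    elif slot == 8:
        state.v[i] -= 1
        state.v[i - 1] += 1
    else:
        state.v[i] -= 1
        state.v[i + 1] += 1
    state.t += dt
    return _SLOT_NAMES[slot], int(i), float(dt)


def initial_condition(
    eq: GameEquilibrium, n_patches: int, rng: np.random.Generator, noise: int = 5
) -> LatticeState:
    """Rounded equilibrium counts plus independent integer-uniform noise on
    [-noise, noise] per patch (the standard perturbed start)."""
    u = int(round(eq.u0)) + rng.integers(-noise, noise + 1, size=n_patches)
    v = int(round(eq.v0)) + rng.integers(-noise, noise + 1, size=n_patches)
    return LatticeState(u=np.maximum(u, 0), v=np.maximum(v, 0))


@dataclass
class ReplicateResult:
    times: np.ndarray
    u: np.ndarray  # (n_snapshots, n_patches)
    v: np.ndarray
    seed: int
    extinct: bool
    t_stop: float
    event_counts: np.ndarray


@dataclass
class EnsembleSummary:
    """Window means per patch, averaged over non-extinct replicates."""

    mean_u: np.ndarray
    mean_v: np.ndarray
    mean_pH: np.ndarray
    mean_pD: np.ndarray
    window: Tuple[float, float]
    n_replicates: int
    n_excluded: int

    @property
    def spatial_mean_u(self) -> float:
        return float(np.mean(self.mean_u))

    @property
    def spatial_mean_v(self) -> float:
        return float(np.mean(self.mean_v))


@dataclass
class SimulationResult:
    config: StochasticConfig
    replicates: List[ReplicateResult]
    summary: EnsembleSummary


def _window_means(rep: ReplicateResult, matrix: PayoffMatrix, t_start: float):
    mask = rep.times >= t_start - 1e-9
    u_w = rep.u[mask].astype(float)
    v_w = rep.v[mask].astype(float)
    p_h, p_d = payoffs(u_w, v_w, matrix)
    return u_w.mean(axis=0), v_w.mean(axis=0), p_h.mean(axis=0), p_d.mean(axis=0)


def simulate(config: StochasticConfig) -> SimulationResult:
    """Run the replicate ensemble and summarize the final time window.

    Each replicate gets an independent seeded stream; fixed ``config.seed``
    gives bit-identical trajectories.  Per-patch means of counts and payoffs
    are taken over snapshots in the last ``window_fraction`` of the horizon;
    replicates that go extinct before the window opens are excluded from the
    ensemble means and reported in ``summary.n_excluded``.
    """
    eq = coexistence_equilibrium(config.matrix, config.kappa)
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_replicates
    ) % (2**31)
    m, rule = config.matrix, config.movement
    t_window = (1.0 - config.window_fraction) * config.t_end

    reps: List[ReplicateResult] = []
    for r in range(config.n_replicates):
        seed_r = int(child_seeds[r])
        rng = np.random.default_rng(seed_r)
        ic = initial_condition(eq, config.n_patches, rng, noise=config.ic_noise)
        snap_u, snap_v, times, counts, status, t_stop = _kernel.run_lattice(
            ic.u, ic.v, m.T, m.R, m.S, m.P, config.kappa,
            rule.mu_u, rule.mu_v, rule.w_u, rule.w_v, rule.code,
            config.t_end, config.snapshot_dt, seed_r,
        )
        if status == _kernel.STATUS_BAD_WEIGHT:
            raise ValueError(
                f"replicate {r}: affine movement weight became nonpositive at t={t_stop:.3g}"
            )
        reps.append(
            ReplicateResult(
                times=times, u=snap_u, v=snap_v, seed=seed_r,
                extinct=(status == _kernel.STATUS_EXTINCT), t_stop=t_stop,
                event_counts=counts,
            )
        )

    included = [rep for rep in reps if not (rep.extinct and rep.t_stop < t_window)]
    n_excluded = len(reps) - len(included)
    if not included:
        raise RuntimeError("all replicates went extinct before the averaging window")
    acc = [np.zeros(config.n_patches) for _ in range(4)]
    for rep in included:
        for a, x in zip(acc, _window_means(rep, m, t_window)):
            a += x
    mean_u, mean_v, mean_ph, mean_pd = (a / len(included) for a in acc)
    summary = EnsembleSummary(
        mean_u=mean_u, mean_v=mean_v, mean_pH=mean_ph, mean_pD=mean_pd,
        window=(t_window, config.t_end), n_replicates=len(reps),
        n_excluded=n_excluded,
    )
    return SimulationResult(config=config, replicates=reps, summary=summary)
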