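"""Named parameter regimes and YAML config plumbing.

All presets share the baseline game (V=4, C=6, kappa=1e-3) whose coexistence
state is (u0, v0) = (4000/9, 2000/9) with uniform payoff 2/3.  Each preset is
a complete nested config dict; builders turn the relevant sections into the
typed parameter objects used by the library.
"""

from __future__ import annotations

import copy
from typing import Dict

import yaml

from .game import PayoffMatrix, build_cv_matrix
from .lattice import MovementRule, StochasticConfig
from .pde import Grid1D, LocalPDEParams
from .nonlocal_pde import NonlocalParams

__all__ = [
    "PRESETS",
    "preset",
    "preset_names",
    "to_yaml",
    "from_yaml",
    "build_matrix",
    "build_stochastic_config",
    "build_local_params",
    "build_nonlocal_params",
    "build_grid",
]

_GAME = {"V": 4.0, "C": 6.0, "kappa": 0.001}

PRESETS: Dict[str, dict] = {
    # equal movement abilities: the well-mixed benchmark regime
    "demo-equal-motion": {
        "game": dict(_GAME),
        "abm": {
            "rule": "exponential", "mu_u": 2.0, "mu_v": 2.0, "w_u": 1.0, "w_v": 1.0,
            "n_patches": 100, "t_end": 100.0, "snapshot_dt": 0.5,
            "window_fraction": 0.05, "n_replicates": 1, "seed": 0,
        },
    },
    # purely diffusive lattice motion across the pattern-onset ratio
    "diffusive-sweep": {
        "game": dict(_GAME),
        "abm": {
            "rule": "exponential", "mu_u": 50.0, "mu_v": 0.2, "w_u": 0.0, "w_v": 0.0,
            "n_patches": 100, "t_end": 100.0, "snapshot_dt": 0.5,
            "window_fraction": 0.05, "n_replicates": 1, "seed": 0,
        },
    },
    # payoff-driven lattice motion, equal mobilities
    "payoff-driven-abm": {
        "game": dict(_GAME),
        "abm": {
            "rule": "exponential", "mu_u": 1.0, "mu_v": 1.0, "w_u": 0.1, "w_v": 20.0,
            "n_patches": 100, "t_end": 100.0, "snapshot_dt": 0.5,
            "window_fraction": 0.05, "n_replicates": 1, "seed": 0,
        },
    },
    # mixed-mechanism lattice regime (fast hawks, payoff-sensitive doves)
    "mixed-abm": {
        "game": dict(_GAME),
        "abm": {
            "rule": "exponential", "mu_u": 4.8, "mu_v": 0.1, "w_u": 0.1, "w_v": 40.0,
            "n_patches": 100, "t_end": 100.0, "snapshot_dt": 0.5,
            "window_fraction": 0.05, "n_replicates": 1, "seed": 0,
        },
    },
    # Turing threshold analysis of the reaction-diffusion limit
    "turing-thresholds": {
        "game": dict(_GAME),
        "domain": {"length": 40.0, "n": 400, "boundary": "zero-flux"},
        "pde": {"rule": "exponential", "D_u": 4.93, "D_v": 0.1, "w_u": 0.0, "w_v": 0.0},
    },
    # just-above-threshold Turing pattern (single unstable mode m=12)
    "turing-pattern": {
        "game": dict(_GAME),
        "domain": {"length": 40.0, "n": 400, "boundary": "zero-flux"},
        "pde": {"rule": "exponential", "D_u": 4.93, "D_v": 0.1, "w_u": 0.0, "w_v": 0.0},
        "run": {"t_end": 40000.0, "seed": 0},
    },
    # sub-Turing diffusivities where the determinant route opens at w_v*=0.848
    "mixed-pde-onset": {
        "game": dict(_GAME),
        "domain": {"length": 40.0, "n": 400, "boundary": "zero-flux"},
        "pde": {"rule": "exponential", "D_u": 4.2, "D_v": 0.1, "w_u": 0.05, "w_v": 0.9},
    },
    # nonlocal sensing: equal diffusivities but a finite unstable band
    "nonlocal-band": {
        "game": dict(_GAME),
        "domain": {"length": 40.0, "n": 400, "boundary": "periodic"},
        "nonlocal": {
            "rule": "exponential", "D_u": 0.1, "D_v": 0.1,
            "w_u": 1.0, "w_v": 10.0, "rho": 0.01,
        },
    },
}


def preset_names():
    return sorted(PRESETS)


def preset(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    return copy.deepcopy(PRESETS[name])


def to_yaml(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


def from_yaml(text: str) -> dict:
    return yaml.safe_load(text)


def build_matrix(cfg: dict) -> PayoffMatrix:
    game = cfg["game"]
    if "V" in game:
        return build_cv_matrix(game["V"], game["C"])
    return PayoffMatrix(T=game["T"], R=game["R"], S=game["S"], P=game["P"])


def build_stochastic_config(cfg: dict, **overrides) -> StochasticConfig:
    abm = dict(cfg["abm"])
    abm.update(overrides)
    rule = MovementRule(
        kind=abm.pop("rule"), mu_u=abm.pop("mu_u"), mu_v=abm.pop("mu_v"),
        w_u=abm.pop("w_u"), w_v=abm.pop("w_v"),
    )
    return StochasticConfig(
        matrix=build_matrix(cfg), kappa=cfg["game"]["kappa"], movement=rule, **abm
    )


def build_grid(cfg: dict) -> Grid1D:
    d = cfg["domain"]
    return Grid1D(length=d["length"], n=d["n"], boundary=d.get("boundary", "zero-flux"))


def build_local_params(cfg: dict, **overrides) -> LocalPDEParams:
    p = dict(cfg["pde"])
    p.update(overrides)
    return LocalPDEParams(matrix=build_matrix(cfg), kappa=cfg["game"]["kappa"], **p)


def build_nonlocal_params(cfg: dict, **overrides) -> NonlocalParams:
    p = dict(cfg["nonlocal"])
    p.update(overrides)
    return NonlocalParams(matrix=build_matrix(cfg), kappa=cfg["game"]["kappa"], **p)
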