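"""Parameters of the two-mode stochastic logistic birth-death model.

A cell population grows in discrete time with per-capita birth rate
``beta`` and death rate ``delta``.  Each cell can use one of two metabolic
modes: a *defensive* mode (low turnover, long expected lifetime) and an
*aggressive* mode (high turnover, larger net per-capita growth).  Density
regulation acts entirely through the death rate: at population size ``N``
the effective death rate is ``delta + (beta - delta) * N / K`` so that net
per-capita growth vanishes exactly at the carrying capacity ``K``.

The growth-survival trade-off requires

    0 < delta_def < delta_aggr            (defensive cells live longer)
    0 < beta_def - delta_def
        < beta_aggr - delta_aggr          (aggressive cells grow faster)

The state space is the integer grid ``0 .. ceil(K * l)`` with ``l > 1``;
the head-room factor ``l`` exists only to contain stochastic excursions
above ``K``, and ``N = 0`` is absorbing (extinction).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path
from typing import Union

import numpy as np
import yaml


class GrowthMode(enum.IntEnum):
    """The two metabolic modes.  Integer-valued so mode grids can be
    stored as compact arrays."""

    DEFENSIVE = 0
    AGGRESSIVE = 1


@dataclasses.dataclass(frozen=True)
class ModeRates:
    """Intrinsic per-time-step birth and death rates of one mode."""

    beta: float
    delta: float

    @property
    def net_growth(self) -> float:
        """Intrinsic per-capita growth rate ``beta - delta``."""
        return self.beta - self.delta

    @property
    def expected_lifetime(self) -> float:
        """Expected cell lifetime ``1 / delta`` in time steps."""
        return 1.0 / self.delta

    @property
    def reproductive_success(self) -> float:
        """Expected lifetime offspring number ``beta / delta``."""
        return self.beta / self.delta


#: Default intrinsic rates: (beta, delta) = (0.025, 0.005) defensive,
#: (0.125, 0.075) aggressive, i.e. net growth 0.02 vs 0.05 per step.
DEFAULT_RATES_DEFENSIVE = ModeRates(beta=0.025, delta=0.005)
DEFAULT_RATES_AGGRESSIVE = ModeRates(beta=0.125, delta=0.075)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Full model configuration.

    Parameters
    ----------
    rates_def, rates_aggr
        Intrinsic rates of the defensive and aggressive modes.
    K
        Carrying capacity (positive integer population size).
    l
        State-space head-room factor (> 1); the state space is
        ``0 .. ceil(K * l)``.
    T
        Horizon / cycle length in time steps.
    N_initial
        Initial population size.
    """

    rates_def: ModeRates = DEFAULT_RATES_DEFENSIVE
    rates_aggr: ModeRates = DEFAULT_RATES_AGGRESSIVE
    K: int = 500
    l: float = 1.5
    T: int = 750
    N_initial: int = 10

    @property
    def n_top(self) -> int:
        """Largest representable population size ``ceil(K * l)``."""
        return math.ceil(self.K * self.l)

    @property
    def n_states(self) -> int:
        return self.n_top + 1

    def rates(self, mode: GrowthMode) -> ModeRates:
        return self.rates_aggr if mode == GrowthMode.AGGRESSIVE else self.rates_def

    @property
    def beta_by_mode(self) -> np.ndarray:
        """Birth rates indexed by ``GrowthMode`` value."""
        return np.array([self.rates_def.beta, self.rates_aggr.beta])

    @property
    def delta_by_mode(self) -> np.ndarray:
        return np.array([self.rates_def.delta, self.rates_aggr.delta])

    def replace(self, **changes) -> "ModelConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def default_config(**changes) -> ModelConfig:
    """The default configuration (K=500, l=1.5, T=750, N_initial=10)."""
    return ModelConfig().replace(**changes)


def validate_config(config: ModelConfig) -> list[str]:
    """Check the trade-off assumptions and structural constraints.

    Returns a list of human-readable names of the violated constraints;
    an empty list means the configuration is valid.  Nothing is raised.
    """
    violations: list[str] = []
    bd, dd = config.rates_def.beta, config.rates_def.delta
    ba, da = config.rates_aggr.beta, config.rates_aggr.delta
    if not (0.0 < dd < da):
        violations.append("death_rate_order: 0 < delta_def < delta_aggr")
    if not (0.0 < bd - dd < ba - da):
        violations.append(
            "growth_rate_order: 0 < beta_def - delta_def < beta_aggr - delta_aggr"
        )
    if not (bd > dd > 0.0):
        violations.append("defensive_net_growth: 0 < delta_def < beta_def")
    if not (ba > da > 0.0):
        violations.append("aggressive_net_growth: 0 < delta_aggr < beta_aggr")
    if not (isinstance(config.K, (int, np.integer)) and config.K >= 1):
        violations.append("carrying_capacity: K must be a positive integer")
    if not config.l > 1.0:
        violations.append("state_space_factor: l must be > 1")
    if not (isinstance(config.T, (int, np.integer)) and config.T >= 1):
        violations.append("horizon: T must be a positive integer")
    if not (0 <= config.N_initial <= config.n_top):
        violations.append("initial_size: N_initial must lie in 0 .. ceil(K*l)")
    if not np.isfinite(ba * config.K * config.l):
        violations.append("event_intensity: beta_aggr * K * l must be finite")
    return violations


def effective_rates(
    mode: GrowthMode,
    N: Union[int, np.ndarray],
    config: ModelConfig,
    competitor: Union[int, np.ndarray] = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-dependent per-capita rates at population size ``N``.

    The birth rate is density-independent; the death rate increases
    linearly with the community density ``N + competitor`` so that net
    growth is zero when the community sits at the carrying capacity:

        beta_eff  = beta_m
        delta_eff = delta_m + (beta_m - delta_m) * (N + competitor) / K

    ``competitor`` is the (fixed) population size of a second phenotype
    sharing the carrying capacity; zero recovers the monoculture rates.
    Scalars or arrays are accepted; out-of-range sizes raise ValueError.
    """
    N = np.asarray(N)
    if np.any(N < 0) or np.any(N > config.n_top):
        raise ValueError(f"population size outside state space 0..{config.n_top}")
    r = config.rates(GrowthMode(mode))
    density = (N + np.asarray(competitor)) / config.K
    beta_eff = np.broadcast_to(np.asarray(r.beta), density.shape)
    delta_eff = r.delta + r.net_growth * density
    if beta_eff.ndim == 0:
        return float(beta_eff), float(delta_eff)
    return beta_eff, delta_eff


# ---------------------------------------------------------------------------
# configuration file handling


def config_to_dict(config: ModelConfig, seed: int | None = None) -> dict:
    """Resolved configuration as a plain dictionary (JSON/YAML friendly)."""
    out = {
        "modes": {
            "defensive": {
                "beta": config.rates_def.beta,
                "delta": config.rates_def.delta,
            },
            "aggressive": {
                "beta": config.rates_aggr.beta,
                "delta": config.rates_aggr.delta,
            },
        },
        "K": int(config.K),
        "l": float(config.l),
        "T": int(config.T),
        "N_initial": int(config.N_initial),
    }
    if seed is not None:
        out["seed"] = int(seed)
    return out


def config_from_dict(data: dict) -> tuple[ModelConfig, int | None]:
    """Build a ``ModelConfig`` from a dictionary (inverse of
    :func:`config_to_dict`).  Returns the config and the optional seed."""
    cfg = ModelConfig()
    modes = data.get("modes", {})
    if "defensive" in modes:
        cfg = cfg.replace(rates_def=ModeRates(**modes["defensive"]))
    if "aggressive" in modes:
        cfg = cfg.replace(rates_aggr=ModeRates(**modes["aggressive"]))
    for key in ("K", "l", "T", "N_initial"):
        if key in data:
            cfg = cfg.replace(**{key: data[key]})
    return cfg, data.get("seed")


def load_config(path: Union[str, Path]) -> tuple[ModelConfig, int | None]:
    """Read a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def echo_config_json(config: ModelConfig, seed: int | None = None) -> str:
    return json.dumps(config_to_dict(config, seed=seed), indent=2)
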