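"""Seeded Monte-Carlo simulation of growth cycles and serial transfers.

Within a growth cycle the population is updated synchronously each time
step: births and deaths are drawn from independent Poisson laws with
intensities ``N * beta_eff`` and ``N * delta_eff``; the size is absorbed
at 0 and capped at the top of the state grid, mirroring the exact
transition kernel.  In a biculture both phenotypes' intensities are
evaluated at the same pre-update joint state (their death rates couple
through the community density).

A serial-transfer experiment chains growth cycles: at the end of each
cycle a *transfer rule* decides the founders of the next cycle - either
a fixed proportion of every phenotype (deterministic rounding) or a
fixed total founder count split multinomially by final frequencies.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .model import GrowthMode, ModelConfig
from .strategies import PairStrategy, Strategy, as_pair_strategy

PROPORTIONAL = "proportional"
FIXED_FOUNDERS = "fixed_founders"


@dataclasses.dataclass(frozen=True)
class TransferProtocol:
    """Serial-transfer protocol.

    ``rule`` is ``"proportional"`` (transfer ``round(fraction * size)``
    of each phenotype, half-up) or ``"fixed_founders"`` (draw a fixed
    total number of founders multinomially from the final frequencies;
    an extinct community founds nothing).
    """

    cycle_length: int
    n_cycles: int
    rule: str = PROPORTIONAL
    fraction: float = 0.2
    founders: int = 50

    def __post_init__(self):
        if self.cycle_length < 1 or self.n_cycles < 1:
            raise ValueError("cycle_length and n_cycles must be >= 1")
        if self.rule == PROPORTIONAL:
            if not 0.0 < self.fraction < 1.0:
                raise ValueError("transfer fraction must lie in (0, 1)")
        elif self.rule == FIXED_FOUNDERS:
            if self.founders < 1:
                raise ValueError("founder count must be >= 1")
        else:
            raise ValueError(f"unknown transfer rule {self.rule!r}")


@dataclasses.dataclass
class Trajectory:
    """One phenotype's path through one growth cycle.

    ``sizes[i]`` is the size at time ``times[i]``; ``modes[i]`` is the
    mode used to step from ``times[i]`` (the final entry repeats the last
    controlled step so the arrays align)."""

    times: np.ndarray
    sizes: np.ndarray
    modes: np.ndarray
    cycle_index: int = 0


def _step_sizes(
    sizes: np.ndarray,
    modes: np.ndarray,
    total: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous birth-death update, vectorized over populations."""
    beta = config.beta_by_mode[modes]
    net = beta - config.delta_by_mode[modes]
    delta_eff = config.delta_by_mode[modes] + net * total / config.K
    births = rng.poisson(beta * sizes)
    deaths = rng.poisson(delta_eff * sizes)
    return np.clip(sizes + births - deaths, 0, config.n_top)


def simulate_cycle(
    N0: int,
    strategy: Strategy,
    config: ModelConfig,
    seed,
    cycle_index: int = 0,
) -> Trajectory:
    """Simulate one monoculture growth cycle of ``config.T`` steps."""
    if not 0 <= N0 <= config.n_top:
        raise ValueError(f"initial size {N0} outside 0..{config.n_top}")
    rng = np.random.default_rng(seed)
    T = config.T
    sizes = np.empty(T + 1, dtype=np.int64)
    modes = np.empty(T + 1, dtype=np.int8)
    sizes[0] = N0
    for t in range(T):
        m = np.int8(strategy.mode_at(t, sizes[t]))
        modes[t] = m
        sizes[t + 1] = _step_sizes(
            sizes[t : t + 1],
            np.array([m]),
            np.asarray(sizes[t], dtype=float),
            config,
            rng,
        )[0]
    modes[T] = modes[T - 1]
    return Trajectory(
        times=np.arange(T + 1), sizes=sizes, modes=modes, cycle_index=cycle_index
    )


def apply_transfer(
    final_sizes, protocol: TransferProtocol, seed
) -> np.ndarray:
    """Founder sizes for the next cycle from end-of-cycle sizes."""
    sizes = np.asarray(final_sizes, dtype=np.int64)
    if np.any(sizes < 0):
        raise ValueError("population sizes must be non-negative")
    if protocol.rule == PROPORTIONAL:
        return np.floor(protocol.fraction * sizes + 0.5).astype(np.int64)
    rng = np.random.default_rng(seed)
    total = sizes.sum()
    if total == 0:
        return np.zeros_like(sizes)
    return rng.multinomial(protocol.founders, sizes / total).astype(np.int64)


def _batch_transfer(
    sizes: np.ndarray, protocol: TransferProtocol, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized transfer for a ``(runs, phenotypes)`` size matrix."""
    if protocol.rule == PROPORTIONAL:
        return np.floor(protocol.fraction * sizes + 0.5).astype(np.int64)
    total = sizes.sum(axis=1)
    alive = total > 0
    if sizes.shape[1] == 1:
        out = np.zeros_like(sizes)
        out[alive, 0] = protocol.founders
        return out
    if sizes.shape[1] != 2:
        raise NotImplementedError("fixed-founder transfers support <= 2 phenotypes")
    p = np.divide(sizes[:, 0], total, out=np.zeros(len(sizes)), where=alive)
    a = rng.binomial(protocol.founders, p)
    out = np.stack([a, protocol.founders - a], axis=1).astype(np.int64)
    out[~alive] = 0
    return out


def simulate_serial_transfer(
    initial,
    strategies,
    protocol: TransferProtocol,
    config: ModelConfig,
    seed,
) -> list[list[Trajectory]]:
    """Chain growth cycles and transfers for one community.

    ``initial`` and ``strategies`` are per-phenotype (one entry for a
    monoculture, two for a biculture); biculture strategies are lifted to
    pair strategies evaluated at the joint state.  Returns, per cycle,
    the list of per-phenotype trajectories.
    """
    initial = np.atleast_1d(np.asarray(initial, dtype=np.int64))
    if isinstance(strategies, (Strategy, PairStrategy)):
        strategies = [strategies]
    P = len(initial)
    if len(strategies) != P:
        raise ValueError("need one strategy per phenotype")
    pair = [as_pair_strategy(s) for s in strategies]
    rng = np.random.default_rng(seed)
    cfg = config.replace(T=protocol.cycle_length)
    sizes = initial.copy()
    cycles: list[list[Trajectory]] = []
    for cyc in range(protocol.n_cycles):
        T = protocol.cycle_length
        hist = np.empty((T + 1, P), dtype=np.int64)
        mhist = np.empty((T + 1, P), dtype=np.int8)
        hist[0] = sizes
        for t in range(T):
            cur = hist[t]
            other = cur.sum() - cur
            modes = np.array(
                [pair[i].mode_at(t, cur[i], other[i]) for i in range(P)],
                dtype=np.int8,
            )
            mhist[t] = modes
            hist[t + 1] = _step_sizes(
                cur.astype(float), modes, float(cur.sum()), cfg, rng
            )
        mhist[T] = mhist[T - 1]
        cycles.append(
            [
                Trajectory(
                    times=np.arange(T + 1),
                    sizes=hist[:, i].copy(),
                    modes=mhist[:, i].copy(),
                    cycle_index=cyc,
                )
                for i in range(P)
            ]
        )
        sizes = apply_transfer(hist[T], protocol, rng)
    return cycles
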