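"""Growth strategies: rules assigning a metabolic mode to each state.

Monoculture strategies map ``(t, N)`` to a mode; pair strategies used in
biculture competitions map ``(t, own size, competitor size)`` to a mode.
All lookups are vectorized over population sizes so that both the exact
distribution propagation and the Monte-Carlo simulator can evaluate them
cheaply.
"""

from __future__ import annotations

import numpy as np

from .model import GrowthMode, ModelConfig


class Strategy:
    """Base class for monoculture strategies ``m(N, t)``."""

    #: True when the assignment does not depend on t
    time_invariant = False
    name = "strategy"

    def mode_at(self, t, N):
        """Mode at time ``t`` for population size(s) ``N`` (vectorized)."""
        raise NotImplementedError

    def mode_vector(self, t: int, n_states: int) -> np.ndarray:
        """Modes for every state ``0 .. n_states-1`` at time ``t``."""
        return np.asarray(self.mode_at(t, np.arange(n_states)), dtype=np.int8)


class PureStrategy(Strategy):
    """One fixed mode at all times and sizes."""

    time_invariant = True

    def __init__(self, mode: GrowthMode):
        self.mode = GrowthMode(mode)
        self.name = self.mode.name.lower()

    def mode_at(self, t, N):
        return np.full(np.shape(N), np.int8(self.mode))


class GreedyStrategy(Strategy):
    """Maximize the instantaneous per-capita growth rate.

    Below and at the carrying capacity the aggressive mode has the larger
    net growth; above it both modes shrink but the aggressive one shrinks
    faster, so the rule is: defensive iff ``N > K``.  Time-invariant.
    """

    time_invariant = True
    name = "greedy"

    def __init__(self, config: ModelConfig):
        self.K = config.K

    def mode_at(self, t, N):
        return np.where(
            np.asarray(N) > self.K,
            np.int8(GrowthMode.DEFENSIVE),
            np.int8(GrowthMode.AGGRESSIVE),
        )


class MapStrategy(Strategy):
    """Strategy read off a solved control map (mode per ``(t, N)``)."""

    name = "optimal"

    def __init__(self, control_map):
        self.control_map = control_map
        self._modes = control_map.modes  # (T, n_states) int8

    def mode_at(self, t, N):
        t = min(int(t), self._modes.shape[0] - 1)
        return self._modes[t, np.asarray(N)]

    def mode_vector(self, t, n_states):
        t = min(int(t), self._modes.shape[0] - 1)
        return self._modes[t]


# ---------------------------------------------------------------------------
# pair strategies (biculture)


class PairStrategy:
    """Base class for biculture strategies ``m(own, competitor, t)``."""

    time_invariant = False
    name = "pair"

    def mode_at(self, t, own, other):
        raise NotImplementedError


class PurePairStrategy(PairStrategy):
    time_invariant = True

    def __init__(self, mode: GrowthMode):
        self.mode = GrowthMode(mode)
        self.name = self.mode.name.lower()

    def mode_at(self, t, own, other):
        return np.full(np.broadcast(own, other).shape, np.int8(self.mode))


class GreedyPlaneStrategy(PairStrategy):
    """Greedy rule on the community density: defensive iff
    ``own + competitor > K``.  Symmetric in the two phenotypes and
    time-invariant; equals the terminal slice of the anticipative
    control tensor."""

    time_invariant = True
    name = "greedy"

    def __init__(self, config: ModelConfig):
        self.K = config.K

    def mode_at(self, t, own, other):
        return np.where(
            np.asarray(own) + np.asarray(other) > self.K,
            np.int8(GrowthMode.DEFENSIVE),
            np.int8(GrowthMode.AGGRESSIVE),
        )


class TensorStrategy(PairStrategy):
    """Strategy read off a control tensor (mode per ``(t, own, comp)``)."""

    def __init__(self, tensor, name: str | None = None):
        self.tensor = tensor
        self._modes = tensor.modes  # (T, n, n) int8
        self.name = name or tensor.provenance

    def mode_at(self, t, own, other):
        t = min(int(t), self._modes.shape[0] - 1)
        return self._modes[t, np.asarray(own), np.asarray(other)]


def as_pair_strategy(strategy) -> PairStrategy:
    """Lift a monoculture strategy into the biculture setting by
    evaluating its rule at the community density."""
    if isinstance(strategy, PairStrategy):
        return strategy
    if isinstance(strategy, PureStrategy):
        return PurePairStrategy(strategy.mode)

    class _Lifted(PairStrategy):
        time_invariant = strategy.time_invariant
        name = strategy.name

        def mode_at(self, t, own, other):
            return strategy.mode_at(t, np.asarray(own) + np.asarray(other))

    return _Lifted()
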