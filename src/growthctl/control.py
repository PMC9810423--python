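"""Finite-horizon optimal control of the growth mode.

The expected gain ``J(N, t)`` is the expected final population size when
the optimal mode is used from state ``N`` at time ``t`` onward, with the
boundary condition ``J(N, T) = N``.  Backward induction

    J(N, t) = max_m  sum_{N'} J(N', t+1) W(N' | N; m)

over the whole state grid yields the optimal *control map*
``m_opt(N, t)`` together with the gains and the per-state advantage of
the optimal mode over the alternative (the gain margin).  Exact ties are
resolved in favour of the defensive (lower-variance) mode, which also
fixes the convention that the absorbing state 0 is labelled defensive.

The same backward recursion solved with the carrying capacity shifted by
a fixed competitor population size produces, slice by slice, the
anticipative control tensor used in biculture competitions (see
:mod:`growthctl.biculture`).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from . import kernel
from .model import GrowthMode, ModelConfig
from .strategies import (
    GreedyStrategy,
    MapStrategy,
    PureStrategy,
    Strategy,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ControlMap:
    """Solved optimal policy for a monoculture.

    Attributes
    ----------
    modes
        ``(T, n_states)`` int8 array; ``modes[t, N]`` is the optimal mode.
    gains
        ``(T+1, n_states)`` expected gains; ``gains[T] = N`` (boundary).
    gain_margin
        ``(T, n_states)`` absolute gain difference between the optimal
        and the alternative mode (raw, unnormalized).
    """

    config: ModelConfig
    modes: np.ndarray
    gains: np.ndarray
    gain_margin: np.ndarray

    @property
    def T(self) -> int:
        return self.modes.shape[0]

    def strategy(self) -> MapStrategy:
        return MapStrategy(self)


@dataclasses.dataclass
class BoundaryTrace:
    """Mode-change contours of a control map.

    ``segments[t]`` lists ``(N, label)`` pairs: the assigned mode changes
    between ``N`` and ``N + 1``; the label is ``"minimizing"`` when the
    upper side uses the aggressive mode (the contour opposes growth, e.g.
    the lag-creating boundary) and ``"maximizing"`` when the upper side
    is defensive (the contour pushes the population upward).  State 0 is
    skipped: its defensive label is a convention of the absorbing state.
    """

    segments: list


def solve_slices(
    config: ModelConfig,
    comp_sizes,
    keep_gains: bool = False,
    keep_margin: bool = False,
    chunk: int = 32,
    progress: bool = False,
):
    """Backward induction for a batch of fixed competitor sizes.

    For each competitor size ``c`` the monoculture Bellman problem is
    solved with the logistic death term evaluated at the community
    density ``(N + c) / K``; ``c = 0`` is exactly the monoculture
    problem.  Returns ``(modes, gains, margins)`` with shapes
    ``(T, n, n_c)``, ``(T+1, n, n_c)`` (or ``None``) and ``(T, n, n_c)``
    (or ``None``).  Work proceeds in chunks of competitor sizes with all
    large buffers preallocated once.
    """
    comp = np.asarray(comp_sizes, dtype=int).ravel()
    n = config.n_states
    T = config.T
    n_c = comp.size
    chunk = min(chunk, n_c)
    modes_out = np.empty((T, n, n_c), dtype=np.int8)
    gains_out = np.empty((T + 1, n, n_c)) if keep_gains else None
    margin_out = np.empty((T, n, n_c)) if keep_margin else None
    states = np.arange(n, dtype=float)

    W = np.empty((2, chunk, n, n))
    J = np.empty((chunk, n, 1))
    Ed = np.empty((chunk, n, 1))
    Ea = np.empty((chunk, n, 1))
    for lo in range(0, n_c, chunk):
        hi = min(lo + chunk, n_c)
        ncv = hi - lo
        if progress:
            logger.info("bellman slices %d..%d of %d (T=%d, n=%d)", lo, hi, n_c, T, n)
        for mode in (GrowthMode.DEFENSIVE, GrowthMode.AGGRESSIVE):
            kernel.transition_stack(mode, config, comp[lo:hi], out=W[mode, :ncv])
        Jv, Edv, Eav = J[:ncv], Ed[:ncv], Ea[:ncv]
        Jv[:] = states[None, :, None]
        if keep_gains:
            gains_out[T, :, lo:hi] = Jv[:, :, 0].T
        for t in range(T - 1, -1, -1):
            np.matmul(W[0, :ncv], Jv, out=Edv)
            np.matmul(W[1, :ncv], Jv, out=Eav)
            # aggressive wins only a strictly larger gain (defensive ties)
            modes_out[t, :, lo:hi] = (Eav[:, :, 0] > Edv[:, :, 0]).T
            if keep_margin:
                margin_out[t, :, lo:hi] = np.abs(Eav[:, :, 0] - Edv[:, :, 0]).T
            np.maximum(Eav, Edv, out=Jv)
            if keep_gains:
                gains_out[t, :, lo:hi] = Jv[:, :, 0].T
    return modes_out, gains_out, margin_out


def solve_bellman(config: ModelConfig) -> ControlMap:
    """Solve the monoculture optimal-control problem."""
    modes, gains, margin = solve_slices(
        config, [0], keep_gains=True, keep_margin=True
    )
    return ControlMap(
        config=config,
        modes=modes[:, :, 0],
        gains=gains[:, :, 0],
        gain_margin=margin[:, :, 0],
    )


def greedy_strategy(config: ModelConfig) -> GreedyStrategy:
    """The r/K-style greedy rule: defensive iff ``N > K``."""
    return GreedyStrategy(config)


def extract_boundaries(cmap: ControlMap) -> BoundaryTrace:
    """Locate the mode-change contours of a solved control map."""
    segments = []
    for t in range(cmap.T):
        row = cmap.modes[t]
        changes = np.nonzero(row[1:-1] != row[2:])[0] + 1
        segs = []
        for N in changes:
            upper_aggr = row[N + 1] == GrowthMode.AGGRESSIVE
            segs.append((int(N), "minimizing" if upper_aggr else "maximizing"))
        segments.append(segs)
    return BoundaryTrace(segments=segments)


def low_density_defensive_extent(
    cmap: ControlMap, n_max: int | None = None
) -> int:
    """Last time step at which any low-density state (``1 .. n_max``,
    default ``K // 10``) is assigned the defensive mode; -1 when no such
    lag region exists.  The absorbing state 0 is ignored."""
    n_max = n_max if n_max is not None else cmap.config.K // 10
    hit = np.any(cmap.modes[:, 1 : n_max + 1] == GrowthMode.DEFENSIVE, axis=1)
    t = np.nonzero(hit)[0]
    return int(t[-1]) if t.size else -1


def has_lag_region(cmap: ControlMap, N0: int | None = None) -> bool:
    """Whether the optimal policy delays growth from the inoculum size.

    A distinct lag phase requires the low-density defensive region to
    reach the initial population size (default ``config.N_initial``):
    only then does a freshly inoculated population start in defensive
    mode.  A few defensive states at minuscule sizes (N of order 1,
    where survival always dominates) do not constitute a lag regime.
    """
    N0 = N0 if N0 is not None else cmap.config.N_initial
    return bool(np.any(cmap.modes[:, N0] == GrowthMode.DEFENSIVE))


# ---------------------------------------------------------------------------
# lag-time analysis


def lag_time(
    cmap: ControlMap,
    config: ModelConfig,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Median first time the optimal policy plays the aggressive mode.

    Simulates ``n_reps`` trajectories from ``N_initial`` under the
    control map and records, per trajectory, the first step whose
    assigned mode is aggressive (later re-entries into the defensive
    region are ignored).  Trajectories that never switch - including
    those absorbed at 0, where the defensive label is a convention -
    count as "no switch"; when the median itself is unresolved the NaN
    sentinel for "no switch within horizon" is returned.
    """
    rng = np.random.default_rng(seed)
    beta = config.beta_by_mode[GrowthMode.DEFENSIVE]
    delta = config.delta_by_mode[GrowthMode.DEFENSIVE]
    net = beta - delta
    sizes = np.full(n_reps, config.N_initial, dtype=np.int64)
    switch_t = np.full(n_reps, np.inf)
    active = np.ones(n_reps, dtype=bool)
    for t in range(cmap.T):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        now_aggr = cmap.modes[t, sizes[idx]] == GrowthMode.AGGRESSIVE
        switch_t[idx[now_aggr]] = t
        active[idx[now_aggr]] = False
        idx = idx[~now_aggr]
        if idx.size == 0:
            break
        # all still-active runs are, by construction, in defensive states
        s = sizes[idx]
        delta_eff = delta + net * s / config.K
        s_new = s + rng.poisson(beta * s) - rng.poisson(delta_eff * s)
        sizes[idx] = np.clip(s_new, 0, config.n_top)
    med = float(np.median(switch_t))
    return med if math.isfinite(med) else math.nan


def lag_curve(
    config: ModelConfig,
    cycle_lengths,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Optimal lag time as a function of the cycle length ``T``.

    Solves the control problem for each horizon and measures the median
    defensive-to-aggressive switching time from ``N_initial``.
    """
    rows = []
    for i, T in enumerate(cycle_lengths):
        cfg = config.replace(T=int(T))
        cmap = solve_bellman(cfg)
        lag = lag_time(cmap, cfg, n_reps=n_reps, seed=seed + i)
        logger.info("lag curve: T=%d lag=%s", T, lag)
        rows.append({"T": int(T), "lag": lag, "n_reps": n_reps, "seed": seed + i})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# strategy comparison by exact propagation


@dataclasses.dataclass
class StrategyComparison:
    """Median-size time series and final distributions per strategy."""

    medians: pd.DataFrame
    final_distributions: dict
    summaries: pd.DataFrame


def resolve_strategy(name, config: ModelConfig, cmap: ControlMap | None = None):
    """Map a strategy name to a strategy object.

    Accepts ``"aggressive"``, ``"defensive"``, ``"greedy"`` or
    ``"optimal"`` (the latter requires, or triggers, a Bellman solve);
    strategy instances pass through unchanged.
    """
    if isinstance(name, Strategy):
        return name
    if name == "aggressive":
        return PureStrategy(GrowthMode.AGGRESSIVE)
    if name == "defensive":
        return PureStrategy(GrowthMode.DEFENSIVE)
    if name == "greedy":
        return GreedyStrategy(config)
    if name == "optimal":
        return MapStrategy(cmap if cmap is not None else solve_bellman(config))
    raise ValueError(f"unknown strategy {name!r}")


def strategy_comparison(
    config: ModelConfig,
    strategies=("aggressive", "defensive", "greedy", "optimal"),
    T: int | None = None,
    cmap: ControlMap | None = None,
) -> StrategyComparison:
    """Propagate each strategy exactly from ``N_initial`` and summarize.

    Returns the per-step median population size of every strategy
    together with its final population-size distribution and summary
    statistics (median, mean, variance, extinction probability).
    """
    T = T if T is not None else config.T
    kernels = (
        kernel.transition_matrix(GrowthMode.DEFENSIVE, config),
        kernel.transition_matrix(GrowthMode.AGGRESSIVE, config),
    )
    resolved = [resolve_strategy(s, config, cmap=cmap) for s in strategies]
    medians = {}
    finals = {}
    summaries = {}
    for strat in resolved:
        dist = kernel.PopulationDistribution.point_mass(config.N_initial, config)
        med = [kernel.summarize(dist).median]
        for step in range(T):
            dist = kernel.propagate(
                dist, strat, config, 1, kernels=kernels,
                warn_top_mass=(step == T - 1),
            )
            med.append(kernel.summarize(dist).median)
        medians[strat.name] = med
        finals[strat.name] = dist
        summaries[strat.name] = dataclasses.asdict(kernel.summarize(dist))
    return StrategyComparison(
        medians=pd.DataFrame(medians, index=pd.RangeIndex(T + 1, name="t")),
        final_distributions=finals,
        summaries=pd.DataFrame(summaries).T,
    )
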