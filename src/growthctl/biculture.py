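"""Head-to-head competition of growth strategies under shared density.

Two phenotypes share one carrying capacity: each phenotype's effective
death rate is driven by the community density ``N = N_a + N_c``.  The
adaptive focal phenotype can sense both sizes, which turns the
monoculture control map into a three-dimensional *control tensor*: for
every fixed competitor size ``c`` a monoculture Bellman problem is
solved with the density shifted by ``c`` (the *anticipative* phenotype -
it anticipates its own dynamics but treats the competitor as frozen).
The terminal slice of that tensor is the time-invariant *greedy plane*:
defensive exactly when the community density exceeds ``K``.

The *biculture-optimal* phenotype goes one step further and folds the
competitor's full stochastic dynamics into the backward induction over
the joint state space ``(N_a, N_c)``; it is solved here against any
time-invariant competitor strategy (greedy by default).  This joint
solver is exact but cubic in the state count per step, so it is meant
for reduced carrying capacities; a memory guard rejects state spaces
that would not fit.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import kernel
from .control import solve_slices
from .model import GrowthMode, ModelConfig
from .simulate import TransferProtocol, _batch_transfer, simulate_serial_transfer
from .strategies import (
    GreedyPlaneStrategy,
    PairStrategy,
    PurePairStrategy,
    TensorStrategy,
)

logger = logging.getLogger(__name__)

FOCAL_WIN = "focal_win"
FOCAL_LOSS = "focal_loss"
COEXIST = "coexist"
ALL_EXTINCT = "all_extinct"
OUTCOME_LABELS = (FOCAL_WIN, FOCAL_LOSS, COEXIST, ALL_EXTINCT)


class JointStateSpaceError(RuntimeError):
    """Joint solver would exceed its memory budget; reduce K (or l)."""


def competitor_rates(strategy, Na, Nc, config: ModelConfig, t: int = 0):
    """Effective per-capita rates of the competitor phenotype.

    The competitor of size ``Nc`` follows ``strategy`` (a pair strategy
    or a fixed ``GrowthMode``) evaluated at the joint state; its logistic
    death term uses the community density ``(Na + Nc) / K``.
    """
    Na = np.asarray(Na)
    Nc = np.asarray(Nc)
    if np.any(Na < 0) or np.any(Nc < 0) or np.any(Na > config.n_top) or np.any(Nc > config.n_top):
        raise ValueError("joint state outside the state space")
    if isinstance(strategy, PairStrategy):
        mode = np.asarray(strategy.mode_at(t, Nc, Na))
    else:
        mode = np.full(np.broadcast(Na, Nc).shape, int(GrowthMode(strategy)))
    beta = config.beta_by_mode[mode]
    net = beta - config.delta_by_mode[mode]
    delta_eff = config.delta_by_mode[mode] + net * (Na + Nc) / config.K
    if beta.ndim == 0:
        return float(beta), float(delta_eff)
    return beta, delta_eff


@dataclasses.dataclass
class ControlTensor:
    """Stack of control maps over competitor size.

    ``modes[t, Na, Nc]`` is the focal phenotype's mode; ``gains`` (kept
    optionally) carries the expected gains with boundary
    ``gains[T, Na, Nc] = Na``.  ``provenance`` records which solver
    built it: ``"anticipative"`` (per-slice frozen competitor) or
    ``"biculture_optimal"`` (joint-state backward induction).
    """

    config: ModelConfig
    modes: np.ndarray
    provenance: str
    gains: np.ndarray | None = None

    def strategy(self, name: str | None = None) -> TensorStrategy:
        return TensorStrategy(self, name=name)

    def slice_map(self, Nc: int):
        """Monoculture-style view of the slice at fixed competitor size."""
        return self.modes[:, :, Nc]


def build_anticipative_tensor(
    config: ModelConfig,
    keep_gains: bool = False,
    chunk: int = 32,
    progress: bool = False,
) -> ControlTensor:
    """Anticipative control tensor: one Bellman solve per competitor size.

    Slice ``Nc = 0`` is exactly the monoculture control map (built by the
    same backward induction), so every monoculture result is recovered
    when the competitor is absent.
    """
    comp = np.arange(config.n_states)
    modes, gains, _ = solve_slices(
        config, comp, keep_gains=keep_gains, chunk=chunk, progress=progress
    )
    return ControlTensor(
        config=config, modes=modes, provenance="anticipative", gains=gains
    )


def greedy_plane(config: ModelConfig) -> np.ndarray:
    """Time-invariant greedy mode assignment over ``(Na, Nc)``:
    defensive iff the community density exceeds the carrying capacity."""
    n = config.n_states
    total = np.arange(n)[:, None] + np.arange(n)[None, :]
    return np.where(
        total > config.K,
        np.int8(GrowthMode.DEFENSIVE),
        np.int8(GrowthMode.AGGRESSIVE),
    ).astype(np.int8)


# ---------------------------------------------------------------------------
# joint-state machinery


def _joint_kernels(config: ModelConfig, competitor_strategy: PairStrategy):
    """Dense one-step kernels on the joint grid.

    Returns ``(Wa, Wc)`` with ``Wa[m, a, c, b]`` the focal kernel under
    mode ``m`` and ``Wc[a, c, d]`` the competitor kernel under its own
    (time-invariant) strategy; both phenotypes' intensities are evaluated
    at the current joint state, and their increments are conditionally
    independent, so the joint transition is the product of the two rows.
    """
    if not getattr(competitor_strategy, "time_invariant", False):
        raise ValueError("the joint solver needs a time-invariant competitor")
    n = config.n_states
    A = np.arange(n, dtype=float)[:, None]
    C = np.arange(n, dtype=float)[None, :]
    beta = config.beta_by_mode
    delta = config.delta_by_mode
    density = (A + C) / config.K

    Wa = np.empty((2, n, n, n))
    src_a = np.broadcast_to(np.arange(n)[:, None], (n, n)).reshape(-1)
    for m in (0, 1):
        mu1 = np.broadcast_to(A * beta[m], (n, n)).reshape(-1)
        mu2 = (A * (delta[m] + (beta[m] - delta[m]) * density)).reshape(-1)
        kernel._fill_transition_rows(mu1, mu2, src_a, n, Wa[m].reshape(-1, n))

    mc = np.asarray(
        competitor_strategy.mode_at(
            0, np.arange(n)[None, :], np.arange(n)[:, None]
        )
    )
    mc = np.broadcast_to(mc, (n, n))
    bc = beta[mc]
    dc = delta[mc]
    mu1 = (C * bc).reshape(-1)
    mu2 = (C * (dc + (bc - dc) * density)).reshape(-1)
    src_c = np.broadcast_to(np.arange(n)[None, :], (n, n)).reshape(-1)
    Wc = np.empty((n, n, n))
    kernel._fill_transition_rows(mu1, mu2, src_c, n, Wc.reshape(-1, n))
    return Wa, Wc


def _check_joint_budget(config: ModelConfig, memory_budget_bytes: float):
    n = config.n_states
    need = 4 * n**3 * 8
    if need > memory_budget_bytes:
        raise JointStateSpaceError(
            f"joint state space needs ~{need/1e9:.1f} GB of kernels "
            f"(n={n}); reduce K or l, or raise memory_budget_bytes"
        )


def solve_biculture_optimal(
    config: ModelConfig,
    competitor_strategy: PairStrategy | None = None,
    keep_gains: bool = True,
    memory_budget_bytes: float = 2e9,
) -> ControlTensor:
    """Jointly optimal focal strategy against a known competitor.

    Backward induction over the joint states ``(Na, Nc)`` with gain
    boundary ``G(Na, Nc, T) = Na``; the one-step joint transition is the
    product of the focal and competitor Skellam kernels, both evaluated
    at the current joint state, with the competitor's mode fixed by its
    strategy (greedy by default).  The focal mode maximizes the expected
    gain; defensive wins exact ties.
    """
    _check_joint_budget(config, memory_budget_bytes)
    if competitor_strategy is None:
        competitor_strategy = GreedyPlaneStrategy(config)
    n = config.n_states
    T = config.T
    Wa, Wc = _joint_kernels(config, competitor_strategy)
    G = np.broadcast_to(np.arange(n, dtype=float)[:, None], (n, n)).copy()
    modes = np.empty((T, n, n), dtype=np.int8)
    gains = np.empty((T + 1, n, n)) if keep_gains else None
    if keep_gains:
        gains[T] = G
    for t in range(T - 1, -1, -1):
        H = np.matmul(Wc, G.T)  # H[a, c, b] = sum_d Wc[a,c,d] G[b,d]
        Ed = np.einsum("acb,acb->ac", Wa[0], H)
        Ea = np.einsum("acb,acb->ac", Wa[1], H)
        modes[t] = Ea > Ed
        G = np.maximum(Ea, Ed)
        if keep_gains:
            gains[t] = G
    return ControlTensor(
        config=config, modes=modes, provenance="biculture_optimal", gains=gains
    )


def propagate_joint(
    P0: np.ndarray,
    focal_strategy: PairStrategy,
    competitor_strategy: PairStrategy,
    config: ModelConfig,
    steps: int,
    t0: int = 0,
    memory_budget_bytes: float = 2e9,
) -> np.ndarray:
    """Exact forward propagation of a joint distribution ``P[Na, Nc]``."""
    _check_joint_budget(config, memory_budget_bytes)
    n = config.n_states
    Wa, Wc = _joint_kernels(config, competitor_strategy)
    A = np.arange(n)[:, None]
    C = np.arange(n)[None, :]
    P = np.asarray(P0, dtype=float).copy()
    for step in range(steps):
        mf = np.broadcast_to(
            np.asarray(focal_strategy.mode_at(t0 + step, A, C)), (n, n)
        )
        Y = (P * (mf == 0))[:, :, None] * Wa[0]
        Y += (P * (mf == 1))[:, :, None] * Wa[1]
        P = np.einsum("acb,acd->bd", Y, Wc)
    return P


def expected_final_focal(
    initial: tuple[int, int],
    focal_strategy: PairStrategy,
    competitor_strategy: PairStrategy,
    config: ModelConfig,
    T: int | None = None,
) -> float:
    """Expected focal population size after ``T`` steps (exact)."""
    T = T if T is not None else config.T
    n = config.n_states
    P0 = np.zeros((n, n))
    P0[initial[0], initial[1]] = 1.0
    P = propagate_joint(P0, focal_strategy, competitor_strategy, config, T)
    return float(np.arange(n) @ P.sum(axis=1))


# ---------------------------------------------------------------------------
# stochastic competitions


@dataclasses.dataclass
class CompetitionOutcome:
    """Result of one serial-transfer head-to-head run, classified at the
    end of the final cycle's growth (before any further transfer)."""

    label: str
    final_sizes: np.ndarray
    trajectories: list | None = None


def classify_outcome(final_sizes) -> str:
    a, c = int(final_sizes[0]), int(final_sizes[1])
    if a > 0 and c == 0:
        return FOCAL_WIN
    if a == 0 and c > 0:
        return FOCAL_LOSS
    if a == 0 and c == 0:
        return ALL_EXTINCT
    return COEXIST


def default_initial_sizes(config: ModelConfig) -> tuple[int, int]:
    """Equal founding sizes at one tenth of the carrying capacity."""
    f = max(1, round(0.1 * config.K))
    return (f, f)


def simulate_competition(
    strategy_a: PairStrategy,
    strategy_b: PairStrategy,
    protocol: TransferProtocol,
    config: ModelConfig,
    seed,
    initial: tuple[int, int] | None = None,
    record: bool = True,
) -> CompetitionOutcome:
    """One seeded serial-transfer competition between two phenotypes."""
    initial = initial if initial is not None else default_initial_sizes(config)
    cycles = simulate_serial_transfer(
        initial, [strategy_a, strategy_b], protocol, config, seed
    )
    final_sizes = np.array([traj.sizes[-1] for traj in cycles[-1]])
    return CompetitionOutcome(
        label=classify_outcome(final_sizes),
        final_sizes=final_sizes,
        trajectories=cycles if record else None,
    )


def simulate_competition_batch(
    strategy_a: PairStrategy,
    strategy_b: PairStrategy,
    protocol: TransferProtocol,
    config: ModelConfig,
    n_runs: int,
    seed,
    initial: tuple[int, int] | None = None,
) -> np.ndarray:
    """Outcome labels of ``n_runs`` independent competitions.

    Runs are advanced in lock-step with vectorized Poisson draws from a
    single generator seeded by ``seed``; the final classification is made
    after the last cycle's growth, before any transfer.
    """
    initial = initial if initial is not None else default_initial_sizes(config)
    rng = np.random.default_rng(seed)
    beta = config.beta_by_mode
    delta = config.delta_by_mode
    K, top = config.K, config.n_top
    sizes = np.tile(np.asarray(initial, dtype=np.int64), (n_runs, 1))
    for cyc in range(protocol.n_cycles):
        if cyc > 0:
            sizes = _batch_transfer(sizes, protocol, rng)
        for t in range(protocol.cycle_length):
            ma = np.asarray(strategy_a.mode_at(t, sizes[:, 0], sizes[:, 1]))
            mb = np.asarray(strategy_b.mode_at(t, sizes[:, 1], sizes[:, 0]))
            total = sizes.sum(axis=1)
            new = np.empty_like(sizes)
            for i, m in enumerate((ma, mb)):
                b = beta[m]
                net = b - delta[m]
                d_eff = delta[m] + net * total / K
                s = sizes[:, i]
                new[:, i] = np.clip(
                    s + rng.poisson(b * s) - rng.poisson(d_eff * s), 0, top
                )
            sizes = new
    labels = np.select(
        [
            (sizes[:, 0] > 0) & (sizes[:, 1] == 0),
            (sizes[:, 0] == 0) & (sizes[:, 1] > 0),
            (sizes[:, 0] == 0) & (sizes[:, 1] == 0),
        ],
        [0, 1, 3],
        default=2,
    )
    return np.array(OUTCOME_LABELS)[np.where(labels == 3, 3, labels)]


def tabulate_outcomes(labels) -> dict:
    labels = np.asarray(labels)
    n = labels.size
    return {lab: float(np.mean(labels == lab)) for lab in OUTCOME_LABELS} | {
        "n_sims": int(n)
    }


def resolve_pair_strategy(
    name, config: ModelConfig, tensor_cache: dict | None = None
) -> PairStrategy:
    """Build a named competition phenotype for the given configuration.

    Names: ``defensive``, ``aggressive``, ``greedy`` (community-density
    rule), ``anticipative`` (frozen-competitor control tensor solved at
    the configured horizon) and ``biculture_optimal`` (joint-state
    solver, small state spaces only).  Solved tensors are memoized in
    ``tensor_cache`` keyed by ``(name, K, l, T)``.
    """
    if isinstance(name, PairStrategy):
        return name
    if name == "defensive":
        return PurePairStrategy(GrowthMode.DEFENSIVE)
    if name == "aggressive":
        return PurePairStrategy(GrowthMode.AGGRESSIVE)
    if name == "greedy":
        return GreedyPlaneStrategy(config)
    if name in ("anticipative", "biculture_optimal"):
        key = (name, config.K, config.l, config.T)
        if tensor_cache is not None and key in tensor_cache:
            return tensor_cache[key].strategy(name=name)
        if name == "anticipative":
            tensor = build_anticipative_tensor(config, progress=True)
        else:
            tensor = solve_biculture_optimal(config, keep_gains=False)
        if tensor_cache is not None:
            tensor_cache[key] = tensor
        return tensor.strategy(name=name)
    raise ValueError(f"unknown phenotype {name!r}")


def sweep_cycle_lengths(
    pairing,
    cycle_lengths,
    n_sims: int,
    protocol: TransferProtocol,
    config: ModelConfig,
    seed: int = 0,
    initial: tuple[int, int] | None = None,
    tensor_cache: dict | None = None,
) -> pd.DataFrame:
    """Outcome fractions of a pairing across cycle lengths.

    ``pairing`` is a pair of phenotype names (or strategy objects); for
    each cycle length the adaptive phenotypes are re-solved at that
    horizon and ``n_sims`` seeded competitions are tabulated.
    """
    tensor_cache = tensor_cache if tensor_cache is not None else {}
    rows = []
    for i, T in enumerate(cycle_lengths):
        cfg = config.replace(T=int(T))
        proto = dataclasses.replace(
            protocol, cycle_length=int(T)
        )
        strat_a = resolve_pair_strategy(pairing[0], cfg, tensor_cache)
        strat_b = resolve_pair_strategy(pairing[1], cfg, tensor_cache)
        labels = simulate_competition_batch(
            strat_a, strat_b, proto, cfg, n_sims, seed + i, initial=initial
        )
        row = {"T": int(T)} | tabulate_outcomes(labels) | {"seed": seed + i}
        logger.info("sweep %s vs %s: %s", pairing[0], pairing[1], row)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.rename(
        columns={
            FOCAL_WIN: "win",
            FOCAL_LOSS: "loss",
            COEXIST: "coexist",
            ALL_EXTINCT: "all_extinct",
        }
    )
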