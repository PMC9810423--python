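"""Exact one-step transition kernels and forward propagation.

One time step changes the population size by ``births - deaths`` where the
two counts are independent Poisson variables with intensities
``mu1 = N * beta_eff`` and ``mu2 = N * delta_eff``.  The increment is
therefore Skellam distributed.  Outcomes at or below zero are absorbed
into the extinction state 0; outcomes above the top of the state grid are
lumped onto the top state, so every transition row is a proper
probability vector.

Kernel rows are built by convolving the two Poisson pmfs (the definition
of the Skellam law) with real FFTs, which is both numerically stable and
fast for the large event intensities reached near the top of the state
space.  The scalar :func:`skellam_pmf` uses the exponentially scaled
Bessel representation instead; the two routes agree to machine precision
and are cross-checked against a truncated double-sum in the test suite.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Union

import numpy as np
import scipy.fft as _fft
from scipy.special import gammaln, ive

from .model import GrowthMode, ModelConfig

logger = logging.getLogger(__name__)

#: mass tolerance for normalized distributions
MASS_TOL = 1e-10
#: warn when more than this much probability sits in the top states
TOP_MASS_WARN = 1e-9


# ---------------------------------------------------------------------------
# Skellam pmf


def skellam_pmf(mu1, mu2, k):
    """P(Poisson(mu1) - Poisson(mu2) = k), defined for any integer ``k``.

    Uses the exponentially scaled modified Bessel function

        pmf(k) = exp(-(mu1 + mu2) + 2 sqrt(mu1 mu2)
                     + (k / 2) log(mu1 / mu2)) * ive(|k|, 2 sqrt(mu1 mu2))

    with the degenerate Poisson limits handled when either intensity is
    zero.  Scalars or broadcastable arrays are accepted.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    k = np.asarray(k)
    if np.any(mu1 < 0) or np.any(mu2 < 0):
        raise ValueError("Poisson intensities must be non-negative")
    mu1, mu2, k = np.broadcast_arrays(mu1, mu2, k)
    kf = k.astype(float)
    out = np.zeros(kf.shape)
    both = (mu1 > 0) & (mu2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 2.0 * np.sqrt(mu1 * mu2)
        logterm = -(mu1 + mu2) + s + 0.5 * kf * (np.log(mu1) - np.log(mu2))
        vals = np.exp(np.where(both, logterm, -np.inf)) * ive(
            np.abs(kf), np.where(both, s, 0.0)
        )
    out[both] = vals[both]
    # mu2 == 0: pure birth process, Poisson(mu1) at k >= 0
    only1 = (mu2 == 0) & (mu1 > 0)
    out[only1] = np.where(
        kf[only1] >= 0, _poisson_pmf(kf[only1], mu1[only1]), 0.0
    )
    only2 = (mu1 == 0) & (mu2 > 0)
    out[only2] = np.where(
        kf[only2] <= 0, _poisson_pmf(-kf[only2], mu2[only2]), 0.0
    )
    neither = (mu1 == 0) & (mu2 == 0)
    out[neither] = (kf[neither] == 0).astype(float)
    if out.ndim == 0:
        return float(out)
    return out


def _poisson_pmf(k, mu):
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = k * np.log(mu) - mu - gammaln(k + 1.0)
    return np.where(k >= 0, np.exp(logp), 0.0)


# ---------------------------------------------------------------------------
# batched Poisson-convolution machinery

#: exponent floor below which pmf terms are treated as exact zeros; keeps
#: arrays free of subnormals (which are extremely slow on some CPUs)
_LOG_FLOOR = -60.0
#: rows per FFT block, chosen to keep temporaries small enough for the
#: allocator to recycle
_BLOCK_ROWS = 3000


def poisson_support(mu_max: float) -> int:
    """Support length covering a Poisson tail down to ~1e-25."""
    mu_max = float(mu_max)
    return int(np.ceil(mu_max + 12.0 * np.sqrt(mu_max + 1.0) + 25.0))


def _poisson_pmf_block(mu: np.ndarray, length: int) -> np.ndarray:
    """Poisson pmf rows, one per intensity, support ``0..length-1``."""
    k = np.arange(length, dtype=float)
    lg = gammaln(k + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = k[None, :] * np.log(mu[:, None]) - mu[:, None] - lg[None, :]
    np.nan_to_num(logp, copy=False, nan=-np.inf, neginf=-np.inf)
    small = logp < _LOG_FLOOR
    out = np.exp(np.maximum(logp, _LOG_FLOOR))
    out[small] = 0.0
    zero = mu == 0
    out[zero] = 0.0
    out[zero, 0] = 1.0
    return out


def skellam_band(mu1, mu2, Lb: int, Ld: int) -> np.ndarray:
    """Skellam pmf rows for paired intensity vectors.

    Returns an array of shape ``(len(mu1), Lb + Ld - 1)`` whose column
    ``j`` holds ``P(increment = j - (Ld - 1))``; i.e. the band covers
    increments ``-(Ld-1) .. Lb-1``.  Computed as the FFT convolution of
    the birth and (reversed) death Poisson pmfs.
    """
    mu1 = np.asarray(mu1, dtype=float).ravel()
    mu2 = np.asarray(mu2, dtype=float).ravel()
    L = Lb + Ld - 1
    nf = _fft.next_fast_len(L, real=True)
    B = _poisson_pmf_block(mu1, Lb)
    D = _poisson_pmf_block(mu2, Ld)
    conv = _fft.irfft(
        _fft.rfft(B, nf, axis=-1) * _fft.rfft(D[:, ::-1], nf, axis=-1),
        nf,
        axis=-1,
    )[:, :L]
    np.clip(conv, 0.0, None, out=conv)
    return conv


def _scatter_rows(
    band: np.ndarray, sources: np.ndarray, n_states: int, Ld: int, out: np.ndarray
) -> None:
    """Scatter Skellam bands into dense transition rows (one block).

    ``band[r, j]`` is the probability of increment ``j - (Ld - 1)`` from
    source state ``sources[r]``.  Mass landing at or below zero is
    absorbed into state 0, mass landing at or above the top state is
    lumped onto it, and rows for source 0 are a point mass at 0.
    """
    R, L = band.shape
    cum = np.cumsum(band, axis=1)
    dest = np.arange(n_states)
    # column index of destination d for source s: j = d - s + (Ld - 1)
    jidx = dest[None, :] - sources[:, None] + (Ld - 1)
    valid = (jidx >= 0) & (jidx < L)
    out[:] = np.take_along_axis(band, np.clip(jidx, 0, L - 1), axis=1)
    out[~valid] = 0.0
    # absorbing boundary: everything at destination <= 0
    j0 = np.clip(jidx[:, 0], -1, L - 1)
    low = np.where(
        j0 >= 0, np.take_along_axis(cum, np.maximum(j0, 0)[:, None], 1)[:, 0], 0.0
    )
    out[:, 0] = low
    # top lump: everything at destination >= n_top; using the exact total
    # mass 1 keeps each row normalized to machine precision
    jpen = np.clip(jidx[:, -1] - 1, -1, L - 1)
    below_top = np.where(
        jpen >= 0, np.take_along_axis(cum, np.maximum(jpen, 0)[:, None], 1)[:, 0], 0.0
    )
    out[:, -1] = np.maximum(1.0 - below_top, 0.0)
    zero_src = sources == 0
    out[zero_src] = 0.0
    out[zero_src, 0] = 1.0


def _fill_transition_rows(
    mu1: np.ndarray,
    mu2: np.ndarray,
    sources: np.ndarray,
    n_states: int,
    out: np.ndarray,
) -> None:
    """Build dense transition rows for many (mu1, mu2, source) triples.

    Processed in blocks so that every temporary stays small; ``out`` must
    be a preallocated ``(len(mu1), n_states)`` array.
    """
    Lb = poisson_support(mu1.max())
    Ld = poisson_support(mu2.max())
    for lo in range(0, mu1.size, _BLOCK_ROWS):
        hi = min(lo + _BLOCK_ROWS, mu1.size)
        band = skellam_band(mu1[lo:hi], mu2[lo:hi], Lb, Ld)
        _scatter_rows(band, sources[lo:hi], n_states, Ld, out[lo:hi])


def transition_stack(
    mode: GrowthMode,
    config: ModelConfig,
    competitor_sizes,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Dense transition matrices for one mode, one per competitor size.

    ``out[c, N, N']`` is the probability of moving from ``N`` to ``N'``
    in one step when a second phenotype of fixed size
    ``competitor_sizes[c]`` shares the carrying capacity (0 recovers the
    monoculture kernel).  Shape ``(len(competitor_sizes), n, n)``.
    """
    comp = np.asarray(competitor_sizes, dtype=float).ravel()
    n = config.n_states
    N = np.arange(n, dtype=float)
    r = config.rates(GrowthMode(mode))
    mu1 = np.broadcast_to(N[None, :] * r.beta, (comp.size, n)).reshape(-1)
    delta_eff = r.delta + r.net_growth * (N[None, :] + comp[:, None]) / config.K
    mu2 = (N[None, :] * delta_eff).reshape(-1)
    if out is None:
        out = np.empty((comp.size, n, n))
    sources = np.broadcast_to(np.arange(n), (comp.size, n)).reshape(-1)
    _fill_transition_rows(mu1, mu2, sources, n, out.reshape(-1, n))
    return out


def transition_matrix(
    mode: GrowthMode, config: ModelConfig, competitor: int = 0
) -> np.ndarray:
    """Dense one-step transition matrix ``W[N, N']`` for one mode."""
    return transition_stack(mode, config, [competitor])[0]


# ---------------------------------------------------------------------------
# distributions


@dataclasses.dataclass
class TransitionRow:
    """One-step destination distribution from a single source state."""

    source: int
    mode: GrowthMode
    probs: np.ndarray


@dataclasses.dataclass
class PopulationDistribution:
    """Probability vector over population sizes ``0 .. n_top`` at time t."""

    probs: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -MASS_TOL):
            raise ValueError("negative probabilities")
        if abs(self.probs.sum() - 1.0) > MASS_TOL:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def point_mass(cls, N: int, config: ModelConfig, t: int = 0):
        probs = np.zeros(config.n_states)
        probs[N] = 1.0
        return cls(probs=probs, t=t)


@dataclasses.dataclass(frozen=True)
class DistributionSummary:
    median: int
    mean: float
    variance: float
    extinction_probability: float


def transition_row(
    N: int, mode: GrowthMode, config: ModelConfig, competitor: int = 0
) -> TransitionRow:
    """Exact one-step transition probabilities from state ``N``."""
    if not 0 <= N <= config.n_top:
        raise ValueError(f"source state {N} outside 0..{config.n_top}")
    n = config.n_states
    if N == 0:
        probs = np.zeros(n)
        probs[0] = 1.0
        return TransitionRow(source=0, mode=GrowthMode(mode), probs=probs)
    r = config.rates(GrowthMode(mode))
    mu1 = N * r.beta
    mu2 = N * (r.delta + r.net_growth * (N + competitor) / config.K)
    probs = np.empty((1, n))
    _fill_transition_rows(
        np.array([mu1]), np.array([mu2]), np.array([N]), n, probs
    )
    return TransitionRow(source=N, mode=GrowthMode(mode), probs=probs[0])


def propagate(
    dist: PopulationDistribution,
    strategy,
    config: ModelConfig,
    steps: int,
    kernels: tuple[np.ndarray, np.ndarray] | None = None,
    warn_top_mass: bool = True,
) -> PopulationDistribution:
    """Push a population-size distribution forward in time.

    Applies the master-equation update ``P_{t+1} = P_t W`` for ``steps``
    steps, where the row of ``W`` used at state ``N`` and time ``t`` is
    the kernel of the mode assigned by ``strategy`` (an object exposing
    ``mode_vector(t, n_states)``).  ``kernels`` may carry precomputed
    ``(W_def, W_aggr)`` matrices to amortize kernel construction.
    """
    if kernels is None:
        kernels = (
            transition_matrix(GrowthMode.DEFENSIVE, config),
            transition_matrix(GrowthMode.AGGRESSIVE, config),
        )
    W_def, W_aggr = kernels
    p = dist.probs.copy()
    masked = np.empty_like(p)
    for step in range(steps):
        t = dist.t + step
        modes = strategy.mode_vector(t, config.n_states)
        aggr = modes.astype(bool)
        np.multiply(p, ~aggr, out=masked)
        nxt = masked @ W_def
        np.multiply(p, aggr, out=masked)
        nxt += masked @ W_aggr
        p = nxt
    top_mass = p[-5:].sum()
    if warn_top_mass and top_mass > TOP_MASS_WARN:
        warnings.warn(
            f"probability mass {top_mass:.2e} within the top 5 states; "
            "the state-space factor l may be too small",
            stacklevel=2,
        )
    return PopulationDistribution(probs=p, t=dist.t + steps)


def summarize(dist: PopulationDistribution) -> DistributionSummary:
    """Median (smallest N with cumulative mass >= 1/2), mean, variance
    and extinction probability of a population-size distribution."""
    p = dist.probs
    states = np.arange(p.size)
    cum = np.cumsum(p)
    median = int(np.searchsorted(cum, 0.5 - 1e-12))
    mean = float(p @ states)
    var = float(p @ (states - mean) ** 2)
    return DistributionSummary(
        median=median,
        mean=mean,
        variance=var,
        extinction_probability=float(p[0]),
    )
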