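"""The Monte Carlo engine: Fermi imitation under random sequential update.

One elementary step: pick a site x uniformly at random, accumulate its
payoff Pi_x over its four neighbors, pick one neighbor y uniformly,
accumulate Pi_y the same way (on the current grid, including x's current
strategy), then let x adopt y's strategy with the Fermi probability

    W(s_x <- s_y) = 1 / (1 + exp((Pi_x - Pi_y) / K)),

where K is the adoption noise.  A full Monte Carlo step (MCS) is L^2
elementary steps, so each player revises its strategy once on average.

Two interchangeable engines run the same dynamics: a numba-compiled
kernel (default) and a literal pure-Python reference.  Both consume an
identical pre-drawn random stream (site index, neighbor pick, uniform
acceptance draw per elementary step), so for the same seed they produce
bit-identical trajectories; the test suite relies on this equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .core_model import (
    GameVariant,
    PayoffMatrix,
    PayoffParams,
    Strategy,
    build_payoff_matrix,
    get_variant,
    pair_payoff,
)
from .lattice import InitialStateSpec, LatticeState, init_state, neighbor_table, neighbors

__all__ = [
    "DynamicsParams",
    "SimulationConfig",
    "TimeSeries",
    "fermi_probability",
    "site_payoff",
    "elementary_step",
    "run_simulation",
]

_EXP_CLAMP = 700.0  # |argument| beyond this would overflow exp in float64


@dataclass(frozen=True)
class DynamicsParams:
    """Strategy-adoption noise K (payoff units); K = 0.5 throughout the
    study, quantifying uncertainty in evaluating the opponent."""

    K: float = 0.5

    def __post_init__(self) -> None:
        if not (self.K > 0) or not np.isfinite(self.K):
            raise ValueError(f"K must be strictly positive and finite, got {self.K}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a single simulation run (one replicate).

    ``relaxation_mcs`` marks the burn-in discarded before any stationary
    averaging; ``sample_every`` is the MCS interval between samples of
    the strategy fractions.
    """

    variant: GameVariant | str = "three_strategy"
    params: PayoffParams = field(default_factory=PayoffParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    L: int = 100
    max_mcs: int = 1000
    sample_every: int = 10
    relaxation_mcs: int = 0
    seed: int = 0
    initial: InitialStateSpec = field(default_factory=InitialStateSpec)
    replicates: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", get_variant(self.variant))
        if self.max_mcs < 0 or self.relaxation_mcs < 0:
            raise ValueError("MCS budgets must be nonnegative")
        if self.max_mcs < self.relaxation_mcs:
            raise ValueError("max_mcs must be >= relaxation_mcs")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TimeSeries:
    """Sampled per-strategy fractions over Monte Carlo time.

    ``fractions[k]`` are the strategy fractions (variant order) at
    ``mcs[k]``; they are exact site counts over L^2 and sum to 1.
    ``extinction_mcs`` maps a strategy to the MCS time at which its count
    first reached zero (imitation can never resurrect it).
    """

    variant: GameVariant
    mcs: np.ndarray
    fractions: np.ndarray
    final_state: LatticeState
    extinction_mcs: dict[Strategy, float] = field(default_factory=dict)

    def fraction_of(self, strategy: Strategy) -> np.ndarray:
        return self.fractions[:, self.variant.index[strategy]]

    def window_mean(self, start_mcs: float, end_mcs: float | None = None) -> np.ndarray:
        """Time-averaged fractions over samples with start <= mcs <= end."""
        sel = self.mcs >= start_mcs
        if end_mcs is not None:
            sel &= self.mcs <= end_mcs
        if not sel.any():
            raise ValueError("no samples in requested window")
        return self.fractions[sel].mean(axis=0)

    def to_dataframe(self):
        import pandas as pd

        cols = {"mcs": self.mcs}
        for s in self.variant.strategies:
            cols[f"f_{s.name}"] = self.fraction_of(s)
        return pd.DataFrame(cols)


def fermi_probability(pi_x: float, pi_y: float, K: float) -> float:
    """Probability that x adopts y's strategy given payoffs Pi_x, Pi_y.

    Strictly increasing in Pi_y - Pi_x; extreme payoff differences
    saturate to 0 or 1 without overflow.
    """
    if not (K > 0):
        raise ValueError(f"K must be strictly positive, got {K}")
    if not (math.isfinite(pi_x) and math.isfinite(pi_y)):
        raise ValueError("payoffs must be finite")
    arg = (pi_x - pi_y) / K
    arg = max(-_EXP_CLAMP, min(_EXP_CLAMP, arg))
    return 1.0 / (1.0 + math.exp(arg))


def site_payoff(state: LatticeState, site: tuple[int, int], matrix: PayoffMatrix) -> float:
    """Payoff of the player at ``site``: sum of the pairwise game with its
    four von Neumann neighbors (no normalization)."""
    focal = state.variant.strategies[state.grid[site]]
    total = 0.0
    for nb in neighbors(site, state.L):
        total += pair_payoff(matrix, focal, state.variant.strategies[state.grid[nb]])
    return total


def elementary_step(
    state: LatticeState,
    matrix: PayoffMatrix,
    K: float,
    rng: np.random.Generator,
) -> LatticeState:
    """One random-sequential-update attempt, in place.

    Draws the focal site, one of its four neighbors and the acceptance
    uniform from ``rng`` (three draws per step, in that order).
    """
    L = state.L
    flat = int(rng.integers(0, L * L))
    pick = int(rng.integers(0, 4))
    u = float(rng.random())
    _literal_step(state, matrix, K, flat, pick, u)
    return state


def _literal_step(
    state: LatticeState, matrix: PayoffMatrix, K: float, flat: int, pick: int, u: float
) -> None:
    """Literal transcription of the update rule; the reference engine."""
    L = state.L
    x = (flat // L, flat % L)
    pi_x = site_payoff(state, x, matrix)
    y = neighbors(x, L)[pick]
    pi_y = site_payoff(state, y, matrix)
    if u < fermi_probability(pi_x, pi_y, K):
        state.grid[x] = state.grid[y]


@njit(cache=True)
def _run_block(grid, nbr, M, K, sites, picks, us, counts, ext_step):  # pragma: no cover
    """Run len(sites) elementary steps on the flat grid, in place.

    ``counts`` (per-strategy site counts) is updated incrementally;
    ``ext_step`` records the 0-based step index within this block at
    which a strategy count first hit zero (-1 otherwise).
    """
    n = sites.shape[0]
    for t in range(n):
        x = sites[t]
        sx = grid[x]
        y = nbr[x, picks[t]]
        sy = grid[y]
        pi_x = 0.0
        pi_y = 0.0
        for k in range(4):
            pi_x += M[sx, grid[nbr[x, k]]]
            pi_y += M[sy, grid[nbr[y, k]]]
        arg = (pi_x - pi_y) / K
        if arg > 700.0:
            arg = 700.0
        elif arg < -700.0:
            arg = -700.0
        w = 1.0 / (1.0 + np.exp(arg))
        if us[t] < w and sy != sx:
            counts[sx] -= 1
            counts[sy] += 1
            grid[x] = sy
            if counts[sx] == 0:
                ext_step[sx] = t


def _reference_block(state, matrix, K, sites, picks, us, counts, ext_step) -> None:
    """Mirror of :func:`_run_block` built on the literal per-step rule."""
    L = state.L
    for t in range(sites.shape[0]):
        flat = int(sites[t])
        x = (flat // L, flat % L)
        sx = int(state.grid[x])
        y = neighbors(x, L)[int(picks[t])]
        sy = int(state.grid[y])
        pi_x = site_payoff(state, x, matrix)
        pi_y = site_payoff(state, y, matrix)
        if us[t] < fermi_probability(pi_x, pi_y, K) and sy != sx:
            counts[sx] -= 1
            counts[sy] += 1
            state.grid[x] = sy
            if counts[sx] == 0:
                ext_step[sx] = t


def run_simulation(config: SimulationConfig, engine: str = "fast") -> TimeSeries:
    """Run one replicate of the lattice dynamics.

    Samples the strategy fractions at MCS 0 and every ``sample_every``
    MCS thereafter, up to ``max_mcs``.  Reproducible: the same config
    (including seed) yields a bit-identical TimeSeries with either
    engine.

    Parameters
    ----------
    config
        Run specification; ``config.seed`` seeds both the initial state
        and the update sequence.
    engine
        ``"fast"`` (numba kernel) or ``"reference"`` (literal
        pure-Python transcription of the update rule; orders of
        magnitude slower, for validation only).
    """
    if engine not in ("fast", "reference"):
        raise ValueError(f"engine must be 'fast' or 'reference', got {engine!r}")
    variant = config.variant
    L = config.L
    rng = np.random.default_rng(config.seed)
    state = init_state(config.initial, variant, L, rng)
    matrix = build_payoff_matrix(config.params, variant)
    K = config.dynamics.K
    nstrat = variant.n_strategies
    nsite = L * L

    nbr = neighbor_table(L)
    grid = state.grid.reshape(-1)
    counts = np.bincount(grid, minlength=nstrat).astype(np.int64)
    extinctions: dict[Strategy, float] = {
        variant.strategies[i]: 0.0 for i in range(nstrat) if counts[i] == 0
    }

    times = [0.0]
    samples = [counts / nsite]
    mcs_done = 0
    while mcs_done < config.max_mcs:
        block_mcs = min(config.sample_every, config.max_mcs - mcs_done)
        nsteps = block_mcs * nsite
        sites = rng.integers(0, nsite, size=nsteps)
        picks = rng.integers(0, 4, size=nsteps)
        us = rng.random(nsteps)
        ext_step = np.full(nstrat, -1, dtype=np.int64)
        if engine == "fast":
            _run_block(grid, nbr, matrix.entries, K, sites, picks, us, counts, ext_step)
        else:
            _reference_block(state, matrix, K, sites, picks, us, counts, ext_step)
        for i in range(nstrat):
            if ext_step[i] >= 0:
                extinctions[variant.strategies[i]] = mcs_done + (ext_step[i] + 1) / nsite
        mcs_done += block_mcs
        times.append(float(mcs_done))
        samples.append(counts / nsite)
        if np.count_nonzero(counts) <= 1:
            # homogeneous states are absorbing: pad remaining samples
            while mcs_done < config.max_mcs:
                block_mcs = min(config.sample_every, config.max_mcs - mcs_done)
                mcs_done += block_mcs
                times.append(float(mcs_done))
                samples.append(counts / nsite)
            break

    return TimeSeries(
        variant=variant,
        mcs=np.asarray(times),
        fractions=np.asarray(samples),
        final_state=state,
        extinction_mcs=extinctions,
    )
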