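"""Strategies, payoff parameters and pairwise payoff matrices.

The spatial inspection game is played between *ordinary people* (O), who
neither commit nor sanction crime, *criminals* (C), and *punishers*, who
pay an inspection cost to sanction criminals.  In the uniform-punishment
game there is a single punisher type P.  In the heterogeneous-punishment
game punishers come in three ranks L, M and H that carry 1/3, 2/3 and the
full punishment cost respectively, and receive a proportionally scaled
reward and impose a proportionally scaled fine.

Per pairwise interaction the payoffs are built from three parameters:

* ``alpha`` -- cost of inspection, paid by a punisher in every interaction;
* ``beta``  -- temptation to commit crime, equal to the loss suffered by
  its victim;
* ``gamma`` -- reward for punishing a criminal.

The punishment fine is normalized to 1, so a criminal meeting a rank-``r``
punisher earns ``beta - r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from fractions import Fraction
from io import StringIO
from typing import Iterable

import numpy as np

__all__ = [
    "Strategy",
    "PayoffParams",
    "GameVariant",
    "VARIANTS",
    "get_variant",
    "PayoffMatrix",
    "build_payoff_matrix",
    "pair_payoff",
]


class Strategy(IntEnum):
    """Strategy codes shared by all game variants.

    The integer value is the global code; each variant maps a subset of
    these onto contiguous matrix indices.
    """

    O = 0  # ordinary: no crime, no sanctioning (second-order free-rider)
    C = 1  # criminal
    L = 2  # punisher, rank 1/3
    M = 3  # punisher, rank 2/3
    H = 4  # punisher, rank 1 (heterogeneous model)
    P = 5  # punisher, rank 1 (uniform model; behaves identically to H)

    @property
    def rank(self) -> Fraction:
        """Punisher commitment fraction r (0 for O and C)."""
        return _RANKS[self]

    @property
    def is_punisher(self) -> bool:
        return self.rank > 0


_RANKS = {
    Strategy.O: Fraction(0),
    Strategy.C: Fraction(0),
    Strategy.L: Fraction(1, 3),
    Strategy.M: Fraction(2, 3),
    Strategy.H: Fraction(1),
    Strategy.P: Fraction(1),
}


@dataclass(frozen=True)
class PayoffParams:
    """Payoff parameters (dimensionless payoff units).

    ``fine`` is the normalized punishment fine; it is 1 by construction
    and only exposed so degenerate (all-zero payoff) dynamics can be set
    up for neutral-drift checks.
    """

    alpha: float = 0.5
    beta: float = 0.8
    gamma: float = 0.8
    fine: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "fine"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class GameVariant:
    """A named strategy set with a fixed matrix-index order."""

    name: str
    strategies: tuple[Strategy, ...]
    index: dict[Strategy, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("variant must have a nonempty strategy set")
        object.__setattr__(
            self, "index", {s: i for i, s in enumerate(self.strategies)}
        )

    @property
    def n_strategies(self) -> int:
        return len(self.strategies)

    def __contains__(self, s: Strategy) -> bool:
        return s in self.index


THREE_STRATEGY = GameVariant("three_strategy", (Strategy.O, Strategy.C, Strategy.P))
FIVE_STRATEGY = GameVariant(
    "five_strategy",
    (Strategy.O, Strategy.C, Strategy.L, Strategy.M, Strategy.H),
)
#: Minimal interface model: the five-strategy matrix restricted to C, L, M.
MINIMAL_CLM = GameVariant("minimal_CLM", (Strategy.C, Strategy.L, Strategy.M))

VARIANTS: dict[str, GameVariant] = {
    v.name: v for v in (THREE_STRATEGY, FIVE_STRATEGY, MINIMAL_CLM)
}


def get_variant(name: str | GameVariant) -> GameVariant:
    if isinstance(name, GameVariant):
        return name
    try:
        return VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; expected one of {sorted(VARIANTS)}"
        ) from None


@dataclass(frozen=True)
class PayoffMatrix:
    """Focal-vs-opponent payoff table for one variant.

    ``entries[i, j]`` is the payoff the focal player with strategy
    ``variant.strategies[i]`` collects from one interaction with an
    opponent playing ``variant.strategies[j]``.
    """

    variant: GameVariant
    params: PayoffParams
    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        n = self.variant.n_strategies
        if e.shape != (n, n):
            raise ValueError(f"entries must be {n}x{n}, got {e.shape}")
        object.__setattr__(self, "entries", e)
        e.setflags(write=False)

    def to_csv(self) -> str:
        """Matrix as CSV with a header row/column of strategy labels."""
        buf = StringIO()
        labels = [s.name for s in self.variant.strategies]
        buf.write("," + ",".join(labels) + "\n")
        for lab, row in zip(labels, self.entries):
            buf.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()


def _pair_entry(focal: Strategy, opp: Strategy, p: PayoffParams) -> float:
    """Payoff of ``focal`` against ``opp`` for a single interaction.

    Punishers pay the inspection cost r*alpha in every interaction and
    collect r*(gamma - alpha) from a criminal; they do not suffer the
    victim loss.  A criminal earns beta from an ordinary victim and
    beta - r*fine from a rank-r punisher; criminals gain nothing from
    each other.  Ordinary people lose beta to a criminal and exchange
    nothing otherwise.
    """
    rf = float(focal.rank)
    if rf > 0:  # focal is a punisher
        if opp is Strategy.C:
            return rf * (p.gamma - p.alpha)
        return -rf * p.alpha
    if focal is Strategy.C:
        if opp is Strategy.O:
            return p.beta
        if opp is Strategy.C:
            return 0.0
        return p.beta - float(opp.rank) * p.fine
    # focal is ordinary
    if opp is Strategy.C:
        return -p.beta
    return 0.0


def build_payoff_matrix(
    params: PayoffParams, variant: str | GameVariant
) -> PayoffMatrix:
    """Construct the pairwise payoff matrix for a variant.

    Parameters
    ----------
    params
        Payoff parameters (alpha, beta, gamma; fine normalized to 1).
    variant
        One of ``three_strategy``, ``five_strategy``, ``minimal_CLM``
        or a :class:`GameVariant`.

    Returns
    -------
    PayoffMatrix
        Square table indexed [focal][opponent] in the variant's strategy
        order.
    """
    v = get_variant(variant)
    n = v.n_strategies
    entries = np.empty((n, n), dtype=float)
    for i, si in enumerate(v.strategies):
        for j, sj in enumerate(v.strategies):
            entries[i, j] = _pair_entry(si, sj, params)
    return PayoffMatrix(v, params, entries)


def pair_payoff(matrix: PayoffMatrix, focal: Strategy, opponent: Strategy) -> float:
    """Look up the focal player's payoff for one pairwise interaction."""
    v = matrix.variant
    try:
        i = v.index[focal]
        j = v.index[opponent]
    except KeyError as exc:
        raise KeyError(f"strategy {exc.args[0]!r} not in variant {v.name!r}") from None
    return float(matrix.entries[i, j])


def strategy_labels(strategies: Iterable[Strategy]) -> str:
    """Canonical '+'-joined label for a set of strategies, e.g. 'O+C+P'."""
    order = {s: i for i, s in enumerate(Strategy)}
    return "+".join(s.name for s in sorted(strategies, key=order.__getitem__))
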